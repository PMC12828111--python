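"""Convenience dose-response plots for truth scenarios."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scenarios import ScenarioTruth

__all__ = ["plot_scenario"]


def plot_scenario(s: ScenarioTruth, out_path: str | None = None):
    """Plot the true mean immune response, toxicity and SD/CR/PR rate against
    dose, one line per schedule, one row per subgroup."""
    fig, axes = plt.subplots(2, 3, figsize=(10, 6), sharex=True)
    doses = s.doses
    for m in range(2):
        for k in range(s.n_schedules):
            axes[m, 0].plot(doses, s.mu_z_true[:, k, m], "o-", label=s.schedules[k])
            axes[m, 1].plot(doses, s.p_tox_true[:, k], "o-")
            axes[m, 2].plot(
                doses,
                [s.pi(j, k, m) for j in range(s.n_doses)],
                "o-",
            )
        axes[m, 0].set_ylabel(f"M={m}")
    axes[0, 0].set_title("mean immune response")
    axes[0, 1].set_title("toxicity probability")
    axes[0, 2].set_title("Pr(Y > 0)")
    axes[1, 1].set_xlabel("dose")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
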