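"""Quick-look plots for experiment runs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless use; callers can switch backends beforehand
import matplotlib.pyplot as plt

from .experiments import ExperimentResult


def plot_normalized_concentrations(result: ExperimentResult, path=None):
    """Normalized concentration (C/C0) versus time for each dye, one line per
    trial, with the preset's expected steady-state fractions as dashed levels."""
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"EG": "tab:blue", "TZ": "tab:orange"}
    for df in result.concentrations:
        for dye in ("TZ", "EG"):
            col = f"C_{dye.lower()}_norm"
            if col in df:
                ax.plot(
                    df["time_s"] / 60.0, df[col], color=colors.get(dye), alpha=0.6, lw=0.8
                )
    for p, (t0, t1) in enumerate(result.preset.phase_bounds_s):
        for dye, frac in result.preset.expected_fractions[p].items():
            ax.hlines(frac, t0 / 60.0, t1 / 60.0, colors=colors.get(dye), ls="--", lw=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("C / C0")
    ax.set_title(f"{result.preset.name}: recovered normalized concentrations")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
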