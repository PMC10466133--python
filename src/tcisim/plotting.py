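"""Optional plotting helpers (matplotlib required).

Renders the cohort concentration-time band plot: median profile with the 95%
prediction interval per arm, the target line, and the +/-10% accuracy band.
"""

from __future__ import annotations

from .trial import CohortSummary

__all__ = ["plot_ct_bands"]


def plot_ct_bands(
    summaries: dict[str, CohortSummary],
    target: float | None = None,
    ax=None,
):
    """Plot median +/- PI95 bands for each arm. Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    colors = {"open_loop": "0.5", "closed_loop": "tab:blue"}
    for arm, s in summaries.items():
        c = colors.get(arm, None)
        ax.fill_between(s.times, s.lo95, s.hi95, alpha=0.3, color=c, label=f"{arm} PI95")
        ax.plot(s.times, s.median, color=c, label=f"{arm} median")
    if target is not None:
        ax.axhline(target, ls="--", color="k", lw=1, label="target")
        ax.axhspan(0.9 * target, 1.1 * target, color="k", alpha=0.06)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend(loc="lower right", fontsize=8)
    return ax
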