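"""Minimal exploratory plotting: individual biomarker profiles."""

from __future__ import annotations

from .core_types import Cohort

__all__ = ["plot_profiles"]


def plot_profiles(cohort: Cohort, max_subjects: int = 30, ax=None):
    """Spaghetti plot of ln(1 + IgG) trajectories with the cohort mean trend.

    Matplotlib is imported lazily so the modeling stack has no hard plotting
    dependency. Returns the axes.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    all_t, all_y = [], []
    for s in cohort.subjects[:max_subjects]:
        t = [o.t for o in s.observations]
        y = [o.y for o in s.observations]
        ax.plot(t, y, color="steelblue", alpha=0.35, lw=0.8)
        all_t.extend(t)
        all_y.extend(y)
    if all_t:
        coeffs = np.polyfit(all_t, all_y, 1)
        grid = np.linspace(min(all_t), max(all_t), 50)
        ax.plot(grid, np.polyval(coeffs, grid), color="firebrick", lw=2, label="mean trend")
        ax.legend()
    ax.set_xlabel("months since onset")
    ax.set_ylabel("ln(1 + IgG titer)")
    return ax
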