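"""Basic plotting helpers: trajectory fans and the status dendrogram."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_status_dendrogram", "plot_trajectory_fan"]


def plot_status_dendrogram(points, path=None, ax=None):
    """Ward dendrogram of (growth rate, p_decline) status points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram, linkage

    X = np.array([[p.lambda_unharvested, p.p_decline] for p in points])
    Z = linkage(X, method="ward")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    dendrogram(Z, labels=[p.subpop_id for p in points], ax=ax)
    ax.set_ylabel("Ward linkage distance")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_trajectory_fan(ensemble, start_year=0, ax=None, quantiles=(0.05, 0.5, 0.95)):
    """Quantile fan of an ensemble's abundance trajectories."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = ensemble.trajectories
    years = start_year + np.arange(traj.shape[1])
    if ax is None:
        _, ax = plt.subplots()
    qs = np.quantile(traj, quantiles, axis=0)
    ax.fill_between(years, qs[0], qs[-1], alpha=0.3, label=f"{quantiles[0]:.0%}-{quantiles[-1]:.0%}")
    ax.plot(years, qs[len(quantiles) // 2], lw=2, label="median")
    ax.set_xlabel("year")
    ax.set_ylabel("N")
    ax.legend()
    return ax
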