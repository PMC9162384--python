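"""Minimal plotting helpers (Agg backend; no display required)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_qq", "plot_roc", "plot_null_distribution"]


def plot_qq(screen, path: str | Path) -> None:
    """Normal Q-Q plot from a QQScreenResult, flagged subjects highlighted."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(screen.theoretical, screen.ordered, "o", ms=4)
    lo, hi = screen.theoretical[0], screen.theoretical[-1]
    mu, sd = np.mean(screen.ordered), np.std(screen.ordered, ddof=1)
    ax.plot([lo, hi], [mu + lo * sd, mu + hi * sd], "-", color="gray", lw=1)
    flagged = set(screen.flagged)
    if flagged:
        # robust z is a monotone map of the raw value, so sorting by it
        # recovers the subject order of the sorted sample
        ids_sorted = [screen.subject_ids[i] for i in np.argsort(screen.robust_z,
                                                                kind="stable")]
        for q, v, sid in zip(screen.theoretical, screen.ordered, ids_sorted):
            if sid in flagged:
                ax.plot(q, v, "rx", ms=8)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("observed value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(fpr, tpr, auc: float, path: str | Path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, "-", lw=1.5, label=f"{label} AUC={auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_null_distribution(null_max_sizes, observed: int, path: str | Path) -> None:
    """Permutation null of the maximal component size with the observed value."""
    fig, ax = plt.subplots(figsize=(4, 3))
    sizes = np.asarray(null_max_sizes)
    ax.hist(sizes, bins=np.arange(sizes.min(), sizes.max() + 2) - 0.5,
            color="steelblue")
    ax.axvline(observed, color="red", lw=1.5)
    ax.set_xlabel("max component size")
    ax.set_ylabel("permutations")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
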