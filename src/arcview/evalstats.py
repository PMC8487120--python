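"""Cohort-level comparison of viewing-angle sets.

Mirrors the evaluation protocol used when judging an automatic angle
selector against a reference (expert settings, or phantom ground truth):
per-group means and spreads, a two-sided hypothesis test gated on
normality (Shapiro-Wilk on both samples at the same alpha; Student's
t-test when both pass, Mann-Whitney U otherwise), per-case absolute
differences, and the proportions of cases with differences below 3
degrees, between 3 and 5, and at or above 5.

Tests are unpaired (group means are being compared); the per-case absolute
differences are a separate, paired summary.  Whether a reported spread is
SD or SEM is often ambiguous in summaries, so both are emitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["AngleComparison", "compare_angle_sets", "difference_bins"]

#: Bin boundaries (degrees) for absolute angle differences, left-closed
#: right-open, plus an overflow bin.
DEFAULT_BIN_EDGES = (3.0, 5.0)


@dataclass
class AngleComparison:
    """Summary of a method-vs-reference angle comparison."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    p_value: float
    test_used: str
    abs_differences: np.ndarray
    bins: tuple[float, ...]
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    alpha: float = 0.05
    paired_differences: bool = True
    paired_test: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["abs_differences"] = self.abs_differences.tolist()
        return d


def difference_bins(
    diffs: Sequence[float], edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> tuple[float, ...]:
    """Proportions of differences per left-closed right-open bin.

    ``edges=(3, 5)`` yields proportions in [0, 3), [3, 5) and [5, inf).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("diffs must be non-empty")
    if np.any(d < 0):
        raise ValueError("differences must be non-negative")
    e = np.asarray(edges, dtype=float)
    if e.size == 0 or np.any(np.diff(e) <= 0):
        raise ValueError("edges must be non-empty and strictly increasing")
    idx = np.searchsorted(e, d, side="right")
    counts = np.bincount(idx, minlength=e.size + 1)
    return tuple(counts / d.size)


def compare_angle_sets(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> AngleComparison:
    """Compare two case-paired lists of angles (degrees).

    Both samples are screened with Shapiro-Wilk at ``alpha``; if both look
    normal an unpaired two-sided Student's t-test is applied, otherwise a
    two-sided Mann-Whitney U test.  Absolute per-case differences and their
    binned proportions are computed from the pairing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"samples must be 1-D and case-paired, got {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError(f"need at least 3 cases, got {a.size}")
    normal_a = stats.shapiro(a).pvalue > alpha
    normal_b = stats.shapiro(b).pvalue > alpha
    if normal_a and normal_b:
        test_used = "t-test"
        p_value = float(stats.ttest_ind(a, b).pvalue)
    else:
        test_used = "Mann-Whitney U"
        p_value = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    diffs = np.abs(a - b)
    return AngleComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        p_value=p_value,
        test_used=test_used,
        abs_differences=diffs,
        bins=difference_bins(diffs, bin_edges),
        bin_edges=tuple(float(e) for e in bin_edges),
        alpha=float(alpha),
    )


def plot_comparison(comparison: AngleComparison, a, b, out_dir) -> list:
    """Optional panels: boxplot of both groups, per-case difference line,
    difference-bin bars.  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([np.asarray(a, float), np.asarray(b, float)],
               tick_labels=["method", "reference"])
    ax.set_ylabel("viewing angle (deg)")
    fig.savefig(out_dir / "angles_boxplot.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "angles_boxplot.png")

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(comparison.abs_differences, marker="o", lw=1)
    ax.set_xlabel("case")
    ax.set_ylabel("|angle difference| (deg)")
    fig.savefig(out_dir / "angle_differences.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "angle_differences.png")

    fig, ax = plt.subplots(figsize=(4, 3))
    labels = ["[0, 3)", "[3, 5)", ">= 5"] if len(comparison.bins) == 3 else [
        str(i) for i in range(len(comparison.bins))
    ]
    ax.bar(labels, comparison.bins)
    ax.set_ylabel("proportion of cases")
    fig.savefig(out_dir / "difference_bins.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "difference_bins.png")
    return written
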