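"""Cross-dataset reproducibility: pairwise overlap of signatures at several
observation levels (miRNA, target gene, functional category) and the paired
test comparing overlap before vs after regulatory filtering."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OVERLAP_MODES = ("jaccard", "min")


def overlap_percentage(A: set[str], B: set[str], mode: str = "jaccard") -> float:
    """Overlap of two id sets in [0, 1].

    ``jaccard``: |A∩B| / |A∪B| (default); ``min``: |A∩B| / min(|A|, |B|).
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap mode {mode!r}")
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("both sets empty")
    inter = len(A & B)
    if mode == "jaccard":
        return inter / len(A | B)
    denom = min(len(A), len(B))
    return inter / denom if denom else 0.0


@dataclass
class OverlapReport:
    level: str
    mode: str
    pairs: pd.DataFrame  # columns: dataset_a, dataset_b, overlap

    @property
    def mean(self) -> float:
        return float(self.pairs["overlap"].mean())

    @property
    def median(self) -> float:
        return float(self.pairs["overlap"].median())

    @property
    def overlaps(self) -> np.ndarray:
        return self.pairs["overlap"].to_numpy()


def pairwise_overlap(lists: Mapping[str, set[str]], mode: str = "jaccard", level: str = "miRNA") -> OverlapReport:
    """Overlap for every unordered dataset pair (C(5,2)=10 pairs for 5 datasets)."""
    if len(lists) < 2:
        raise ValueError("need at least two datasets")
    rows = []
    for a, b in combinations(sorted(lists), 2):
        rows.append((a, b, overlap_percentage(lists[a], lists[b], mode)))
    pairs = pd.DataFrame(rows, columns=["dataset_a", "dataset_b", "overlap"])
    return OverlapReport(level=level, mode=mode, pairs=pairs)


def paired_ttest(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on the per-pair overlap differences, two-sided."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size < 2:
        raise ValueError("before/after must be equal-length with n >= 2")
    diffs = after - before
    # treat numerically-constant differences as zero variance
    spread = np.max(diffs) - np.min(diffs)
    if spread <= 1e-12 * max(1.0, float(np.max(np.abs(diffs)))):
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(after, before)
    return float(res.statistic), float(res.pvalue)


def level_report(
    level_lists: Mapping[str, Mapping[str, set[str]]],
    mode: str = "jaccard",
) -> tuple[dict[str, OverlapReport], pd.DataFrame]:
    """One overlap report per level plus a cross-level summary table.

    ``level_lists`` maps level name -> (dataset id -> id set).  Levels with
    missing inputs raise, naming the level.
    """
    reports: dict[str, OverlapReport] = {}
    for level, lists in level_lists.items():
        if not lists or any(v is None for v in lists.values()):
            raise ValueError(f"missing inputs for level {level!r}")
        reports[level] = pairwise_overlap(lists, mode=mode, level=level)
    summary = pd.DataFrame(
        {
            "mean_overlap": {lv: r.mean for lv, r in reports.items()},
            "median_overlap": {lv: r.median for lv, r in reports.items()},
            "n_pairs": {lv: len(r.pairs) for lv, r in reports.items()},
        }
    )
    summary.index.name = "level"
    return reports, summary
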