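"""Similarity of differential contrasts: set overlap and fold-change correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ContrastResult


@dataclass
class OverlapResult:
    jaccard: float
    overlap: int
    pval: float
    odds_ratio: float
    universe_size: int


def jaccard_index(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_test(a: set, b: set, universe_size: int) -> OverlapResult:
    """One-sided Fisher exact test for enrichment of the overlap of two sets
    drawn from a common universe, with the sample odds ratio
    (0.5 continuity correction when any cell is zero)."""
    a, b = set(a), set(b)
    if len(a | b) > universe_size:
        raise ValueError("universe smaller than |A ∪ B|")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = universe_size - len(a | b)
    table = np.array([[n11, n12], [n21, n22]])
    _, p = stats.fisher_exact(table, alternative="greater")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapResult(jaccard_index(a, b), n11, float(p), float(odds), universe_size)


def foldchange_correlation(ca: ContrastResult, cb: ContrastResult):
    """Pearson correlation of the two contrasts' log2 fold-change vectors
    over their shared non-missing features; returns (R, p)."""
    shared = ca.log2fc.dropna().index.intersection(cb.log2fc.dropna().index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared features with fold changes")
    r, p = stats.pearsonr(ca.log2fc.loc[shared], cb.log2fc.loc[shared])
    return float(r), float(p)


def pairwise_jaccard(sets: dict) -> pd.DataFrame:
    """Jaccard-index matrix over a dict of named sets (heatmap-ready)."""
    names = list(sets)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i in names:
        for j in names:
            mat.loc[i, j] = jaccard_index(sets[i], sets[j])
    return mat
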