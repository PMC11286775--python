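"""Virtual protein-activity inference from a differential-expression signature.

A contrast's nominal p-values are Z-transformed with the sign of the fold
change, converted to rank-based normal scores, and each regulator's activity
is the weighted mean of its targets' scores: for a target t with mode of
regulation ``mor`` and confidence ``w``,

    s_t  = mor * q2_t + (1 - |mor|) * q1_t
    NES  = sum_t  (w_t / sqrt(sum w^2)) * s_t

where q2 is the signed two-tail rank score and q1 the one-tail magnitude
score.  Under an exchangeable null (random target labels) NES is standard
normal, so p-values are analytic; q-values are Benjamini-Hochberg across
regulators.  A regulator is "differentially activated" at q < fdr and
|NES| > nes_min.  Leading-edge targets and a shadow (pleiotropy) analysis
between significant regulators with overlapping regulons are attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import Regulon, RegulonSet
from .diffexp import ContrastResult, bh_fdr

logger = logging.getLogger(__name__)

_Z_CLIP = 38.0


@dataclass
class Signature:
    """Signed z-scores with their rank-based normal transforms."""

    z: pd.Series
    q1: pd.Series  # one-tail magnitude score
    q2: pd.Series  # two-tail signed score

    @property
    def features(self) -> pd.Index:
        return self.z.index


@dataclass
class ActivityResult:
    """Per-regulator enrichment statistics with shadow in-degrees."""

    table: pd.DataFrame  # columns: es, nes, pval, qval, n_targets, significant
    leading_edges: dict = field(default_factory=dict)
    shadow_edges: list = field(default_factory=list)
    fdr: float = 0.10
    nes_min: float = 5.0

    def significant_regulators(self) -> set:
        return set(self.table.index[self.table["significant"]])

    def write(self, path) -> None:
        out = self.table.copy()
        out["leading_edge"] = [
            ",".join(self.leading_edges.get(r, [])) for r in out.index
        ]
        out.to_csv(path, sep="\t", index_label="regulator")


def make_signature(contrast: ContrastResult) -> Signature:
    """Z-transform a contrast: z = sign(log2FC) * Phi^-1(1 - p/2), |z| <= 38."""
    p = contrast.pval
    lfc = contrast.log2fc
    obs = p.notna() & lfc.notna()
    if not obs.any():
        raise ValueError("contrast has no usable p-values")
    p_obs = p[obs].to_numpy(dtype=float)
    z = np.sign(lfc[obs].to_numpy()) * stats.norm.isf(np.minimum(p_obs, 1.0) / 2.0)
    z = np.clip(np.nan_to_num(z, posinf=_Z_CLIP, neginf=-_Z_CLIP), -_Z_CLIP, _Z_CLIP)
    n = len(z)
    r2 = stats.rankdata(z, method="average")
    r1 = stats.rankdata(np.abs(z), method="average")
    q2 = stats.norm.ppf(r2 / (n + 1.0))
    q1 = stats.norm.ppf(r1 / (n + 1.0))
    idx = p[obs].index
    return Signature(
        pd.Series(z, index=idx), pd.Series(q1, index=idx), pd.Series(q2, index=idx)
    )


def _target_scores(signature: Signature, regulon: Regulon):
    present = [i for i, t in enumerate(regulon.targets) if t in signature.z.index]
    if not present:
        return None
    targets = [regulon.targets[i] for i in present]
    mor = regulon.mor[present]
    w = regulon.likelihood[present]
    q2 = signature.q2.loc[targets].to_numpy()
    q1 = signature.q1.loc[targets].to_numpy()
    s = mor * q2 + (1.0 - np.abs(mor)) * q1
    return targets, s, w


def area_nes(signature: Signature, regulon: Regulon):
    """Analytic-rank enrichment of one regulon: returns (ES, NES, p).

    NES uses L2-normalised weights (unit-variance null); ES is the plain
    likelihood-weighted mean of the target scores.
    """
    scored = _target_scores(signature, regulon)
    if scored is None:
        logger.warning("regulon has no target present in the signature")
        return np.nan, np.nan, np.nan
    _, s, w = scored
    nes = float(np.sum(w / np.sqrt(np.sum(w**2)) * s))
    es = float(np.sum(w / np.sum(w) * s))
    p = 2.0 * stats.norm.sf(abs(nes))
    return es, nes, p


def leading_edge(signature: Signature, regulon: Regulon) -> list:
    """Smallest prefix of targets (by decreasing contribution) whose partial
    weighted sum reaches 90% of |NES|; ties broken lexicographically."""
    scored = _target_scores(signature, regulon)
    if scored is None:
        return []
    targets, s, w = scored
    wprime = w / np.sqrt(np.sum(w**2))
    _, nes, _ = area_nes(signature, regulon)
    if not np.isfinite(nes) or nes == 0.0:
        return []
    sign = np.sign(nes)
    contrib = wprime * s * sign
    order = sorted(range(len(targets)), key=lambda i: (-contrib[i], targets[i]))
    cum = 0.0
    edge = []
    for i in order:
        cum += contrib[i]
        edge.append(targets[i])
        if cum >= 0.9 * abs(nes):
            break
    return edge


def viper_contrast(
    signature: Signature,
    regulons: RegulonSet,
    fdr: float = 0.10,
    nes_min: float = 5.0,
    shadow: bool = True,
    overlap_min_jaccard: float = 0.1,
) -> ActivityResult:
    """Score every regulon against the signature and flag activated regulators."""
    rows = {}
    for reg, regulon in regulons.items():
        es, nes, p = area_nes(signature, regulon)
        n_present = sum(t in signature.z.index for t in regulon.targets)
        rows[reg] = (es, nes, p, n_present)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["es", "nes", "pval", "n_targets"]
    )
    table["qval"] = bh_fdr(table["pval"])
    table["significant"] = (table["qval"] < fdr) & (table["nes"].abs() > nes_min)
    result = ActivityResult(table, fdr=fdr, nes_min=nes_min)
    for reg in table.index[table["significant"]]:
        result.leading_edges[reg] = leading_edge(signature, regulons[reg])
    if shadow:
        edges, indeg = shadow_analysis(
            result, regulons, signature, overlap_min_jaccard=overlap_min_jaccard
        )
        result.shadow_edges = edges
        result.table["shadow_indegree"] = (
            pd.Series(indeg, dtype=float).reindex(table.index).fillna(0.0).astype(int)
        )
    else:
        result.table["shadow_indegree"] = 0
    return result


def _nes_without(signature: Signature, regulon: Regulon, removed: set) -> float:
    keep = [i for i, t in enumerate(regulon.targets) if t not in removed]
    if not keep:
        return 0.0
    reduced = Regulon(
        [regulon.targets[i] for i in keep], regulon.mor[keep], regulon.likelihood[keep]
    )
    _, nes, _ = area_nes(signature, reduced)
    return nes if np.isfinite(nes) else 0.0


def shadow_analysis(
    activity: ActivityResult,
    regulons: RegulonSet,
    signature: Signature,
    overlap_min_jaccard: float = 0.1,
    nes_min: float | None = None,
):
    """Pleiotropy test between significant regulators with overlapping regulons.

    For an ordered pair (A, B) with target-set Jaccard >= the threshold, B's
    NES is recomputed with the shared targets removed from its regulon.  If B
    loses significance (|NES| below nes_min or p >= 0.05) while A retains it
    in the reciprocal test, A shadows B (edge A -> B).  When both lose on
    their unique targets, the regulator with the larger original |NES|
    shadows the weaker one; an exact tie shadows mutually.  Returns the edge
    list and per-regulator in-degrees.
    """
    nes_min = activity.nes_min if nes_min is None else nes_min
    sig_regs = sorted(activity.significant_regulators())
    if len(sig_regs) < 2:
        return [], {}
    target_sets = {r: regulons[r].target_set for r in sig_regs}
    reduced_ok = {}
    for r1 in sig_regs:
        for r2 in sig_regs:
            if r1 >= r2:
                continue
            shared = target_sets[r1] & target_sets[r2]
            union = target_sets[r1] | target_sets[r2]
            if not union or len(shared) / len(union) < overlap_min_jaccard:
                continue
            for a, b in ((r1, r2), (r2, r1)):
                nes_b = _nes_without(signature, regulons[b], shared)
                p_b = 2.0 * stats.norm.sf(abs(nes_b))
                reduced_ok[(a, b)] = abs(nes_b) > nes_min and p_b < 0.05
    edges = []
    nes_abs = activity.table["nes"].abs()
    for (a, b), b_retains in reduced_ok.items():
        if b_retains:
            continue
        if reduced_ok.get((b, a), True):
            edges.append((a, b))  # A survives on unique targets, B does not
        elif nes_abs[a] >= nes_abs[b]:
            edges.append((a, b))  # both lose: the stronger shadows the weaker
    indeg = {}
    for _, b in edges:
        indeg[b] = indeg.get(b, 0) + 1
    return sorted(set(edges)), indeg
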