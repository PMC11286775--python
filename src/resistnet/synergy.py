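"""Chou-Talalay median-effect analysis of dose-response and drug combinations.

The median-effect equation relates the fraction affected fa to dose D:

    log(fa / fu) = m * log(D) - m * log(Dm),    fu = 1 - fa

so a straight-line fit of logit10(fa) on log10(D) yields the slope m
(sigmoidicity) and the median-effect dose Dm (the IC50).  For a
combination at doses (D1, D2) producing combined effect fa_c, the
combination index in the mutually exclusive form is

    CI = D1 / Dx1 + D2 / Dx2,   Dx_i = Dm_i * (fa_c / (1 - fa_c))^(1/m_i)

with CI < 1 synergism, CI = 1 additivity, CI > 1 antagonism.  The two
terms are the normalised isobologram coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FA_EPS = 1e-3


@dataclass
class DoseResponse:
    """Vehicle-normalised viability measurements for one drug."""

    drug: str
    doses: np.ndarray  # nM, > 0
    viability: np.ndarray  # fraction of vehicle, in [0, 1.2]
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if (self.doses <= 0).any():
            raise ValueError("doses must be positive")
        if (self.viability < 0).any():
            raise ValueError("viability must be non-negative")


@dataclass
class MedianEffectFit:
    drug: str
    m: float
    dm: float
    r: float
    fa: pd.DataFrame = field(default_factory=pd.DataFrame)  # per-dose fa used


@dataclass
class ComboMeasurement:
    dose1: float
    dose2: float
    viability: float


@dataclass
class SynergyResult:
    """Per combination point: equivalent single-agent doses and CI."""

    table: pd.DataFrame  # columns: dose1, dose2, fa, dx1, dx2, ci, iso1, iso2


def fraction_affected(viability: float | np.ndarray):
    """fa = 1 - viability, clamped into (0, 1) by FA_EPS for fitting.

    Viability above 1 (stimulation) clamps to fa = FA_EPS and is flagged in
    the log; negative viability is an error.
    """
    v = np.asarray(viability, dtype=float)
    if (v < 0).any():
        raise ValueError("viability below 0")
    if (v > 1).any():
        logger.info("viability above vehicle (stimulation) clamped to fa = %.0e", FA_EPS)
    fa = np.clip(1.0 - v, FA_EPS, 1.0 - FA_EPS)
    return fa if fa.shape else float(fa)


def median_effect_fit(dr: DoseResponse) -> MedianEffectFit:
    """Least-squares fit of the median-effect line.

    Replicates at a dose are averaged on the viability scale before the
    logit transform.  Requires >= 3 distinct doses; a non-positive slope
    (non-monotone data) is only warned about.
    """
    df = pd.DataFrame({"dose": dr.doses, "viability": dr.viability})
    mean_v = df.groupby("dose")["viability"].mean()
    if len(mean_v) < 3:
        raise ValueError("need at least 3 distinct doses")
    fa = fraction_affected(mean_v.to_numpy())
    x = np.log10(mean_v.index.to_numpy())
    y = np.log10(fa / (1.0 - fa))
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        logger.warning("non-positive median-effect slope for %s", dr.drug)
        dm = math.nan
    else:
        dm = 10.0 ** (-intercept / slope)
    r = float(stats.pearsonr(x, y)[0]) if len(x) > 2 else math.nan
    fa_table = pd.DataFrame({"dose": mean_v.index, "fa": fa})
    return MedianEffectFit(dr.drug, float(slope), float(dm), r, fa_table)


def ic50(fit: MedianEffectFit) -> float:
    """The dose producing fa = 0.5, i.e. the median-effect dose Dm."""
    return fit.dm


def _dx(fit: MedianEffectFit, fa: float) -> float:
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    fit_a: MedianEffectFit, fit_b: MedianEffectFit, combos: list[ComboMeasurement]
) -> SynergyResult:
    """Combination index (mutually exclusive form) per combination point.

    A zero dose for one agent reduces CI to the other agent's potency
    ratio; points whose combined fa falls outside (0, 1) after clamping are
    skipped with a log entry.
    """
    rows = []
    for combo in combos:
        fa = fraction_affected(combo.viability)
        if not (0.0 < fa < 1.0):
            logger.info("combination point with fa out of range skipped")
            continue
        dx1 = _dx(fit_a, fa)
        dx2 = _dx(fit_b, fa)
        iso1 = combo.dose1 / dx1
        iso2 = combo.dose2 / dx2
        rows.append((combo.dose1, combo.dose2, fa, dx1, dx2, iso1 + iso2, iso1, iso2))
    table = pd.DataFrame(
        rows, columns=["dose1", "dose2", "fa", "dx1", "dx2", "ci", "iso1", "iso2"]
    )
    return SynergyResult(table)
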