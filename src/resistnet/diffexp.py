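"""Per-feature differential contrasts for counts and intensities.

Counts follow a negative-binomial generalised linear model with a log link,
sample-specific size-factor offsets and one mean parameter per condition
(no intercept); the contrast is a Wald test on the difference of two
condition means.  Intensities follow a per-protein linear model on the
(quantile-normalised) log2 scale with optional empirical-Bayes variance
moderation.  Both report Benjamini-Hochberg q-values per contrast.

The NB dispersion is parameterised as Var = mu + alpha * mu^2 and is
estimated per feature by maximum likelihood with a floor at 1e-8 and a
first-order degrees-of-freedom bias correction (the analogue of dividing a
residual sum of squares by n - p rather than n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, polygamma

from .dataio import ExpressionMatrix

logger = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-8
_LN2 = math.log(2.0)


@dataclass
class ContrastResult:
    """Per-feature statistics for one pairwise condition contrast (B over A)."""

    name: tuple
    table: pd.DataFrame  # columns: log2fc, se, stat, pval, qval
    size_factors: pd.Series | None = field(default=None)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def pval(self) -> pd.Series:
        return self.table["pval"]

    @property
    def qval(self) -> pd.Series:
        return self.table["qval"]

    def significant(self, fdr: float = 0.10) -> set:
        return set(self.table.index[self.table["qval"] < fdr])

    def write(self, path) -> None:
        out = self.table.rename(
            columns={"log2fc": "log2FC", "se": "SE", "stat": "stat", "pval": "p", "qval": "q"}
        )
        out.to_csv(path, sep="\t", index_label="feature")


def filter_features(
    counts: ExpressionMatrix, min_count: int = 10, min_fraction: float = 0.2
) -> ExpressionMatrix:
    """Keep features with count > ``min_count`` in at least
    ceil(``min_fraction`` * n_samples) samples."""
    n = counts.data.shape[1]
    need = math.ceil(min_fraction * n)
    keep = (counts.data > min_count).sum(axis=1) >= need
    if not keep.any():
        logger.warning("count filter removed every feature")
    return ExpressionMatrix(counts.data.loc[keep], counts.conditions, counts.kind)


def size_factors(counts: ExpressionMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalisation factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples, computed
    over features positive in every sample.  With ``pseudo_reference`` the
    geometric mean is taken over positive counts only, rescuing matrices
    where no feature is positive everywhere.
    """
    mat = counts.data.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(mat > 0, np.log(np.maximum(mat, 1e-300)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        usable = np.isfinite(ref) & (ref > 0)
        if not usable.any():
            raise ValueError("no usable feature for pseudo-reference size factors")
        ratios = np.where(mat[usable] > 0, mat[usable] / ref[usable, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
    else:
        allpos = (mat > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no feature with all-positive counts; rerun with pseudo_reference=True"
            )
        sub = mat[allpos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        s = np.median(sub / ref[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.sample_ids, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; alpha broadcast per row."""
    inv = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1.0)
        + inv * np.log(inv / (inv + mu))
        + y * np.log(mu / (inv + mu))
    )
    return ll.sum(axis=1)


def _fit_group_means(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Newton fit of one log-mean beta per group; returns (betas, infos)."""
    n_genes = y.shape[0]
    betas = np.empty((n_genes, len(groups)))
    infos = np.empty((n_genes, len(groups)))
    for gi, idx in enumerate(groups):
        yg, sg = y[:, idx], s[idx]
        base = yg.sum(axis=1) / sg.sum()
        beta = np.log(np.maximum(base, 1e-8))
        a = alpha[:, None]
        for _ in range(50):
            mu = sg[None, :] * np.exp(beta)[:, None]
            w = 1.0 + a * mu
            score = ((yg - mu) / w).sum(axis=1)
            info = (mu / w).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5.0, 5.0)
            beta = np.clip(beta + step, -30.0, 30.0)
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = sg[None, :] * np.exp(beta)[:, None]
        betas[:, gi] = beta
        infos[:, gi] = (mu / (1.0 + a * mu)).sum(axis=1)
    return betas, infos


def _fit_dispersion(
    y: np.ndarray, mu: np.ndarray, lo: float = _ALPHA_FLOOR, hi: float = 50.0
) -> np.ndarray:
    """Vectorised golden-section MLE of alpha on the log scale, fixed means."""
    phi_lo = np.full(y.shape[0], math.log(lo))
    phi_hi = np.full(y.shape[0], math.log(hi))
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    c = phi_hi - gr * (phi_hi - phi_lo)
    d = phi_lo + gr * (phi_hi - phi_lo)
    fc = _nb_loglik(y, mu, np.exp(c)[:, None])
    fd = _nb_loglik(y, mu, np.exp(d)[:, None])
    for _ in range(60):
        take_c = fc > fd
        phi_hi = np.where(take_c, d, phi_hi)
        phi_lo = np.where(take_c, phi_lo, c)
        c = phi_hi - gr * (phi_hi - phi_lo)
        d = phi_lo + gr * (phi_hi - phi_lo)
        fc = _nb_loglik(y, mu, np.exp(c)[:, None])
        fd = _nb_loglik(y, mu, np.exp(d)[:, None])
    return np.exp((phi_lo + phi_hi) / 2.0)


def _robust_log_spread(values: np.ndarray, reference: np.ndarray) -> float:
    resid = np.log(np.maximum(values, _ALPHA_FLOOR)) - np.log(reference)
    mad = np.median(np.abs(resid - np.median(resid)))
    return float((1.4826 * mad) ** 2)


def _fit_alpha_mle(y, s, groups, gidx):
    """Alternating ML fit of per-gene dispersions with a df bias correction."""
    alpha = np.full(y.shape[0], 0.1)
    for _ in range(2):
        betas, _ = _fit_group_means(y, s, alpha, groups)
        mu = s[None, :] * np.exp(betas[:, gidx])
        alpha = _fit_dispersion(y, mu)
    n, p = y.shape[1], len(groups)
    return np.maximum(alpha * n / max(n - p, 1), _ALPHA_FLOOR)


def _shrink_dispersion(
    y: np.ndarray,
    s: np.ndarray,
    alpha_mle: np.ndarray,
    mubar: np.ndarray,
    groups: list[np.ndarray],
    gidx: np.ndarray,
    prior_var_floor: float = 0.01,
    canon: np.ndarray | None = None,
) -> np.ndarray:
    """Empirical-Bayes shrinkage of per-gene dispersions toward the
    mean-dispersion trend alpha(mu) = a0 + a1/mu.

    The between-gene prior variance on the log scale is the excess of the
    observed spread of the trend residuals over the estimator's sampling
    spread, the latter calibrated by one parametric bootstrap of the whole
    dispersion fit under the trend.  When the observed spread is
    indistinguishable from the sampling spread (within a 15% margin) the
    dispersions collapse onto the trend.
    """
    ok = alpha_mle > 1e-6
    if ok.sum() >= 10:
        design = np.column_stack([np.ones(ok.sum()), 1.0 / mubar[ok]])
        coef, *_ = np.linalg.lstsq(design, alpha_mle[ok], rcond=None)
        a0, a1 = max(coef[0], _ALPHA_FLOOR), max(coef[1], 0.0)
    else:
        a0, a1 = max(float(np.median(alpha_mle)), _ALPHA_FLOOR), 0.0
    trend = a0 + a1 / mubar
    obs_var = _robust_log_spread(alpha_mle, trend)

    # parametric bootstrap under the trend quantifies pure sampling spread;
    # columns are put in a canonical order first so the draw (hence the
    # result) is invariant to the sample order of the input matrix
    rng = np.random.default_rng(1_234_567)
    if canon is None:
        canon = np.arange(y.shape[1])
    betas_t, _ = _fit_group_means(y, s, trend, groups)
    mu_t = (s[None, :] * np.exp(betas_t[:, gidx]))[:, canon]
    s_c = s[canon]
    gidx_c = gidx[canon]
    groups_c = [np.where(gidx_c == gi)[0] for gi in range(len(groups))]
    lam = rng.gamma(1.0 / trend[:, None], mu_t * trend[:, None])
    y_boot = rng.poisson(lam).astype(float)
    alpha_boot = _fit_alpha_mle(y_boot, s_c, groups_c, gidx_c)
    boot_var = _robust_log_spread(alpha_boot, trend)

    excess = obs_var - boot_var
    prior_var = max(excess, prior_var_floor) if excess > 0.15 * boot_var else prior_var_floor
    w = prior_var / (prior_var + max(boot_var, 1e-6))
    return np.exp(
        w * np.log(np.maximum(alpha_mle, _ALPHA_FLOOR)) + (1.0 - w) * np.log(trend)
    )


def nb_contrast(
    counts: ExpressionMatrix,
    conditions: pd.Series | None = None,
    pair: tuple = None,
    factors: pd.Series | None = None,
    shrink: bool = True,
) -> ContrastResult:
    """Negative-binomial Wald contrast of condition ``pair[1]`` over ``pair[0]``.

    One mean parameter per condition (all conditions in the matrix are fit,
    which stabilises the dispersion estimate), log link, size-factor
    offsets.  Per-gene ML dispersions get a degrees-of-freedom bias
    correction and (with ``shrink``) empirical-Bayes shrinkage toward the
    mean-dispersion trend.  Features with zero counts in both contrasted
    conditions get missing statistics.
    """
    if pair is None:
        raise ValueError("pair=(A, B) is required")
    cond = counts.conditions if conditions is None else conditions
    cond = pd.Series(cond).reindex(counts.sample_ids)
    a, b = pair
    for label in (a, b):
        if (cond == label).sum() < 2:
            raise ValueError(f"condition {label!r} has fewer than 2 replicates")
    if factors is None:
        try:
            factors = size_factors(counts)
        except ValueError:
            factors = size_factors(counts, pseudo_reference=True)
    y = counts.data.to_numpy(dtype=float)
    s = factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    levels = list(dict.fromkeys(cond))
    groups = [np.where((cond == lv).to_numpy())[0] for lv in levels]
    ia, ib = levels.index(a), levels.index(b)
    gidx = _group_index(groups, y.shape[1])

    alpha = _fit_alpha_mle(y, s, groups, gidx)
    if shrink:
        mubar = np.maximum((y / s).mean(axis=1), 1e-8)
        canon = np.array(
            sorted(
                range(y.shape[1]),
                key=lambda j: (str(levels[gidx[j]]), str(counts.sample_ids[j])),
            )
        )
        alpha = _shrink_dispersion(y, s, alpha, mubar, groups, gidx, canon=canon)
    betas, infos = _fit_group_means(y, s, alpha, groups)

    delta = betas[:, ib] - betas[:, ia]
    var = 1.0 / np.maximum(infos[:, ia], 1e-12) + 1.0 / np.maximum(infos[:, ib], 1e-12)
    se = np.sqrt(var)
    stat = delta / se
    pval = 2.0 * stats.norm.sf(np.abs(stat))

    undefined = y[:, groups[ia]].sum(axis=1) + y[:, groups[ib]].sum(axis=1) == 0
    log2fc = delta / _LN2
    se2 = se / _LN2
    for arr in (log2fc, se2, stat, pval):
        arr[undefined] = np.nan
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se2,
            "stat": stat,
            "pval": pval,
            "qval": bh_fdr(pval),
        },
        index=counts.data.index,
    )
    return ContrastResult((a, b), table, factors)


def _group_index(groups: list[np.ndarray], n: int) -> np.ndarray:
    out = np.empty(n, dtype=int)
    for gi, idx in enumerate(groups):
        out[idx] = gi
    return out


def quantile_normalize(intensities: ExpressionMatrix) -> ExpressionMatrix:
    """Between-sample quantile normalisation with pairwise-missing support.

    Complete-case features define the reference distribution (the mean of
    the sorted columns); each column's non-missing values are replaced by
    the reference evaluated at their (tie-averaged) ranks.  Missing values
    stay missing.
    """
    if intensities.data.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    mat = intensities.data.to_numpy(dtype=float)
    complete = ~np.isnan(mat).any(axis=1)
    if not complete.any():
        raise ValueError("no complete-case feature to define the reference distribution")
    ref = np.sort(mat[complete], axis=0).mean(axis=1)
    m = len(ref)
    out = np.full_like(mat, np.nan)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        obs = ~np.isnan(col)
        k = obs.sum()
        if k == 0:
            continue
        ranks = stats.rankdata(col[obs], method="average")  # 1..k, ties averaged
        pos = (ranks - 1.0) * ((m - 1.0) / (k - 1.0)) if k > 1 else np.array([(m - 1) / 2.0])
        out[obs, j] = np.interp(pos, np.arange(m), ref)
    return ExpressionMatrix(
        pd.DataFrame(out, index=intensities.data.index, columns=intensities.data.columns),
        intensities.conditions,
        "intensity",
    )


def _fit_prior_var(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior
    on the log scale (prior df d0, prior variance s0^2)."""
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - polygamma(0, d / 2.0) + np.log(d / 2.0)
    ebar = e.mean()
    target = np.mean((e - ebar) ** 2 * ok.sum() / (ok.sum() - 1.0) - polygamma(1, d / 2.0))
    if target <= 0:
        return np.inf, float(np.exp(ebar))
    # invert trigamma(d0/2) = target by Newton on x = d0/2
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (tri - target) / polygamma(2, x)
        x = max(x + step, 1e-3)
        if abs(tri - target) < 1e-10:
            break
    d0 = 2.0 * x
    s0_sq = float(np.exp(ebar + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def lm_contrast(
    intensities: ExpressionMatrix,
    conditions: pd.Series | None = None,
    pair: tuple = None,
    moderate: bool = True,
) -> ContrastResult:
    """Two-group linear-model contrast on (quantile-normalised) log2 values.

    With ``moderate`` the per-protein variances are shrunk toward a common
    prior by empirical Bayes and the t test uses the augmented degrees of
    freedom; without it the test is the classical pooled-variance two-sample
    t.  Proteins observed in fewer than 2 samples per group get missing
    statistics.
    """
    if pair is None:
        raise ValueError("pair=(A, B) is required")
    cond = intensities.conditions if conditions is None else conditions
    cond = pd.Series(cond).reindex(intensities.sample_ids)
    a, b = pair
    ia = (cond == a).to_numpy()
    ib = (cond == b).to_numpy()
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("need >= 2 replicates per contrasted condition")
    mat = intensities.data.to_numpy(dtype=float)
    xa, xb = mat[:, ia], mat[:, ib]
    na = (~np.isnan(xa)).sum(axis=1).astype(float)
    nb_ = (~np.isnan(xb)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(xa, axis=1)
        mb = np.nanmean(xb, axis=1)
        ssa = np.nansum((xa - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((xb - mb[:, None]) ** 2, axis=1)
    usable = (na >= 2) & (nb_ >= 2)
    df = na + nb_ - 2.0
    s2 = np.where(usable & (df > 0), (ssa + ssb) / np.maximum(df, 1.0), np.nan)
    log2fc = np.where(usable, mb - ma, np.nan)

    if moderate:
        d0, s0_sq = _fit_prior_var(s2[usable], df[usable])
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_post = np.full_like(df, np.inf)
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            # zero-variance proteins receive the shrunken variance
            s2_post = np.where(usable & ~np.isfinite(s2_post), s0_sq, s2_post)
            df_post = d0 + df
        s2_use, df_use = s2_post, df_post
    else:
        s2_use = np.where(s2 > 0, s2, np.nan)  # zero variance -> missing
        df_use = df
    se = np.sqrt(s2_use * (1.0 / na + 1.0 / nb_))
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = log2fc / se
        pval = np.where(
            np.isfinite(stat), 2.0 * stats.t.sf(np.abs(stat), np.maximum(df_use, 1e-6)), np.nan
        )
    pval = np.where(usable, pval, np.nan)
    stat = np.where(usable, stat, np.nan)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": np.where(usable, se, np.nan),
            "stat": stat,
            "pval": pval,
            "qval": bh_fdr(pval),
        },
        index=intensities.data.index,
    )
    return ContrastResult((a, b), table)


def pca(matrix: ExpressionMatrix | pd.DataFrame, n_components: int = 2):
    """PCA of samples from a features x samples matrix.

    Features with missing values are dropped and the rest centred; scores
    are the projections of the samples onto the top right-singular vectors.
    Returns (scores DataFrame samples x PCs, variance-fraction array).
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    mat = data.to_numpy(dtype=float)
    mat = mat[~np.isnan(mat).any(axis=1)]
    x = mat.T - mat.T.mean(axis=0, keepdims=True)  # samples x features, centred per feature
    if n_components > min(x.shape):
        raise ValueError(f"n_components={n_components} exceeds min(dim)={min(x.shape)}")
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    total = (sv**2).sum()
    frac = (sv[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = pd.DataFrame(
        u[:, :n_components] * sv[:n_components],
        index=data.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, frac


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing p stay missing."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    if ((p[obs] < 0) | (p[obs] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = obs.sum()
    if m == 0:
        return out
    sub = p[obs]
    order = np.argsort(sub, kind="mergesort")
    ranked = sub[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    vals = np.empty(m)
    vals[order] = q
    out[obs] = vals
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index)
    return out
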