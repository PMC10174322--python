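"""Differential expression on two-group count matrices.

The procedure follows the classic count-based exact-test workflow:
median-of-ratios size factors, method-of-moments gene-wise dispersions
with a fitted ``alpha(mu) = a0 + a1/mu`` trend (final dispersion is the
maximum of gene-wise and trend — the conservative sharing mode), a
conditional negative-binomial exact test per gene, fold change oriented
case/reference (B/A), Benjamini-Hochberg q-values, and the screen
``p <= 0.05 and |log2FC| > 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GROUP_A, GROUP_B, CountMatrix

logger = logging.getLogger(__name__)

REG_UP = "Up"
REG_DOWN = "Down"
REG_NS = "NS"

# relative slack when comparing split probabilities to the observed one,
# guarding against ties lost to floating-point rounding
_PROB_TOL = 1e-7


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    ``s_j = median_g counts_gj / geomean_g`` over genes whose counts are
    positive in every sample (positive geometric mean).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "is undefined (consider a pseudo-reference fallback upstream)"
        )
    log_geo = np.log(arr[allpos]).mean(axis=1)
    ratios = np.log(arr[allpos]) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=mat.columns, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = estimate_size_factors(cm)
    return cm.counts.div(sf, axis=1)


@dataclass
class DispersionFit:
    alpha_gene: pd.Series    # method-of-moments estimate, floored at 0
    alpha_trend: pd.Series   # a0 + a1/mu evaluated at the gene's base mean
    alpha_final: pd.Series   # max(gene-wise, trend)
    base_mean: pd.Series
    a0: float
    a1: float


def estimate_dispersions(cm: CountMatrix, sf: pd.Series) -> DispersionFit:
    """Gene-wise method-of-moments dispersion with a 1/mu trend.

    On normalized counts, with pooled within-group variance ``w_g`` and
    base mean ``mu_g``, the raw estimate is
    ``(w_g - mu_g * mean(1/s_j)) / mu_g^2`` (the subtraction removes the
    Poisson sampling part). A trend ``a0 + a1/mu`` is fitted by
    non-negative least squares over genes with positive estimates and the
    final per-gene value is the maximum of the gene-wise estimate and the
    trend.
    """
    groups = cm.groups
    nA = (groups == GROUP_A).sum()
    nB = (groups == GROUP_B).sum()
    if nA < 2 and nB < 2:
        raise ValueError("need at least 2 replicates in one group for dispersion")
    norm = normalized_counts(cm, sf)
    mu = norm.mean(axis=1)
    # pooled within-group variance
    ss = pd.Series(0.0, index=norm.index)
    dof = 0
    for g in (GROUP_A, GROUP_B):
        cols = groups.index[groups == g]
        if len(cols) >= 2:
            sub = norm[cols]
            ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
            dof += len(cols) - 1
    w = ss / dof
    xi = mu * float((1.0 / sf).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - xi) / mu**2
    raw = raw.replace([np.inf, -np.inf], np.nan)
    alpha_gene = raw.clip(lower=0.0).fillna(0.0)
    fit_mask = (raw > 0) & (mu > 0)
    if fit_mask.sum() >= 2:
        from scipy.optimize import nnls

        A = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask].to_numpy()])
        coef, _ = nnls(A, raw[fit_mask].to_numpy())
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        logger.warning("too few genes with positive dispersion; flat trend at 0")
        a0 = a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / mu
    trend = trend.replace([np.inf, -np.inf], 0.0).fillna(0.0).clip(lower=0.0)
    final = pd.concat([alpha_gene, trend], axis=1).max(axis=1)
    return DispersionFit(alpha_gene, trend, final, mu, a0, a1)


def _log_group_pmf(k_range: np.ndarray, q: float, s: np.ndarray, alpha: float) -> np.ndarray:
    """log pmf of the summed group count at each value in k_range.

    The sum of NB counts with means ``q*s_j`` and common dispersion is
    approximated by one NB matching its mean ``q*S`` and variance
    ``q*S + alpha*q^2*sum(s_j^2)``; at ``alpha = 0`` it is exactly Poisson.
    """
    S = s.sum()
    mu = q * S
    if alpha <= 0:
        return stats.poisson.logpmf(k_range, mu)
    var_extra = alpha * q * q * (s**2).sum()
    size = mu * mu / var_extra
    return stats.nbinom.logpmf(k_range, size, size / (size + mu))


def nbinom_exact_test(
    kA: np.ndarray, kB: np.ndarray, sfA: np.ndarray, sfB: np.ndarray, alpha: float
) -> float:
    """Conditional exact NB test for one gene.

    Conditions on the total ``K = sum(kA) + sum(kB)``: every split
    ``(a, K - a)`` is weighted by the product of the two group pmfs at the
    pooled mean, and the p-value is the total weight of splits no more
    probable than the observed one, normalized by the total weight.
    """
    kA = np.asarray(kA, dtype=float)
    kB = np.asarray(kB, dtype=float)
    sfA = np.asarray(sfA, dtype=float)
    sfB = np.asarray(sfB, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    sumA, sumB = kA.sum(), kB.sum()
    K = int(round(sumA + sumB))
    if K == 0:
        return 1.0
    q = (sumA + sumB) / (sfA.sum() + sfB.sum())
    a_range = np.arange(K + 1)
    logpA = _log_group_pmf(a_range, q, sfA, alpha)
    logpB = _log_group_pmf(a_range, q, sfB, alpha)
    logp = logpA + logpB[::-1]              # log P(a, K-a)
    logp_obs = logpA[int(round(sumA))] + logpB[K - int(round(sumA))]
    keep = logp <= logp_obs + _PROB_TOL
    # normalized in probability space via log-sum-exp
    m = logp.max()
    total = np.exp(logp - m).sum()
    tail = np.exp(logp[keep] - m).sum()
    return float(min(1.0, tail / total))


def run_de(
    cm: CountMatrix,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Full per-gene differential expression table.

    Genes with zero counts in every sample are dropped (fold change
    undefined); the dropped count is logged. ``dispersions`` overrides the
    estimated per-gene values (useful when the truth is known, e.g. in
    simulation studies).

    Returns a DataFrame with columns ``mean_A, mean_B, FC, log2FC,
    pValue, qValue, Regulation`` indexed by gene id, mirroring the usual
    published table layout. FC is case/reference (B/A).
    """
    nonzero = cm.counts.sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("dropping %d all-zero genes before testing", dropped)
        cm = cm.subset_genes(cm.counts.index[nonzero])
    sf = estimate_size_factors(cm)
    if dispersions is None:
        disp = estimate_dispersions(cm, sf).alpha_final
    else:
        disp = dispersions.reindex(cm.counts.index)
        if disp.isna().any():
            raise ValueError("dispersions missing for some genes")
    norm = normalized_counts(cm, sf)
    colsA = cm.samples_in_group(GROUP_A)
    colsB = cm.samples_in_group(GROUP_B)
    meanA = norm[colsA].mean(axis=1)
    meanB = norm[colsB].mean(axis=1)
    sfA = sf[colsA].to_numpy()
    sfB = sf[colsB].to_numpy()
    kA = cm.counts[colsA].to_numpy()
    kB = cm.counts[colsB].to_numpy()
    pvals = np.array([
        nbinom_exact_test(kA[i], kB[i], sfA, sfB, float(disp.iloc[i]))
        for i in range(cm.counts.shape[0])
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = meanB / meanA
        log2fc = np.log2(fc)
    res = pd.DataFrame({
        "mean_A": meanA, "mean_B": meanB, "FC": fc, "log2FC": log2fc,
        "pValue": pvals,
    })
    res.index.name = "id"
    return call_DE(res, p_max=p_max, lfc_min=lfc_min)


def call_DE(results: pd.DataFrame, p_max: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Label each gene Up / Down / NS and attach BH q-values.

    Up means ``log2FC > lfc_min`` at ``p <= p_max``; Down is the mirrored
    call. The screen is driven by the raw p-value; the BH-adjusted q-value
    is reported alongside.
    """
    res = results.copy()
    res["qValue"] = multipletests(res["pValue"].to_numpy(), method="fdr_bh")[1]
    lfc = res["log2FC"]
    sig = res["pValue"] <= p_max
    res["Regulation"] = np.select(
        [sig & (lfc > lfc_min), sig & (lfc < -lfc_min)],
        [REG_UP, REG_DOWN],
        default=REG_NS,
    )
    return res


def de_counts(results: pd.DataFrame) -> dict[str, int]:
    c = results["Regulation"].value_counts()
    return {k: int(c.get(k, 0)) for k in (REG_UP, REG_DOWN, REG_NS)}
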