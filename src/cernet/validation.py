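"""Wet-lab-facing evaluation: 2^-ddCt relative quantification and ROC/AUC.

The ROC area is the normalized rank-sum (Mann-Whitney) statistic with
midranks for ties — the probability that a random positive outranks a
random negative, counting ties as half. Confidence intervals use the
DeLong structural-components variance by default, with a seeded bootstrap
alternative (and fallback when the DeLong variance degenerates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ ddCt

def ddct(table: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample relative expression by the 2^-ddCt method.

    ``table`` columns: ``sample_id, group, target_ct, reference_ct`` (an
    optional ``replicate`` column marks technical replicates, which are
    averaged on the Ct scale first). dCt = target - reference per sample;
    ddCt subtracts the calibrator group's mean dCt; relative expression is
    ``2^-ddCt``. Rows with a missing reference Ct are dropped with a
    logged warning.
    """
    required = {"sample_id", "group", "target_ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    tbl = table.copy()
    bad = tbl["reference_ct"].isna() | tbl["target_ct"].isna()
    if bad.any():
        logger.warning("dropping %d Ct rows with missing measurements", int(bad.sum()))
        tbl = tbl[~bad]
    per_sample = tbl.groupby(["sample_id", "group"], sort=False, as_index=False)[
        ["target_ct", "reference_ct"]
    ].mean()
    if not (per_sample["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    per_sample["delta_ct"] = per_sample["target_ct"] - per_sample["reference_ct"]
    calib = per_sample.loc[per_sample["group"] == calibrator_group, "delta_ct"].mean()
    per_sample["ddct"] = per_sample["delta_ct"] - calib
    per_sample["rel_expr"] = np.power(2.0, -per_sample["ddct"])
    return per_sample


# ------------------------------------------------------------------- ROC

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    n_pos: int
    n_neg: int
    se: float
    method: str


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """AUC as the midrank Mann-Whitney statistic."""
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: len(pos)].sum()
    u = rank_sum_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong structural-components standard error of the AUC."""
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)          # per-positive components
    v01 = cmp.mean(axis=0)          # per-negative components
    var = (np.var(v10, ddof=1) / len(pos)) + (np.var(v01, ddof=1) / len(neg))
    return float(np.sqrt(var))


def _bootstrap_se(pos, neg, level, rng, n_boot=2000):
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        q = rng.choice(neg, size=len(neg), replace=True)
        cmp = (p[:, None] > q[None, :]).mean() + 0.5 * (p[:, None] == q[None, :]).mean()
        aucs[b] = cmp
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(aucs.std(ddof=1)), float(lo), float(hi)


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong",
           seed: int = 0, n_boot: int = 2000) -> ROCResult:
    """AUC with a confidence interval and a test against AUC = 0.5.

    ``method='delong'`` (default) uses the structural-components variance
    with a normal interval truncated to [0, 1]; a degenerate variance
    (e.g. perfect separation) falls back to the bootstrap, logged.
    ``method='bootstrap'`` uses seeded percentile resampling throughout.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 samples per class for a CI")
    auc = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    used = method
    if method == "delong":
        se = _delong_se(pos, neg)
        if se == 0.0:
            logger.info("degenerate DeLong variance; bootstrap fallback")
            se, lo, hi = _bootstrap_se(pos, neg, level, rng, n_boot)
            used = "bootstrap-fallback"
        else:
            z = stats.norm.ppf(1 - (1 - level) / 2)
            lo, hi = auc - z * se, auc + z * se
    elif method == "bootstrap":
        se, lo, hi = _bootstrap_se(pos, neg, level, rng, n_boot)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = max(0.0, min(lo, auc))
    hi = min(1.0, max(hi, auc))
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi, p_vs_half=float(min(1.0, p)),
                     n_pos=len(pos), n_neg=len(neg), se=se, method=used)


def roc_report(markers: dict[str, tuple], level: float = 0.95) -> pd.DataFrame:
    """One-row-per-marker AUC report: ``{name: (scores, labels)}`` in."""
    rows = []
    for name, (scores, labels) in markers.items():
        res = auc_ci(scores, labels, level=level)
        rows.append({
            "marker": name, "AUC": res.auc,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_vs_half": res.p_vs_half, "n_pos": res.n_pos, "n_neg": res.n_neg,
        })
    return pd.DataFrame(rows)
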