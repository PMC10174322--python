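"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} is empty")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(overlap >= k).

    ``K`` genes of an ``N``-gene universe belong to the set; ``n`` genes
    are drawn (the query list); ``k`` of them land in the set.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible configuration k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving on ties."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


ENRICH_COLUMNS = ["term_id", "description", "k", "K", "n", "N", "p", "fdr", "top"]


def enrich(
    gene_list,
    gene_sets: list[GeneSet],
    universe,
    top_k: int = 30,
) -> pd.DataFrame:
    """Over-representation table for a gene list against a GMT collection.

    The universe is the background population (conventionally, all genes
    tested in the run); query ids outside it are dropped with a logged
    count, and set members are intersected with it. One row per set with
    at least one hit, sorted by p ascending (ties: larger overlap, then
    term id); the ``top`` flag marks the first ``top_k`` rows. Both the
    raw p and the BH FDR are reported.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(gene_list)
    outside = len(query - universe)
    if outside:
        logger.info("dropping %d query genes outside the universe", outside)
    query &= universe
    N = len(universe)
    n = len(query)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        k = len(members & query)
        if k < 1:
            continue
        rows.append({
            "term_id": gs.term_id, "description": gs.description,
            "k": k, "K": len(members), "n": n, "N": N,
            "p": hypergeom_p(k, len(members), n, N),
        })
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-2])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(by=["p", "k", "term_id"],
                            ascending=[True, False, True],
                            kind="mergesort", ignore_index=True)
        df["top"] = np.arange(len(df)) < top_k
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["top"] = pd.Series(dtype=bool)
    return df
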