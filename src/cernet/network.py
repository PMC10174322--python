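"""ceRNA (lncRNA-miRNA-mRNA) network assembly.

The pipeline's central logic: sign-constrained Pearson coexpression
screens between RNA layers, a shared-MRE ceRNA score per candidate
lncRNA-mRNA pair (the MuTaME reading: shared-miRNA fraction, site
density, site distribution evenness and shared-site proportion, combined
on the log scale and min-max scaled to [0, 100]), an optional
hypergeometric co-targeting test, intersection of all evidence into
triplets, top-N axis extraction and Cytoscape-loadable export.

Correlations are computed on ``log2(normalized count + 1)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .diffexp import estimate_size_factors, normalized_counts

logger = logging.getLogger(__name__)

NEGATIVE = "negative"
POSITIVE = "positive"

SITE_WIDTH = 7       # nominal seed-site footprint used by the density score
_LOG_FLOOR = 1e-12

EDGE_MI_LNC = "mi_lnc"
EDGE_MI_MRNA = "mi_mrna"
EDGE_LNC_MRNA = "lnc_mrna"


@dataclass(frozen=True)
class ScreenThresholds:
    """Screening thresholds for edges and pairs."""

    r_min: float = 0.7
    p_max: float = 0.05
    score_min: float = 50.0
    require_hyper: bool = False
    hyper_p_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must lie in (0, 1]")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")


def log_expression(cm: CountMatrix, sf=None) -> pd.DataFrame:
    """log2(normalized count + 1) matrix for correlation screens."""
    return np.log2(normalized_counts(cm, sf if sf is not None else
                                     estimate_size_factors(cm)) + 1.0)


def pearson_edges(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    sign: str,
    th: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """All cross-layer Pearson edges passing the sign and threshold screen.

    ``X`` and ``Y`` are features x samples on the log scale with identical
    sample columns. The p-value is the two-sided t test on
    ``t = r * sqrt((n-2) / (1-r^2))`` with ``n - 2`` degrees of freedom.
    Zero-variance features are skipped (count logged). Returns a DataFrame
    with columns ``id_a, id_b, r, p, n`` where ``id_a`` indexes ``X``.
    """
    th = th or ScreenThresholds()
    if sign not in (NEGATIVE, POSITIVE):
        raise ValueError("sign must be 'negative' or 'positive'")
    if list(X.columns) != list(Y.columns):
        raise ValueError("sample columns differ between layers")
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation screen")
    Xa = X.to_numpy(dtype=float)
    Ya = Y.to_numpy(dtype=float)
    sx = Xa.std(axis=1)
    sy = Ya.std(axis=1)
    okx = sx > 0
    oky = sy > 0
    skipped = int((~okx).sum() + (~oky).sum())
    if skipped:
        logger.info("skipping %d zero-variance features in correlation screen", skipped)
    Zx = (Xa[okx] - Xa[okx].mean(axis=1, keepdims=True)) / sx[okx][:, None]
    Zy = (Ya[oky] - Ya[oky].mean(axis=1, keepdims=True)) / sy[oky][:, None]
    R = np.clip(Zx @ Zy.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = np.where(np.abs(R) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df=n - 2))
    if sign == NEGATIVE:
        mask = (R <= -th.r_min) & (P <= th.p_max)
    else:
        mask = (R >= th.r_min) & (P <= th.p_max)
    ia, ib = np.nonzero(mask)
    ids_a = X.index[okx]
    ids_b = Y.index[oky]
    return pd.DataFrame({
        "id_a": ids_a[ia],
        "id_b": ids_b[ib],
        "r": R[ia, ib],
        "p": P[ia, ib],
        "n": n,
    })


# ------------------------------------------------------------- ceRNA score

def _site_stats(starts: list[int], tx_len: int) -> tuple[float, float]:
    """(density d, evenness e) of one miRNA's sites on one transcript."""
    k = len(starts)
    if k < 2:
        return 1.0 / tx_len, 1.0
    starts = sorted(starts)
    span = starts[-1] - starts[0] + SITE_WIDTH
    gaps = np.diff(starts)
    return k / span, float(gaps.min() / gaps.mean())


def mutame_score(
    pairs: list[tuple[str, str]],
    hits: pd.DataFrame,
    de_mirnas: set[str],
    tx_len: dict[str, int],
) -> pd.DataFrame:
    """Shared-MRE ceRNA score for candidate lncRNA-mRNA pairs.

    Per pair (A = lncRNA, B = mRNA) with shared miRNA set M (miRNAs with
    at least one predicted site on both):

    * S1 — shared fraction: ``|M|^2 / (|M_A| * |M_B|)``
    * S2 — site density: mean over shared miRNAs and both transcripts of
      ``n_sites / (span + 7)`` (single site: ``1 / transcript length``)
    * S3 — site distribution evenness: mean of ``min(gap) / mean(gap)``
      (single gap or single site: 1)
    * S4 — shared-site proportion: shared-miRNA hits over all DE-miRNA
      hits on the pair
    * ``raw = ln S1 + ln S2 + ln S3 + ln S4`` (components floored at
      1e-12), min-max scaled to [0, 100] across all evaluated pairs.

    Pairs with an empty M are excluded. ``hits`` is the MRE table
    (columns mirna, transcript, start) restricted here to ``de_mirnas``.
    """
    hits = hits[hits["mirna"].isin(de_mirnas)]
    by_tx: dict[str, dict[str, list[int]]] = {}
    for (tx, mi), sub in hits.groupby(["transcript", "mirna"], sort=False):
        by_tx.setdefault(tx, {})[mi] = sorted(int(s) for s in sub["start"])
    rows = []
    for lnc_id, mrna_id in pairs:
        hits_a = by_tx.get(lnc_id, {})
        hits_b = by_tx.get(mrna_id, {})
        shared = sorted(set(hits_a) & set(hits_b))
        if not shared:
            continue
        s1 = len(shared) ** 2 / (len(hits_a) * len(hits_b))
        dsum = esum = 0.0
        n_shared_sites = 0
        for mi in shared:
            dA, eA = _site_stats(hits_a[mi], tx_len[lnc_id])
            dB, eB = _site_stats(hits_b[mi], tx_len[mrna_id])
            dsum += (dA + dB) / 2.0
            esum += (eA + eB) / 2.0
            n_shared_sites += len(hits_a[mi]) + len(hits_b[mi])
        s2 = dsum / len(shared)
        s3 = esum / len(shared)
        n_total = sum(len(v) for v in hits_a.values()) + sum(len(v) for v in hits_b.values())
        s4 = n_shared_sites / n_total
        raw = sum(np.log(max(s, _LOG_FLOOR)) for s in (s1, s2, s3, s4))
        rows.append({
            "lnc_id": lnc_id, "mrna_id": mrna_id,
            "shared_mirnas": ",".join(shared),
            "n_shared": len(shared), "n_mi_lnc": len(hits_a), "n_mi_mrna": len(hits_b),
            "s1": s1, "s2": s2, "s3": s3, "s4": s4, "raw": raw,
        })
    out = pd.DataFrame(rows, columns=[
        "lnc_id", "mrna_id", "shared_mirnas", "n_shared", "n_mi_lnc", "n_mi_mrna",
        "s1", "s2", "s3", "s4", "raw",
    ])
    if len(out):
        lo, hi = out["raw"].min(), out["raw"].max()
        if hi > lo:
            out["score"] = 100.0 * (out["raw"] - lo) / (hi - lo)
        else:
            out["score"] = 100.0
    else:
        out["score"] = pd.Series(dtype=float)
    return out


def shared_mirna_test(n_shared: int, n_mi_lnc: int, n_mi_mrna: int, n_universe: int) -> float:
    """Hypergeometric p for observing >= n_shared co-targeting miRNAs.

    Population = all DE miRNAs, successes = miRNAs targeting the lncRNA,
    draws = miRNAs targeting the mRNA.
    """
    if max(n_mi_lnc, n_mi_mrna) > n_universe or n_shared > min(n_mi_lnc, n_mi_mrna):
        raise ValueError("inconsistent set sizes for the co-targeting test")
    if n_shared == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_shared - 1, n_universe, n_mi_lnc, n_mi_mrna))


def add_hyper_p(scored: pd.DataFrame, n_universe: int) -> pd.DataFrame:
    scored = scored.copy()
    scored["hyper_p"] = [
        shared_mirna_test(int(r.n_shared), int(r.n_mi_lnc), int(r.n_mi_mrna), n_universe)
        for r in scored.itertuples(index=False)
    ]
    return scored


# -------------------------------------------------------------- assembly

TRIPLET_COLUMNS = [
    "lnc_id", "mirna_id", "mrna_id",
    "r_mi_lnc", "r_mi_mrna", "r_lnc_mrna", "score",
]


def assemble_network(
    neg_mi_lnc: pd.DataFrame,
    neg_mi_mrna: pd.DataFrame,
    pos_lnc_mrna: pd.DataFrame,
    scored_pairs: pd.DataFrame,
    th: ScreenThresholds | None = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Intersect the three edge screens with the ceRNA scores.

    A triplet (L, k, G) is emitted iff the miRNA k is negatively
    correlated with both L and G, L and G are positively correlated, k is
    in the shared-miRNA set of the scored (L, G) pair, and the pair passes
    ``score_min`` (and the co-targeting test when required). Every emitted
    triplet is re-checked against the sign pattern (-, -, +).
    """
    th = th or ScreenThresholds()
    e_mi_lnc = {(r.id_a, r.id_b): r.r for r in neg_mi_lnc.itertuples(index=False)}
    e_mi_mrna = {(r.id_a, r.id_b): r.r for r in neg_mi_mrna.itertuples(index=False)}
    e_lnc_mrna = {(r.id_a, r.id_b): r.r for r in pos_lnc_mrna.itertuples(index=False)}
    rows = []
    for pr in scored_pairs.itertuples(index=False):
        if pr.score < th.score_min:
            continue
        if th.require_hyper and getattr(pr, "hyper_p", 1.0) > th.hyper_p_max:
            continue
        if (pr.lnc_id, pr.mrna_id) not in e_lnc_mrna:
            continue
        for mi in pr.shared_mirnas.split(","):
            if (mi, pr.lnc_id) in e_mi_lnc and (mi, pr.mrna_id) in e_mi_mrna:
                r1 = e_mi_lnc[(mi, pr.lnc_id)]
                r2 = e_mi_mrna[(mi, pr.mrna_id)]
                r3 = e_lnc_mrna[(pr.lnc_id, pr.mrna_id)]
                assert r1 < 0 and r2 < 0 and r3 > 0, "sign pattern violated"
                rows.append({
                    "lnc_id": pr.lnc_id, "mirna_id": mi, "mrna_id": pr.mrna_id,
                    "r_mi_lnc": r1, "r_mi_mrna": r2, "r_lnc_mrna": r3,
                    "score": pr.score,
                })
    triplets = pd.DataFrame(rows, columns=TRIPLET_COLUMNS)
    triplets = triplets.sort_values(["lnc_id", "mirna_id", "mrna_id"],
                                    ignore_index=True)
    net = nx.Graph()
    for t in triplets.itertuples(index=False):
        net.add_node(t.lnc_id, kind="lnc")
        net.add_node(t.mirna_id, kind="mirna")
        net.add_node(t.mrna_id, kind="mrna")
        net.add_edge(t.mirna_id, t.lnc_id, relation=EDGE_MI_LNC, r=t.r_mi_lnc)
        net.add_edge(t.mirna_id, t.mrna_id, relation=EDGE_MI_MRNA, r=t.r_mi_mrna)
        net.add_edge(t.lnc_id, t.mrna_id, relation=EDGE_LNC_MRNA, r=t.r_lnc_mrna,
                     score=t.score)
    return triplets, net


def top_axes(triplets: pd.DataFrame, n: int = 200) -> pd.DataFrame:
    """First N axes by (pair score desc, |r(L,G)| desc, (L,k,G) lexicographic)."""
    if n <= 0:
        raise ValueError("n must be positive")
    df = triplets.copy()
    df["_abs_r"] = df["r_lnc_mrna"].abs()
    df = df.sort_values(
        by=["score", "_abs_r", "lnc_id", "mirna_id", "mrna_id"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
    ).drop(columns="_abs_r")
    return df.head(n).reset_index(drop=True)


def export_network(
    net: nx.Graph,
    outdir: str | os.PathLike,
    node_attrs: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write SIF plus node/edge attribute TSVs (Cytoscape-loadable).

    ``node_attrs`` may carry per-id ``log2FC`` and ``Regulation`` columns
    (e.g. a concatenated DE table) to decorate the node table. Output is
    byte-stable for a fixed network.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in
             [("sif", "network.sif"), ("nodes", "nodes.tsv"), ("edges", "edges.tsv")]}
    edges = sorted(
        (d["relation"], a, b, d) for a, b, d in net.edges(data=True)
    )
    with open(paths["sif"], "w") as fh:
        for rel, a, b, _ in edges:
            fh.write(f"{a}\t{rel}\t{b}\n")
    node_rows = []
    for node in sorted(net.nodes):
        row = {"id": node, "type": net.nodes[node].get("kind", "")}
        if node_attrs is not None and node in node_attrs.index:
            row["log2FC"] = node_attrs.loc[node].get("log2FC", "")
            row["regulation"] = node_attrs.loc[node].get("Regulation", "")
        else:
            row["log2FC"] = ""
            row["regulation"] = ""
        node_rows.append(row)
    pd.DataFrame(node_rows, columns=["id", "type", "log2FC", "regulation"]).to_csv(
        paths["nodes"], sep="\t", index=False)
    edge_rows = [
        {"source": a, "relation": rel, "target": b,
         "r": d.get("r", ""), "score": d.get("score", "")}
        for rel, a, b, d in edges
    ]
    pd.DataFrame(edge_rows, columns=["source", "relation", "target", "r", "score"]).to_csv(
        paths["edges"], sep="\t", index=False)
    return paths


# ------------------------------------------------------------ full pipeline

def run_network(
    counts: dict[str, CountMatrix],
    hits: pd.DataFrame,
    th: ScreenThresholds | None = None,
    de_mirnas: set[str] | None = None,
    restrict: dict[str, set[str]] | None = None,
    tx_len: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, nx.Graph, pd.DataFrame]:
    """End-to-end network inference from count layers and an MRE table.

    ``restrict`` optionally limits each layer to a feature subset (e.g.
    the DE features, as the original workflow does). ``de_mirnas``
    defaults to every miRNA in the (restricted) miRNA layer. Candidate
    lncRNA-mRNA pairs for the ceRNA score are all pairs with at least one
    shared predicted miRNA. ``tx_len`` supplies true transcript lengths
    for the density score; without it the furthest hit end is used as a
    conservative stand-in. Returns (triplets, graph, scored pairs).
    """
    th = th or ScreenThresholds()
    expr = {}
    for layer, cm in counts.items():
        X = log_expression(cm)
        if restrict and layer in restrict:
            X = X.loc[[g for g in X.index if g in restrict[layer]]]
        expr[layer] = X
    if de_mirnas is None:
        de_mirnas = set(expr["mirna"].index)
    neg_mi_lnc = pearson_edges(expr["mirna"], expr["lnc"], NEGATIVE, th)
    neg_mi_mrna = pearson_edges(expr["mirna"], expr["mrna"], NEGATIVE, th)
    pos_lnc_mrna = pearson_edges(expr["lnc"], expr["mrna"], POSITIVE, th)
    rel_hits = hits[hits["mirna"].isin(de_mirnas)
                    & (hits["transcript"].isin(expr["lnc"].index)
                       | hits["transcript"].isin(expr["mrna"].index))]
    by_tx = rel_hits.groupby("transcript")["mirna"].agg(set)
    lnc_with_hits = [g for g in expr["lnc"].index if g in by_tx.index]
    mrna_with_hits = [g for g in expr["mrna"].index if g in by_tx.index]
    pairs = [
        (l, g) for l in lnc_with_hits for g in mrna_with_hits
        if by_tx[l] & by_tx[g]
    ]
    if tx_len is None:
        # conservative stand-in when no FASTA is at hand
        tx_len = {tx: int(sub["end"].max()) for tx, sub in rel_hits.groupby("transcript")}
    scored = mutame_score(pairs, rel_hits, de_mirnas, tx_len)
    if len(scored):
        scored = add_hyper_p(scored, len(de_mirnas))
    triplets, net = assemble_network(neg_mi_lnc, neg_mi_mrna, pos_lnc_mrna, scored, th)
    return triplets, net, scored
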