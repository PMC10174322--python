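"""lncRNA transcript catalog: filtering, orientation classes, FPKM, PCA.

Coordinates are 1-based closed genomic intervals (GTF convention); two
records overlap when they share a chromosome and their intervals intersect
in at least one base.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

SENSE = "sense"
ANTISENSE = "antisense"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: locus, exon count, biotype and spliced length.

    ``annotated`` marks transcripts present in a reference annotation (as
    opposed to newly assembled candidates); known annotated lncRNAs keep
    their single-exon members, the exon filter applies to novel candidates
    only.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_count: int
    biotype: str            # lncRNA_candidate | protein_coding | other
    length: int             # spliced length, nt
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.id}")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.id}")
        if self.length < 1 or self.exon_count < 1:
            raise ValueError(f"invalid length/exon_count for {self.id}")


@dataclass
class CatalogSummary:
    n_total: int = 0
    n_sense: int = 0
    n_antisense: int = 0
    n_unclassified: int = 0
    length_histogram: dict[str, int] = field(default_factory=dict)
    chromosome_counts: dict[str, int] = field(default_factory=dict)
    exon_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def antisense_percent(self) -> float:
        classified = self.n_sense + self.n_antisense
        return 100.0 * self.n_antisense / classified if classified else float("nan")


def filter_lncRNA_candidates(
    records: list[TranscriptRecord], min_len: int = 201, min_exons: int = 2
) -> list[TranscriptRecord]:
    """Select lncRNA candidates: length over 200 nt and, for unannotated
    candidates, at least ``min_exons`` exons (annotated known lncRNAs keep
    single-exon entries)."""
    out = []
    for r in records:
        if r.biotype != "lncRNA_candidate":
            continue
        if r.length < min_len:
            continue
        if not r.annotated and r.exon_count < min_exons:
            continue
        out.append(r)
    return out


def _overlap(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Intersection length of two 1-based closed intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def classify_orientation(
    lncs: list[TranscriptRecord], coding: list[TranscriptRecord]
) -> dict[str, str]:
    """Sense/antisense/unclassified call per lncRNA against coding loci.

    A lncRNA overlapping a coding transcript on the same strand is sense,
    on the opposite strand antisense, with no overlap unclassified. When
    several coding transcripts overlap, the winner is chosen by largest
    overlap, then antisense over sense, then lowest coding id.
    """
    by_chrom: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for c in coding:
        by_chrom[c.chrom].append(c)
    calls: dict[str, str] = {}
    for lnc in lncs:
        best = None  # (overlap, is_antisense, -id) maximized
        for c in by_chrom.get(lnc.chrom, ()):
            ov = _overlap(lnc, c)
            if ov == 0:
                continue
            anti = c.strand != lnc.strand
            key = (ov, anti)
            if best is None or key > best[0] or (key == best[0] and c.id < best[1]):
                best = (key, c.id)
        if best is None:
            calls[lnc.id] = UNCLASSIFIED
        else:
            calls[lnc.id] = ANTISENSE if best[0][1] else SENSE
    return calls


def default_length_bins(max_length: int) -> list[tuple[int, int]]:
    """[200, 2000), then 2000-wide bins up to max_length."""
    bins = [(200, 2000)]
    lo = 2000
    while lo <= max_length:
        bins.append((lo, lo + 2000))
        lo += 2000
    return bins


def summarize_catalog(
    records: list[TranscriptRecord],
    orientation: dict[str, str] | None = None,
    length_bins: list[tuple[int, int]] | None = None,
) -> CatalogSummary:
    """Census of a transcript catalog: orientation, lengths, chromosomes, exons."""
    summary = CatalogSummary(n_total=len(records))
    if orientation is not None:
        tally = Counter(orientation.get(r.id, UNCLASSIFIED) for r in records)
        summary.n_sense = tally[SENSE]
        summary.n_antisense = tally[ANTISENSE]
        summary.n_unclassified = tally[UNCLASSIFIED]
    else:
        summary.n_unclassified = len(records)
    if records:
        if length_bins is None:
            length_bins = default_length_bins(max(r.length for r in records))
        hist = {}
        for lo, hi in length_bins:
            label = f"{lo}-{hi}"
            hist[label] = sum(1 for r in records if lo <= r.length < hi)
        below = sum(1 for r in records if r.length < length_bins[0][0])
        above = sum(1 for r in records if r.length >= length_bins[-1][1])
        if below:
            hist[f"<{length_bins[0][0]}"] = below
        if above:
            hist[f">={length_bins[-1][1]}"] = above
        summary.length_histogram = hist
    summary.chromosome_counts = dict(sorted(Counter(r.chrom for r in records).items()))
    summary.exon_histogram = dict(sorted(Counter(r.exon_count for r in records).items()))
    return summary


def compute_fpkm(counts: CountMatrix | pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM_gj = counts_gj * 1e9 / (length_g * column_sum_j)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lengths = pd.Series(lengths).reindex(mat.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    colsum = mat.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("zero library size in at least one sample")
    return mat.astype(float).mul(1e9).div(lengths, axis=0).div(colsum, axis=1)


def log10_fpkm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """log10(FPKM + 1), the usual scale for expression-distribution plots."""
    return np.log10(fpkm + 1.0)


def pca_samples(logexpr: pd.DataFrame, n_components: int | None = None):
    """Sample-level PCA of a genes x samples log-expression matrix.

    Gene-centered SVD; sample coordinates are the right singular vectors
    scaled by the singular values and the variance fractions are the
    normalized squared singular values. Each component's sign is fixed by
    making its largest-magnitude gene loading positive.

    Returns ``(coords, var_frac)``: coords is samples x components.
    """
    if logexpr.shape[0] < 2 or logexpr.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    X = logexpr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        warnings.warn("constant expression matrix: PCA coordinates are all zero")
        k = n_components or min(X.shape)
        coords = pd.DataFrame(
            np.zeros((X.shape[1], k)), index=logexpr.columns,
            columns=[f"PC{i+1}" for i in range(k)],
        )
        return coords, np.zeros(k)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # orient: largest-magnitude loading of each component positive
    for i in range(len(s)):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i, :] *= -1
    keep = len(s) if n_components is None else min(n_components, len(s))
    var = s**2
    var_frac = (var / var.sum())[:keep]
    coords = pd.DataFrame(
        (Vt[:keep, :] * s[:keep, None]).T,
        index=logexpr.columns,
        columns=[f"PC{i+1}" for i in range(keep)],
    )
    return coords, var_frac
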