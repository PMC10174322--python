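"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
counts TSV
    Genes in rows, samples in columns. The first data row is the reserved
    id ``#group`` carrying the per-sample group label (``A`` reference,
    ``B`` case); all remaining rows are integer counts.
FASTA
    Sequences via Biopython. RNA alphabet (A/C/G/U) in memory; ``T`` on
    disk is accepted and converted to ``U``.
annotation TSV
    One transcript record per line with columns
    ``id chrom strand start end exon_count biotype length annotated``.
GMT
    One gene set per line: term id, description, then member ids,
    tab-separated.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix

GROUP_ROW_ID = "#group"


# ---------------------------------------------------------------- counts TSV

def write_counts_tsv(cm: CountMatrix, path: str | os.PathLike) -> None:
    """Write a CountMatrix with its group labels as the first data row."""
    header = pd.DataFrame(
        [list(cm.groups.values)], index=[GROUP_ROW_ID], columns=cm.counts.columns
    )
    body = pd.concat([header, cm.counts.astype(object)])
    body.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | os.PathLike) -> CountMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if GROUP_ROW_ID not in raw.index:
        raise ValueError(f"counts file {path} lacks the '{GROUP_ROW_ID}' label row")
    groups = pd.Series(raw.loc[GROUP_ROW_ID], name="group")
    counts = raw.drop(index=GROUP_ROW_ID).astype(int)
    counts.index.name = "gene_id"
    return CountMatrix(counts, groups)


# -------------------------------------------------------------------- FASTA

def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read sequences, upper-cased and DNA->RNA converted (T becomes U)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("T", "U")
    return out


# --------------------------------------------------------------- annotation

ANNOTATION_COLUMNS = [
    "id", "chrom", "strand", "start", "end", "exon_count", "biotype",
    "length", "annotated",
]


def write_annotation_tsv(records: Iterable, path: str | os.PathLike) -> None:
    rows = [
        {
            "id": r.id, "chrom": r.chrom, "strand": r.strand,
            "start": r.start, "end": r.end, "exon_count": r.exon_count,
            "biotype": r.biotype, "length": r.length,
            "annotated": int(r.annotated),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | os.PathLike) -> list:
    from .catalog import TranscriptRecord

    df = pd.read_csv(path, sep="\t")
    return [
        TranscriptRecord(
            id=str(r.id), chrom=str(r.chrom), strand=str(r.strand),
            start=int(r.start), end=int(r.end), exon_count=int(r.exon_count),
            biotype=str(r.biotype), length=int(r.length),
            annotated=bool(r.annotated),
        )
        for r in df.itertuples(index=False)
    ]


# --------------------------------------------------------------------- GMT

def read_gmt(path: str | os.PathLike) -> list:
    from .enrichment import GeneSet

    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets.append(GeneSet(term_id=parts[0], description=parts[1],
                                members=frozenset(p for p in parts[2:] if p)))
    return sets


def write_gmt(sets: Iterable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.description, *sorted(gs.members)]) + "\n")
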