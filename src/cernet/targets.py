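"""miRNA response element (MRE) prediction on transcript sequences.

Seed-and-extend strategy: scan the transcript (5'->3') for windows whose
3' half pairs the miRNA seed (positions 2-8 from the miRNA 5' end,
Watson-Crick with at most one G:U wobble), then run a local
affine-gap alignment of the full miRNA against a window around the seed
match, with substitution scores multiplied inside the seed region
(5'-weighting). A hit is emitted when the alignment score reaches the
threshold.

Coordinate conventions: transcript positions are 0-based half-open
internally. A candidate/site start ``p`` refers to the 8-nt window
``[p, p+8)`` whose last base faces miRNA position 1, i.e. the transcript
base at ``p + 8 - k`` faces miRNA position ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEED_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
_WOBBLE = {("G", "U"), ("U", "G")}   # (miRNA base, target base)
_ALPHABET = set("ACGU")


def _check_rna(seq: str, what: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")


def _pairs_wc(m: str, t: str) -> bool:
    return _COMP[m] == t


def _pairs(m: str, t: str) -> bool:
    return _COMP[m] == t or (m, t) in _WOBBLE


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme of the seed-and-extend aligner.

    Defaults mirror the published defaults of the classic ex-vivo target
    scanner this module re-implements: +5 Watson-Crick, +1 G:U, -3
    mismatch, affine gaps -9/-4, a 4x weight on miRNA positions 2-8 and an
    emission threshold of 140.
    """

    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0      # cost of the first residue of a gap
    gap_extend: float = -4.0    # each further residue
    seed_span: tuple[int, int] = (2, 8)   # miRNA positions, 1-based inclusive
    seed_weight: float = 4.0
    score_threshold: float = 140.0
    max_wobble_in_seed: int = 1
    allow_seed_gaps: bool = False
    flank: int = 5              # window flank; window width = len(miRNA) + 2*flank

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")
        lo, hi = self.seed_span
        if not 1 <= lo <= hi:
            raise ValueError("invalid seed_span")

    def in_seed(self, mirna_pos: int) -> bool:
        return self.seed_span[0] <= mirna_pos <= self.seed_span[1]


@dataclass(frozen=True)
class MREHit:
    mirna_id: str
    transcript_id: str
    start: int          # 0-based half-open on the transcript
    end: int
    score: float
    seed_class: str
    aligned_pairs: tuple[str, str, str] = field(default=("", "", ""), compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid hit coordinates")


def seed_scan(mirna: str, transcript: str, params: AlignmentParams | None = None):
    """Candidate seed-match positions with their site class.

    Returns a list of ``(start, seed_class)`` for every 8-nt window whose
    positions facing miRNA 2-8 all pair (Watson-Crick or G:U) with at most
    ``max_wobble_in_seed`` wobbles. The class is the strongest canonical
    definition met on Watson-Crick terms (8mer > 7mer-m8 > 7mer-A1 >
    6mer); candidates pairing only through a wobble in positions 2-7 are
    reported as 6mer.
    """
    params = params or AlignmentParams()
    mirna = mirna.upper().replace("T", "U")
    transcript = transcript.upper().replace("T", "U")
    _check_rna(mirna, "miRNA")
    _check_rna(transcript, "transcript")
    if len(mirna) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    L = len(transcript)
    if L < 8:
        return []
    t = np.frombuffer(transcript.encode("ascii"), dtype=np.uint8)
    n_win = L - 7                       # window starts 0 .. L-8
    pair_all = np.ones(n_win, dtype=bool)
    n_wob = np.zeros(n_win, dtype=np.int8)
    wc_by_k = {}
    for k in range(2, 9):               # miRNA positions 2..8
        m = mirna[k - 1]
        sub = t[8 - k: 8 - k + n_win]
        wc = sub == ord(_COMP[m])
        if m == "G":
            wob = sub == ord("U")
        elif m == "U":
            wob = sub == ord("G")
        else:
            wob = np.zeros(n_win, dtype=bool)
        pair_all &= wc | wob
        n_wob += wob.astype(np.int8)
        wc_by_k[k] = wc
    cand = np.flatnonzero(pair_all & (n_wob <= params.max_wobble_in_seed))
    t1_is_A = t[7:7 + n_win] == ord("A")
    out = []
    for p in cand:
        wc27 = all(wc_by_k[k][p] for k in range(2, 8))
        wc28 = wc27 and wc_by_k[8][p]
        if wc28 and t1_is_A[p]:
            cls = "8mer"
        elif wc28:
            cls = "7mer-m8"
        elif wc27 and t1_is_A[p]:
            cls = "7mer-A1"
        else:
            cls = "6mer"
        out.append((int(p), cls))
    return out


def _substitution(m: str, t: str, params: AlignmentParams) -> float:
    if _pairs_wc(m, t):
        return params.match_score
    if (m, t) in _WOBBLE:
        return params.wobble_score
    return params.mismatch


NEG_INF = float("-inf")


def _local_align(mirna: str, window: str, params: AlignmentParams):
    """Local affine-gap DP of the full miRNA against a transcript window.

    The miRNA is threaded antiparallel: query index ``j`` (0-based along
    the window's 5'->3' reading) corresponds to miRNA position
    ``len(mirna) - j`` (1-based). Substitution scores are multiplied by
    ``seed_weight`` at seed positions; gaps touching the seed region are
    disallowed when ``allow_seed_gaps`` is false.

    Returns ``(score, t_start, t_end, aligned)`` where ``t_start/t_end``
    delimit the aligned window region (half-open) and ``aligned`` is the
    display triple (miRNA line 3'->5' reversed to window sense, pairing
    line, window line).
    """
    n = len(mirna)
    m = len(window)
    query = mirna[::-1]                       # window-sense reading
    mirna_pos = [n - j for j in range(n)]     # 1-based miRNA position per query idx

    def sub(j: int, i: int) -> float:
        s = _substitution(query[j], window[i], params)
        if params.in_seed(mirna_pos[j]):
            s *= params.seed_weight
        return s

    # H: best alignment ending at (j, i) with a substitution
    # E: ending with a gap in the query (window base unmatched)
    # F: ending with a gap in the window (query base unmatched)
    H = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    H[0, :] = 0.0
    H[:, 0] = 0.0
    best = (0.0, 0, 0)
    ptr: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            s = sub(j - 1, i - 1)
            cand = [
                (H[j - 1, i - 1] + s, ("H", j - 1, i - 1)),
                (E[j - 1, i - 1] + s, ("E", j - 1, i - 1)),
                (F[j - 1, i - 1] + s, ("F", j - 1, i - 1)),
                (s, ("start", j - 1, i - 1)),
            ]
            H[j, i], ptr[("H", j, i)] = max(cand, key=lambda c: c[0])
            # E: unpaired window base i, bulged between query bases j and j+1
            e_cand = [
                (H[j, i - 1] + params.gap_open, ("H", j, i - 1)),
                (E[j, i - 1] + params.gap_extend, ("E", j, i - 1)),
            ]
            e_best, e_ptr = max(e_cand, key=lambda c: c[0])
            if not params.allow_seed_gaps and 0 < j < n and (
                params.in_seed(mirna_pos[j - 1]) or params.in_seed(mirna_pos[j])
            ):
                e_best = NEG_INF
            E[j, i] = e_best
            if e_best > NEG_INF:
                ptr[("E", j, i)] = e_ptr
            # F: consume query base j (gap in window)
            f_cand = [
                (H[j - 1, i] + params.gap_open, ("H", j - 1, i)),
                (F[j - 1, i] + params.gap_extend, ("F", j - 1, i)),
            ]
            f_best, f_ptr = max(f_cand, key=lambda c: c[0])
            if not params.allow_seed_gaps and params.in_seed(mirna_pos[j - 1]):
                f_best = NEG_INF
            F[j, i] = f_best
            if f_best > NEG_INF:
                ptr[("F", j, i)] = f_ptr
            if H[j, i] > best[0]:
                best = (H[j, i], j, i)
    score, bj, bi = best
    if score <= 0:
        return 0.0, 0, 0, ("", "", "")
    # traceback from the best substitution cell
    state, j, i = "H", bj, bi
    qline, pline, tline = [], [], []
    t_end = bi
    while True:
        if j == 0 or i == 0:        # ran into the zero boundary
            t_start = i
            break
        prev = ptr.get((state, j, i))
        if state == "H":
            qc, tc = query[j - 1], window[i - 1]
            mchar = "|" if _pairs_wc(qc, tc) else (
                ":" if (qc, tc) in _WOBBLE else " ")
            qline.append(qc)
            pline.append(mchar)
            tline.append(tc)
        elif state == "E":
            qline.append("-")
            pline.append(" ")
            tline.append(window[i - 1])
        elif state == "F":
            qline.append(query[j - 1])
            pline.append(" ")
            tline.append("-")
        if prev is None or prev[0] == "start":
            t_start = (prev[2] if prev else i - 1)
            break
        state, j, i = prev
    return (
        float(score),
        int(t_start),
        int(t_end),
        ("".join(reversed(qline)), "".join(reversed(pline)), "".join(reversed(tline))),
    )


def align_site(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    candidate_pos: int,
    seed_class: str,
    params: AlignmentParams | None = None,
) -> MREHit | None:
    """Extend a seed candidate into a scored hit, or reject it.

    The alignment window spans the expected pairing footprint (the miRNA
    length ending at the seed 3' boundary) plus ``flank`` nt each side,
    clipped to the transcript.
    """
    params = params or AlignmentParams()
    n = len(mirna)
    if not 0 <= candidate_pos <= len(transcript) - 8:
        raise ValueError("candidate position out of bounds")
    w_lo = max(0, candidate_pos + 8 - n - params.flank)
    w_hi = min(len(transcript), candidate_pos + 8 + params.flank)
    window = transcript[w_lo:w_hi]
    score, t0, t1, aligned = _local_align(mirna, window, params)
    if score < params.score_threshold:
        return None
    return MREHit(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=w_lo + t0,
        end=w_lo + t1,
        score=score,
        seed_class=seed_class,
        aligned_pairs=aligned,
    )


def _merge_hits(hits: list[MREHit]) -> list[MREHit]:
    """Merge overlapping hits of one (miRNA, transcript) pair: keep the
    max score, ties going to the leftmost."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    merged: list[MREHit] = []
    cluster: list[MREHit] = []
    cluster_end = -1
    for h in hits:
        if cluster and h.start >= cluster_end:
            merged.append(max(cluster, key=lambda c: (c.score, -c.start)))
            cluster = []
            cluster_end = -1
        cluster.append(h)
        cluster_end = max(cluster_end, h.end)
    if cluster:
        merged.append(max(cluster, key=lambda c: (c.score, -c.start)))
    return merged


def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    params: AlignmentParams | None = None,
) -> list[MREHit]:
    """All MRE hits over the miRNA x transcript cross, merged and sorted.

    Output order is (transcript id, miRNA id, start) and is independent of
    the input dict ordering.
    """
    params = params or AlignmentParams()
    all_hits: list[MREHit] = []
    for tid in sorted(transcripts):
        tx = transcripts[tid].upper().replace("T", "U")
        for mid in sorted(mirnas):
            mi = mirnas[mid].upper().replace("T", "U")
            pair_hits = []
            for pos, cls in seed_scan(mi, tx, params):
                hit = align_site(mid, mi, tid, tx, pos, cls, params)
                if hit is not None:
                    pair_hits.append(hit)
            all_hits.extend(_merge_hits(pair_hits))
    all_hits.sort(key=lambda h: (h.transcript_id, h.mirna_id, h.start))
    return all_hits


def hits_to_frame(hits: list[MREHit]):
    """Hits as a DataFrame (the TSV/table interchange layout)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mirna": h.mirna_id, "transcript": h.transcript_id,
                "start": h.start, "end": h.end, "score": h.score,
                "seed_class": h.seed_class,
            }
            for h in hits
        ],
        columns=["mirna", "transcript", "start", "end", "score", "seed_class"],
    )
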