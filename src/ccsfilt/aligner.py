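"""Local alignment of adapters within reads under VecScreen-style scoring.

The detector replaces an external ``blastn`` call with an in-package
Smith-Waterman aligner using the same scoring scheme: match +1, mismatch
-5, and affine gaps where a gap of length k costs 3 + 3k.  Under this
regime a true adapter hit is nearly exact by construction — a single
mismatch erases five matches — so no seeding, banding or E-value
statistics are needed: full dynamic programming over a <= 45 bp adapter is
cheap, and acceptance is delegated to downstream length/identity
thresholds.

Hit discovery per (adapter, orientation) is iterative: find the best local
alignment, mask its read interval, and repeat while the best score clears
``report_floor``.  Coordinates always refer to the read's forward strand;
``orientation='reverse'`` means the reverse complement of the adapter
matched the read as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from ._kernel import sw_best
from .adapters import AdapterRecord, reverse_complement
from .io_formats import SeqRead

__all__ = [
    "AlignmentScoring",
    "LocalAlignment",
    "AdapterHit",
    "local_align",
    "find_adapter_hits",
    "DEFAULT_SCORING",
    "DEFAULT_REPORT_FLOOR",
]

_NEG = -(1 << 40)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

#: Score of a masked/ambiguous base code; anything >= 4 mismatches everything.
MASK_CODE = 5

DEFAULT_REPORT_FLOOR = 20


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)].copy()


@dataclass(frozen=True)
class AlignmentScoring:
    """Alignment scoring scheme (VecScreen-style defaults).

    A gap of length k costs ``gap_open_cost + k * gap_extend_cost``
    (BLAST convention: a 1-base gap costs 6 at the defaults).
    """

    match_reward: int = 1
    mismatch_penalty: int = -5
    gap_open_cost: int = 3
    gap_extend_cost: int = 3

    def __post_init__(self) -> None:
        if self.match_reward <= 0 or self.mismatch_penalty >= 0:
            raise ValueError("match_reward must be > 0 and mismatch_penalty < 0")
        if self.gap_open_cost <= 0 or self.gap_extend_cost <= 0:
            raise ValueError("gap costs must be > 0")


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query inside a target.

    Coordinates are 0-based, end-exclusive.  ``alignment_columns`` counts
    aligned pairs plus gap columns; ``identity_pct`` is
    100 * matches / alignment_columns.
    """

    score: int
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    matches: int
    mismatches: int
    gap_opens: int
    alignment_columns: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.alignment_columns


@dataclass(frozen=True)
class AdapterHit:
    """A local-alignment match of an adapter inside a read.

    ``read_start``/``read_end`` are on the read's forward strand;
    ``adapter_start``/``adapter_end`` are on the adapter as published
    (converted back for reverse-orientation hits).
    """

    read_id: str
    adapter_name: str
    orientation: str  # 'forward' | 'reverse'
    read_start: int
    read_end: int
    adapter_start: int
    adapter_end: int
    score: int
    alignment_columns: int
    matches: int
    mismatches: int
    gap_opens: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.alignment_columns

    @property
    def span(self) -> int:
        return self.read_end - self.read_start


def _traceback_align(t_codes: np.ndarray, q_codes: np.ndarray, scoring: AlignmentScoring):
    """Full Gotoh DP with traceback on a small window; returns the best
    local alignment with column-level counts, or None if best score <= 0.

    Deterministic preferences: best cell by (score, smaller target end,
    smaller query end); traceback prefers diagonal, then target-gap, then
    query-gap, and closing a gap over extending it.
    """
    n, m = len(t_codes), len(q_codes)
    mt, mm = scoring.match_reward, scoring.mismatch_penalty
    oc = scoring.gap_open_cost + scoring.gap_extend_cost
    ge = scoring.gap_extend_cost
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    best, bi, bj = 0, -1, -1
    for i in range(1, n + 1):
        ti = t_codes[i - 1]
        for j in range(1, m + 1):
            s = mt if (ti == q_codes[j - 1] and ti < 4) else mm
            E[i, j] = max(H[i - 1, j] - oc, E[i - 1, j] - ge)
            F[i, j] = max(H[i, j - 1] - oc, F[i, j - 1] - ge)
            h = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    # traceback
    i, j, state = bi, bj, "H"
    matches = mismatches = gap_opens = columns = 0
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = mt if (t_codes[i - 1] == q_codes[j - 1] and t_codes[i - 1] < 4) else mm
            if H[i, j] == H[i - 1, j - 1] + s:
                columns += 1
                if s == mt:
                    matches += 1
                else:
                    mismatches += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap column consuming a target base
            columns += 1
            if E[i, j] == H[i - 1, j] - oc:
                gap_opens += 1
                state = "H"
            i -= 1
        else:  # F: gap column consuming a query base
            columns += 1
            if F[i, j] == H[i, j - 1] - oc:
                gap_opens += 1
                state = "H"
            j -= 1
    return LocalAlignment(
        score=int(best),
        target_start=i,
        target_end=bi,
        query_start=j,
        query_end=bj,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        alignment_columns=columns,
    )


def _best_alignment(
    t_codes: np.ndarray, q_codes: np.ndarray, scoring: AlignmentScoring
) -> Optional[LocalAlignment]:
    """Two-pass best local alignment: O(m)-memory kernel to locate the
    optimum, then a traceback on its target interval for column counts."""
    score, t_start, t_end = sw_best(
        t_codes,
        q_codes,
        np.int64(scoring.match_reward),
        np.int64(scoring.mismatch_penalty),
        np.int64(scoring.gap_open_cost),
        np.int64(scoring.gap_extend_cost),
    )
    if score <= 0:
        return None
    window = t_codes[t_start:t_end]
    aln = _traceback_align(window, q_codes, scoring)
    assert aln is not None and aln.score == score, "window traceback must recover the optimum"
    return LocalAlignment(
        score=aln.score,
        target_start=int(t_start) + aln.target_start,
        target_end=int(t_start) + aln.target_end,
        query_start=aln.query_start,
        query_end=aln.query_end,
        matches=aln.matches,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        alignment_columns=aln.alignment_columns,
    )


def local_align(
    query: str, target: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> Optional[LocalAlignment]:
    """Maximum-scoring local alignment of ``query`` within ``target``.

    Returns None when the best score is <= 0 (e.g. no shared bases).
    N bases score as mismatches against everything.  Ties are broken
    deterministically toward the smaller target start, then the smaller
    interval.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    return _best_alignment(encode_sequence(target), encode_sequence(query), scoring)


def _iter_hits_one_orientation(
    codes: np.ndarray,
    read_id: str,
    adapter: AdapterRecord,
    orientation: str,
    scoring: AlignmentScoring,
    report_floor: int,
) -> List[AdapterHit]:
    query = adapter.sequence if orientation == "forward" else reverse_complement(
        adapter.sequence
    )
    q_codes = encode_sequence(query)
    m = len(query)
    work = codes.copy()
    hits: List[AdapterHit] = []
    # each reported hit masks >= 1 base, but any passing hit masks >= floor bases
    for _ in range(max(4, codes.size // max(report_floor, 1) + 4)):
        aln = _best_alignment(work, q_codes, scoring)
        if aln is None or aln.score < report_floor:
            break
        if orientation == "reverse":
            a_start, a_end = m - aln.query_end, m - aln.query_start
        else:
            a_start, a_end = aln.query_start, aln.query_end
        hits.append(
            AdapterHit(
                read_id=read_id,
                adapter_name=adapter.name,
                orientation=orientation,
                read_start=aln.target_start,
                read_end=aln.target_end,
                adapter_start=a_start,
                adapter_end=a_end,
                score=aln.score,
                alignment_columns=aln.alignment_columns,
                matches=aln.matches,
                mismatches=aln.mismatches,
                gap_opens=aln.gap_opens,
            )
        )
        work[aln.target_start : aln.target_end] = MASK_CODE
    return hits


def find_adapter_hits(
    read: SeqRead,
    adapters: Sequence[AdapterRecord],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    report_floor: int = DEFAULT_REPORT_FLOOR,
) -> List[AdapterHit]:
    """All adapter hits in a read, both orientations, scoring above
    ``report_floor``.

    Hits are found per (adapter, orientation) by iterative best-hit
    masking, so they are non-overlapping on the read within each such
    combination.  The returned list is sorted by read_start (forward
    orientation first on exact ties).
    """
    if report_floor < 1:
        raise ValueError("report_floor must be >= 1")
    if len(read) == 0:
        return []
    codes = encode_sequence(read.sequence)
    hits: List[AdapterHit] = []
    for adapter in adapters:
        for orientation in ("forward", "reverse"):
            hits.extend(
                _iter_hits_one_orientation(
                    codes, read.read_id, adapter, orientation, scoring, report_floor
                )
            )
    hits.sort(key=lambda h: (h.read_start, h.read_end, h.adapter_name, h.orientation != "forward"))
    return hits
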