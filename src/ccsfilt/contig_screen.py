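"""Adapter screening of assembled contigs.

The same detector used on reads is applied to assembly FASTA, the check
NCBI's VecScreen performs at submission time: any contig with a passing
adapter hit is flagged.  Long contigs are scanned in overlapping windows
so memory stays bounded regardless of contig size; the overlap exceeds
twice the adapter length, so no hit can straddle a boundary undetected.
Remediation (dropping, excising or masking contigs) is deliberately left
to the user — no post-assembly fix is ideal, which is why filtering reads
before assembly is the point of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

from .adapters import AdapterRecord
from .aligner import (
    DEFAULT_SCORING,
    AdapterHit,
    AlignmentScoring,
    find_adapter_hits,
)
from .filtering import FilterConfig, effective_report_floor, hit_passes
from .io_formats import SeqRead, read_sequences

logger = logging.getLogger(__name__)

__all__ = ["ContigFinding", "screen_contigs", "write_contig_tsv"]

DEFAULT_WINDOW = 1_000_000
DEFAULT_OVERLAP = 100  # >= 2x adapter length


@dataclass
class ContigFinding:
    """One adapter-contaminated contig with its passing hits."""

    contig_id: str
    contig_length: int
    hits: List[AdapterHit]

    @property
    def n_passing_hits(self) -> int:
        return len(self.hits)


def _screen_one(
    contig: SeqRead,
    adapters: Sequence[AdapterRecord],
    scoring: AlignmentScoring,
    config: FilterConfig,
    window: int,
    overlap: int,
) -> List[AdapterHit]:
    by_name = {a.name: a for a in adapters}
    floor = effective_report_floor(adapters, config, scoring)
    length = len(contig)
    hits: List[AdapterHit] = []
    seen = set()
    start = 0
    while True:
        end = min(length, start + window)
        chunk = SeqRead(contig.read_id, contig.sequence[start:end])
        for h in find_adapter_hits(chunk, adapters, scoring, report_floor=floor):
            if not hit_passes(h, by_name[h.adapter_name], config):
                continue
            key = (
                h.adapter_name,
                h.orientation,
                start + h.read_start,
                start + h.read_end,
            )
            if key in seen:  # duplicate from window overlap
                continue
            seen.add(key)
            hits.append(
                AdapterHit(
                    read_id=h.read_id,
                    adapter_name=h.adapter_name,
                    orientation=h.orientation,
                    read_start=start + h.read_start,
                    read_end=start + h.read_end,
                    adapter_start=h.adapter_start,
                    adapter_end=h.adapter_end,
                    score=h.score,
                    alignment_columns=h.alignment_columns,
                    matches=h.matches,
                    mismatches=h.mismatches,
                    gap_opens=h.gap_opens,
                )
            )
        if end >= length:
            break
        start = end - overlap
    hits.sort(key=lambda h: (h.read_start, h.read_end, h.adapter_name, h.orientation))
    return hits


def screen_contigs(
    assembly: str | Path,
    adapters: Sequence[AdapterRecord],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    config: FilterConfig = FilterConfig(),
    window: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
) -> List[ContigFinding]:
    """Flag adapter-contaminated contigs in an assembly FASTA.

    Returns one :class:`ContigFinding` per contig with >= 1 passing hit,
    in file order; a clean assembly yields an empty list.
    """
    if overlap < 2 * max((len(a) for a in adapters), default=50):
        raise ValueError("window overlap must be at least twice the adapter length")
    findings: List[ContigFinding] = []
    n_contigs = 0
    for contig in read_sequences(assembly, "fasta"):
        n_contigs += 1
        hits = _screen_one(contig, adapters, scoring, config, window, overlap)
        if hits:
            findings.append(ContigFinding(contig.read_id, len(contig), hits))
    if n_contigs == 0:
        logger.warning("assembly %s contains no contigs", assembly)
    return findings


def write_contig_tsv(findings: Sequence[ContigFinding], path: str | Path) -> None:
    """Same 12-column hit dialect as the read path, plus a trailing
    comment line with the contaminated-contig count."""
    from .filtering import write_hits_tsv

    all_hits = [h for f in findings for h in f.hits]
    write_hits_tsv(all_hits, path)
    with open(path, "at") as fh:
        fh.write(f"# contaminated_contigs: {len(findings)}\n")
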