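"""Threshold acceptance, positional classification and whole-read removal.

A read is contaminated when any adapter hit is both long enough and exact
enough: at defaults, >= 44 of the 45 blunt-adapter bases or >= 34 of the
35 C2-primer bases, at >= 97% identity.  Contaminated reads are removed
whole — never trimmed — because a read carrying an adapter may be a
chimeric molecule whose non-adapter portion is itself suspect.  Survivors
are copied byte-identically from the input.

The ``-l``/``-m`` style overrides in :class:`FilterConfig` replace the
per-adapter defaults uniformly across all adapters, allowing removal of
shorter or less exact matches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .adapters import AdapterRecord
from .aligner import (
    DEFAULT_REPORT_FLOOR,
    DEFAULT_SCORING,
    AdapterHit,
    AlignmentScoring,
    find_adapter_hits,
)
from .io_formats import SeqRead, detect_format, is_gzip, iter_raw_records, write_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "ReadClassification",
    "hit_passes",
    "classify_read",
    "build_blocklist",
    "filter_reads",
    "effective_report_floor",
    "write_blocklist",
    "write_hits_tsv",
]

CATEGORIES = ("five_prime", "internal", "three_prime", "distributed", "other")


@dataclass(frozen=True)
class FilterConfig:
    """User-tunable stringency knobs.

    ``min_match_length_override`` / ``min_identity_override`` mirror the
    CLI ``-l``/``-m`` flags; when unset, each adapter's own defaults
    apply.  ``end_zone_fraction`` defines the 5'/3' zones used for
    positional classification (fraction of read length at each end).
    """

    min_match_length_override: Optional[int] = None
    min_identity_override: Optional[float] = None
    end_zone_fraction: float = 0.10
    other_coverage_fraction: float = 0.80  # hits covering more -> 'other'

    def __post_init__(self) -> None:
        if self.min_match_length_override is not None and self.min_match_length_override < 1:
            raise ValueError("min_match_length_override must be >= 1")
        if self.min_identity_override is not None and not (
            0 < self.min_identity_override <= 100
        ):
            raise ValueError("min_identity_override must be in (0, 100]")
        if not 0 < self.end_zone_fraction < 0.5:
            raise ValueError("end_zone_fraction must be in (0, 0.5)")

    def thresholds_for(self, adapter: AdapterRecord) -> Tuple[int, float]:
        length = (
            self.min_match_length_override
            if self.min_match_length_override is not None
            else adapter.min_match_length_default
        )
        identity = (
            self.min_identity_override
            if self.min_identity_override is not None
            else adapter.min_identity_default
        )
        return length, identity


@dataclass
class ReadClassification:
    """Positional category of a contaminated read."""

    read_id: str
    category: str
    n_hits: int
    orientations: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.n_hits < 1:
            raise ValueError("classification requires at least one hit")


def hit_passes(hit: AdapterHit, adapter: AdapterRecord, config: FilterConfig) -> bool:
    """True iff the hit meets the active length and identity thresholds."""
    if hit.adapter_name != adapter.name:
        raise ValueError(
            f"hit adapter {hit.adapter_name!r} does not match record {adapter.name!r}"
        )
    min_len, min_ident = config.thresholds_for(adapter)
    return hit.alignment_columns >= min_len and hit.identity_pct >= min_ident


def effective_report_floor(
    adapters: Sequence[AdapterRecord],
    config: FilterConfig,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    default_floor: int = DEFAULT_REPORT_FLOOR,
) -> int:
    """Score floor for hit discovery that cannot miss a passing hit.

    The worst-scoring hit that still passes thresholds (L columns at M%
    identity) has ceil(L*M/100) matches and the rest of its columns as
    1-base gaps (the costliest non-match column).  The discovery floor is
    the default capped at that worst case, so relaxed ``-l``/``-m``
    settings surface correspondingly weaker alignments.
    """
    worst = default_floor
    gap1 = scoring.gap_open_cost + scoring.gap_extend_cost
    for adapter in adapters:
        min_len, min_ident = config.thresholds_for(adapter)
        matches = math.ceil(min_len * min_ident / 100.0)
        floor = matches * scoring.match_reward - (min_len - matches) * gap1
        worst = min(worst, max(1, floor))
    return worst


def classify_read(
    read_length: int,
    passing_hits: Sequence[AdapterHit],
    config: FilterConfig = FilterConfig(),
) -> ReadClassification:
    """Assign the positional category of a contaminated read.

    Each hit falls in the 5' zone (start within the first
    ``end_zone_fraction`` of the read), the 3' zone (end within the last
    fraction), or is internal; a hit qualifying for both ends counts as
    5'.  Reads whose hits agree on a zone take that category; disagreeing
    zones give 'distributed'.  Reads whose passing hits cover more than
    ``other_coverage_fraction`` of the read are adapter-dimer-like
    artifacts and are categorized 'other'.
    """
    if not passing_hits:
        raise ValueError("classify_read requires at least one passing hit")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    ids = {h.read_id for h in passing_hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple reads: {sorted(ids)}")
    orientations: Dict[str, int] = {"forward": 0, "reverse": 0}
    for h in passing_hits:
        orientations[h.orientation] += 1

    covered = _union_length(sorted((h.read_start, h.read_end) for h in passing_hits))
    if covered > config.other_coverage_fraction * read_length:
        category = "other"
    else:
        five_edge = config.end_zone_fraction * read_length
        three_edge = (1.0 - config.end_zone_fraction) * read_length
        zones = set()
        for h in passing_hits:
            if h.read_start < five_edge:
                zones.add("five_prime")
            elif h.read_end > three_edge:
                zones.add("three_prime")
            else:
                zones.add("internal")
        category = zones.pop() if len(zones) == 1 else "distributed"
    return ReadClassification(
        read_id=passing_hits[0].read_id,
        category=category,
        n_hits=len(passing_hits),
        orientations=orientations,
    )


def _union_length(intervals: List[Tuple[int, int]]) -> int:
    total, cur_start, cur_end = 0, None, None
    for start, end in intervals:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def build_blocklist(
    reads: Iterable[SeqRead],
    adapters: Sequence[AdapterRecord],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    config: FilterConfig = FilterConfig(),
) -> Tuple[Set[str], List[AdapterHit], List[ReadClassification]]:
    """Scan a read stream and collect the contaminated-read blocklist.

    Returns ``(blocklist, passing_hits, classifications)``: the ids of
    reads with at least one passing hit, every passing hit across all
    reads, and one classification per blocklisted read.  Duplicate read
    ids are fatal — id-based removal requires unique ids.
    """
    by_name = {a.name: a for a in adapters}
    floor = effective_report_floor(adapters, config, scoring)
    blocklist: Set[str] = set()
    seen: Set[str] = set()
    all_hits: List[AdapterHit] = []
    classifications: List[ReadClassification] = []
    for read in reads:
        if read.read_id in seen:
            raise ValueError(f"duplicate read id {read.read_id!r} in input")
        seen.add(read.read_id)
        hits = find_adapter_hits(read, adapters, scoring, report_floor=floor)
        passing = [h for h in hits if hit_passes(h, by_name[h.adapter_name], config)]
        if passing:
            blocklist.add(read.read_id)
            all_hits.extend(passing)
            classifications.append(classify_read(len(read), passing, config))
    return blocklist, all_hits, classifications


def filter_reads(
    input_path: str | Path,
    blocklist: Set[str],
    output_path: str | Path,
    format: str = "auto",
) -> Tuple[int, int]:
    """Write the input minus blocklisted reads; returns (kept, removed).

    FASTQ/FASTA survivors are copied byte-identically (raw record
    selection); BAM inputs are serialized to FASTQ.  Blocklist ids absent
    from the input produce a warning, not an error.
    """
    input_path = Path(input_path)
    fmt = detect_format(input_path) if format == "auto" else format
    kept = removed = 0
    seen_blocked: Set[str] = set()
    if fmt == "bam":
        from .io_formats import read_sequences

        def survivors():
            nonlocal kept, removed
            for read in read_sequences(input_path, "bam"):
                if read.read_id in blocklist:
                    removed += 1
                    seen_blocked.add(read.read_id)
                else:
                    kept += 1
                    yield read

        write_sequences(survivors(), output_path, format="fastq")
    else:
        from .io_formats import open_text_write

        with open_text_write(output_path, is_gzip(output_path)) as out:
            for read_id, raw in iter_raw_records(input_path, fmt):
                if read_id in blocklist:
                    removed += 1
                    seen_blocked.add(read_id)
                else:
                    kept += 1
                    out.write(raw)
    missing = blocklist - seen_blocked
    if missing:
        logger.warning(
            "%d blocklist id(s) not found in input (e.g. %s)",
            len(missing),
            sorted(missing)[:3],
        )
    return kept, removed


def write_blocklist(blocklist_ordered: Sequence[str], path: str | Path) -> None:
    """One read id per line, input order."""
    with open(path, "wt") as fh:
        for read_id in blocklist_ordered:
            fh.write(read_id + "\n")


def write_hits_tsv(hits: Sequence[AdapterHit], path: str | Path) -> None:
    """12-column hit table in the BLAST tabular (outfmt 6) dialect.

    Columns: read id, adapter name with '/fwd' or '/rev' suffix, percent
    identity (2 dp), aligned columns, mismatches, gap opens, read start,
    read end (1-based inclusive), adapter start, adapter end (1-based
    inclusive), '.' (no E-value), raw score.
    """
    with open(path, "wt") as fh:
        for h in hits:
            suffix = "/fwd" if h.orientation == "forward" else "/rev"
            fh.write(
                "\t".join(
                    [
                        h.read_id,
                        h.adapter_name + suffix,
                        f"{h.identity_pct:.2f}",
                        str(h.alignment_columns),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.read_start + 1),
                        str(h.read_end),
                        str(h.adapter_start + 1),
                        str(h.adapter_end),
                        ".",
                        str(h.score),
                    ]
                )
                + "\n"
            )
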