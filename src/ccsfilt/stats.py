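"""Dataset-level contamination summaries.

Mirrors the reporting used in HiFi adapter surveys: the contaminated
proportion of the read pool, the positional-category breakdown, the
forward/reverse orientation split of hits, and length/GC profiles of
contaminated versus clean reads (contaminated reads in real datasets tend
to sit near 10 kb and show slightly elevated GC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

from .aligner import AdapterHit
from .filtering import CATEGORIES, ReadClassification
from .io_formats import SeqRead

__all__ = ["ScanReport", "gc_content", "summarize_scan", "lower_median"]


def gc_content(sequence: str) -> float:
    """Percent G+C among unambiguous bases (N excluded from both sides).

    An all-N sequence reports 0; an empty sequence is an error.
    """
    if not sequence:
        raise ValueError("gc_content of empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    return 100.0 * gc / total if total else 0.0


def lower_median(values: Sequence[float]) -> float:
    """Median using the lower of the two middle values for even n."""
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def _group_summary(lengths: List[int], gcs: List[float]) -> Dict[str, Optional[float]]:
    if not lengths:
        return {
            "n": 0,
            "min_bp": None,
            "median_bp": None,
            "mean_bp": None,
            "max_bp": None,
            "mean_gc_pct": None,
            "median_gc_pct": None,
        }
    return {
        "n": len(lengths),
        "min_bp": min(lengths),
        "median_bp": lower_median(lengths),
        "mean_bp": sum(lengths) / len(lengths),
        "max_bp": max(lengths),
        "mean_gc_pct": sum(gcs) / len(gcs),
        "median_gc_pct": lower_median(gcs),
    }


@dataclass
class ScanReport:
    """Summary of one filtering run.

    Invariants: contaminated + retained == total;
    sum(category_counts) == contaminated; sum(orientation_counts) == hits.
    """

    reads_total: int = 0
    reads_contaminated: int = 0
    reads_retained: int = 0
    proportion_contaminated: float = 0.0
    hits_total: int = 0
    orientation_counts: Dict[str, int] = field(
        default_factory=lambda: {"forward": 0, "reverse": 0}
    )
    category_counts: Dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )
    length_summary: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)
    gc_summary: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reads_total": self.reads_total,
            "reads_contaminated": self.reads_contaminated,
            "reads_retained": self.reads_retained,
            "proportion_contaminated": round(self.proportion_contaminated, 6),
            "hits_total": self.hits_total,
            "orientation_counts": dict(self.orientation_counts),
            "category_counts": dict(self.category_counts),
            "length_summary": self.length_summary,
            "gc_summary": self.gc_summary,
        }

    def write_text(self, path: str | Path) -> None:
        """Flat ``key: value`` report, fixed field order."""
        lines = [
            f"reads_total: {self.reads_total}",
            f"reads_contaminated: {self.reads_contaminated}",
            f"reads_retained: {self.reads_retained}",
            f"proportion_contaminated: {self.proportion_contaminated:.6f}",
            f"hits_total: {self.hits_total}",
        ]
        for key in ("forward", "reverse"):
            lines.append(f"orientation.{key}: {self.orientation_counts.get(key, 0)}")
        for cat in CATEGORIES:
            lines.append(f"category.{cat}: {self.category_counts.get(cat, 0)}")
        for group in ("contaminated", "clean"):
            summary = self.length_summary.get(group, {})
            for key in ("n", "min_bp", "median_bp", "mean_bp", "max_bp"):
                lines.append(f"length.{group}.{key}: {_fmt(summary.get(key))}")
            gsum = self.gc_summary.get(group, {})
            for key in ("mean_gc_pct", "median_gc_pct"):
                lines.append(f"gc.{group}.{key}: {_fmt(gsum.get(key))}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.2f}"
    return str(value)


def summarize_scan(
    reads: Iterable[SeqRead],
    blocklist: Set[str],
    hits: Sequence[AdapterHit],
    classifications: Sequence[ReadClassification],
) -> ScanReport:
    """Build a :class:`ScanReport` from scan outputs.

    ``reads`` is re-streamed for length/GC profiles; ``hits`` must be the
    passing hits and ``classifications`` one entry per blocklisted read.
    """
    report = ScanReport()
    lengths: Dict[str, List[int]] = {"contaminated": [], "clean": []}
    gcs: Dict[str, List[float]] = {"contaminated": [], "clean": []}
    for read in reads:
        report.reads_total += 1
        group = "contaminated" if read.read_id in blocklist else "clean"
        lengths[group].append(len(read))
        if len(read):
            gcs[group].append(gc_content(read.sequence))
    report.reads_contaminated = len(blocklist)
    report.reads_retained = report.reads_total - report.reads_contaminated
    report.proportion_contaminated = (
        report.reads_contaminated / report.reads_total if report.reads_total else 0.0
    )
    report.hits_total = len(hits)
    for h in hits:
        report.orientation_counts[h.orientation] += 1
    for cls in classifications:
        report.category_counts[cls.category] += 1
    for group in ("contaminated", "clean"):
        summary = _group_summary(lengths[group], gcs[group])
        report.length_summary[group] = {
            k: summary[k] for k in ("n", "min_bp", "median_bp", "mean_bp", "max_bp")
        }
        report.gc_summary[group] = {
            "n": summary["n"],
            "mean_gc_pct": summary["mean_gc_pct"],
            "median_gc_pct": summary["median_gc_pct"],
        }
    return report
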