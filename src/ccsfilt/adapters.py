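"""Known PacBio adapter/primer sequences and strand utilities.

PacBio library molecules are circularized with a 45 bp hairpin ("SMRTbell
blunt") adapter and sequenced from a 35 bp (C2) primer.  Both sequences
should be stripped on-instrument during circular-consensus generation, but
copies occasionally survive into HiFi reads; these are the contaminants
this package screens for.

Each adapter carries its own default acceptance thresholds: a near
full-length match (one missing base allowed) at >= 97% identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

__all__ = [
    "AdapterRecord",
    "builtin_adapters",
    "reverse_complement",
    "load_adapter_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_RC = set("ACGTNacgtn")

# The two PacBio contaminant sequences screened by VecScreen-style QC
# (UniVec "PacBio Blunt Adapter" and "PacBio C2 Primer").
PACBIO_BLUNT_ADAPTER = "ATCTCTCTCTTTTCCTCCTCCTCCGTTGTTGTTGTTGAGAGAGAT"
PACBIO_C2_PRIMER = "AAAAAAAAAAAAAAAAAATTAACGGAGGAGGAGGA"


@dataclass(frozen=True)
class AdapterRecord:
    """A named adapter sequence with its default match-acceptance thresholds.

    Attributes
    ----------
    name:
        Identifier used in hit tables and truth tables.
    sequence:
        Uppercase ACGT adapter sequence, 5'->3'.
    min_match_length_default:
        Minimum aligned columns for a hit to count, absent a CLI override.
    min_identity_default:
        Minimum percent identity for a hit to count, absent a CLI override.
    """

    name: str
    sequence: str
    min_match_length_default: int
    min_identity_default: float

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(
                f"adapter {self.name!r}: sequence must be non-empty uppercase ACGT"
            )
        if not 0 < self.min_match_length_default <= len(self.sequence):
            raise ValueError(
                f"adapter {self.name!r}: min_match_length_default must be in "
                f"(0, {len(self.sequence)}]"
            )
        if not 0 < self.min_identity_default <= 100:
            raise ValueError(
                f"adapter {self.name!r}: min_identity_default must be in (0, 100]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def builtin_adapters() -> List[AdapterRecord]:
    """Return the bundled PacBio contaminants with their default thresholds.

    The blunt adapter (45 bp) requires >= 44 aligned columns; the C2 primer
    (35 bp) requires >= 34; both require >= 97% identity.  These sequences
    and thresholds are part of the tool's contract and are stable across
    releases.
    """
    return [
        AdapterRecord("pacbio_blunt_adapter", PACBIO_BLUNT_ADAPTER, 44, 97.0),
        AdapterRecord("pacbio_c2_primer", PACBIO_C2_PRIMER, 34, 97.0),
    ]


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over ACGTN (case preserved).

    Raises
    ------
    ValueError
        If the sequence contains a character outside ACGTN (either case).
    """
    bad = set(sequence) - _VALID_RC
    if bad:
        raise ValueError(
            f"cannot reverse-complement characters {sorted(bad)!r}: only ACGTN supported"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


def load_adapter_fasta(path: str | Path) -> List[AdapterRecord]:
    """Load user-supplied adapters from a FASTA file.

    Each record becomes an :class:`AdapterRecord` with defaults following
    the built-in pattern of one missing base allowed: min length =
    ``len(sequence) - 1`` (floor 1) and 97% identity.
    """
    import pysam

    records = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seq = entry.sequence.upper()
            records.append(
                AdapterRecord(entry.name, seq, max(1, len(seq) - 1), 97.0)
            )
    return records


def unique_adapters(adapters: Iterable[AdapterRecord]) -> List[AdapterRecord]:
    """Validate that adapter names are unique; return them as a list."""
    out: List[AdapterRecord] = []
    seen = set()
    for rec in adapters:
        if rec.name in seen:
            raise ValueError(f"duplicate adapter name {rec.name!r}")
        seen.add(rec.name)
        out.append(rec)
    return out
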