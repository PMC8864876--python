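"""Sequence I/O: FASTQ (plain/gzip), FASTA (plain/gzip) and unaligned BAM.

Reads are modelled as :class:`SeqRead`.  Two access paths are provided:

* :func:`read_sequences` / :func:`write_sequences` — parsed records, used
  by the scanner and the simulator.
* :func:`iter_raw_records` — the raw serialized text of each FASTQ/FASTA
  record, used by the filtering step so that surviving reads are copied
  byte-identically (record selection, never re-serialization).

BAM access goes through pysam; only primary, non-supplementary records are
used (HiFi BAMs are unaligned, so other flags are ignored).
"""

from __future__ import annotations

import gzip
import io
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "SeqRead",
    "FastqParseError",
    "read_sequences",
    "write_sequences",
    "iter_raw_records",
    "detect_format",
    "is_gzip",
]

FASTQ_EXTS = (".fq", ".fastq", ".fq.gz", ".fastq.gz")
FASTA_EXTS = (".fa", ".fasta", ".fna", ".fa.gz", ".fasta.gz", ".fna.gz")


class FastqParseError(ValueError):
    """Raised when a FASTQ stream violates the 4-line record structure."""


@dataclass
class SeqRead:
    """One sequencing read (or contig).

    ``read_id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder (possibly empty).  ``quality`` is a
    Phred string of the same length as ``sequence``, or ``None`` for
    FASTA/BAM records without base qualities.
    """

    read_id: str
    sequence: str
    description: str = ""
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read_id or any(c.isspace() for c in self.read_id):
            raise ValueError(f"invalid read id {self.read_id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def header(self) -> str:
        return f"{self.read_id} {self.description}" if self.description else self.read_id

    def __len__(self) -> int:
        return len(self.sequence)


def is_gzip(path: str | Path) -> bool:
    return str(path).endswith(".gz")


def detect_format(path: str | Path) -> str:
    """Resolve a file's format from its extension: fastq, fasta or bam."""
    name = str(path).lower()
    if name.endswith(FASTQ_EXTS):
        return "fastq"
    if name.endswith(FASTA_EXTS):
        return "fasta"
    if name.endswith(".bam"):
        return "bam"
    raise ValueError(f"cannot infer sequence format from extension of {path!r}")


def _open_text(path: str | Path) -> IO[str]:
    if is_gzip(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


@contextmanager
def open_text_write(path: str | Path, gzip_out: bool):
    """Text handle for writing, gzip-compressed when requested.

    Gzip output is deterministic: no mtime or filename in the header, so
    identical content yields identical bytes across runs.
    """
    if gzip_out:
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                with io.TextIOWrapper(gz) as fh:
                    yield fh
    else:
        with open(path, "wt") as fh:
            yield fh


def _split_header(header: str) -> Tuple[str, str]:
    parts = header.split(None, 1)
    return parts[0], (parts[1] if len(parts) == 2 else "")


def _iter_fastq(handle: IO[str]) -> Iterator[SeqRead]:
    index = 0
    while True:
        head = handle.readline()
        if not head:
            return
        if head.strip() == "":
            continue
        lines = [head, handle.readline(), handle.readline(), handle.readline()]
        if any(not ln for ln in lines[1:]):
            raise FastqParseError(
                f"FASTQ record {index}: truncated record (expected 4 lines)"
            )
        head, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
        if not head.startswith("@"):
            raise FastqParseError(
                f"FASTQ record {index}: header does not start with '@': {head!r}"
            )
        if not plus.startswith("+"):
            raise FastqParseError(f"FASTQ record {index}: missing '+' separator line")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"FASTQ record {index}: sequence and quality lengths differ"
            )
        read_id, desc = _split_header(head[1:])
        yield SeqRead(read_id, seq, desc, qual)
        index += 1


def _iter_fasta(path: str | Path) -> Iterator[SeqRead]:
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield SeqRead(entry.name, entry.sequence, entry.comment or "", None)


def _iter_bam(path: str | Path) -> Iterator[SeqRead]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None:
                logger.warning("BAM record %s has no SEQ field; skipped", rec.query_name)
                continue
            qual = rec.qual  # Phred+33 string or None
            yield SeqRead(rec.query_name, seq, "", qual)


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[SeqRead]:
    """Stream :class:`SeqRead` records from a FASTQ/FASTA/BAM file.

    ``format='auto'`` resolves by extension.  Gzip is handled transparently
    for FASTQ and FASTA.  Records are yielded in file order; memory use is
    bounded per record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = detect_format(path) if format == "auto" else format
    if fmt == "fastq":
        with _open_text(path) as fh:
            yield from _iter_fastq(fh)
    elif fmt == "fasta":
        yield from _iter_fasta(path)
    elif fmt == "bam":
        yield from _iter_bam(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _wrap(seq: str, width: int = 80) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def write_sequences(
    reads: Iterable[SeqRead],
    path: str | Path,
    format: str = "fastq",
    gzip_out: Optional[bool] = None,
) -> int:
    """Write records as FASTQ (4-line) or FASTA (80-column wrap).

    FASTQ output requires every record to carry a quality string.  Returns
    the number of records written.  ``gzip_out=None`` follows the output
    extension.
    """
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unsupported output format {format!r}")
    if gzip_out is None:
        gzip_out = is_gzip(path)
    count = 0
    with open_text_write(path, gzip_out) as out:
        for read in reads:
            if format == "fastq":
                if read.quality is None:
                    raise ValueError(
                        f"read {read.read_id}: FASTQ output requires a quality string"
                    )
                out.write(f"@{read.header}\n{read.sequence}\n+\n{read.quality}\n")
            else:
                out.write(f">{read.header}\n")
                for line in _wrap(read.sequence):
                    out.write(line + "\n")
            count += 1
    return count


def iter_raw_records(path: str | Path, format: str = "auto") -> Iterator[Tuple[str, str]]:
    """Yield ``(read_id, raw_text)`` for each FASTQ/FASTA record.

    ``raw_text`` is the record exactly as serialized in the input
    (including newlines); writing it back unchanged reproduces the input
    byte-for-byte.  Only text formats are supported — BAM inputs are
    re-serialized through :class:`SeqRead` instead.
    """
    path = Path(path)
    fmt = detect_format(path) if format == "auto" else format
    if fmt == "fastq":
        with _open_text(path) as fh:
            index = 0
            while True:
                head = fh.readline()
                if not head:
                    return
                lines = [head, fh.readline(), fh.readline(), fh.readline()]
                if any(not ln for ln in lines[1:]):
                    raise FastqParseError(
                        f"FASTQ record {index}: truncated record (expected 4 lines)"
                    )
                if not lines[0].startswith("@") or not lines[2].startswith("+"):
                    raise FastqParseError(f"FASTQ record {index}: malformed record")
                read_id, _ = _split_header(lines[0][1:].rstrip("\n"))
                yield read_id, "".join(lines)
                index += 1
    elif fmt == "fasta":
        with _open_text(path) as fh:
            header = None
            chunk: list[str] = []
            for line in fh:
                if line.startswith(">"):
                    if header is not None:
                        yield header, "".join(chunk)
                    header, _ = _split_header(line[1:].rstrip("\n"))
                    chunk = [line]
                elif header is not None:
                    chunk.append(line)
            if header is not None:
                yield header, "".join(chunk)
    else:
        raise ValueError(f"raw record iteration unsupported for format {fmt!r}")
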