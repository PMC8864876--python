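"""End-to-end runs: scan -> blocklist -> filtered output -> reports.

Each run writes a manifest recording resolved options, inputs, outputs
and timestamps, sufficient to re-run the command identically.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .adapters import AdapterRecord, builtin_adapters
from .aligner import DEFAULT_SCORING, AlignmentScoring
from .contig_screen import ContigFinding, screen_contigs, write_contig_tsv
from .filtering import (
    FilterConfig,
    build_blocklist,
    filter_reads,
    write_blocklist,
    write_hits_tsv,
)
from .io_formats import detect_format, is_gzip, read_sequences
from .stats import summarize_scan

logger = logging.getLogger(__name__)

__all__ = ["FilterRunResult", "run_filter_one", "run_screen", "write_manifest"]


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


@dataclass
class FilterRunResult:
    input_path: Path
    output_paths: Dict[str, Path]
    reads_total: int
    reads_removed: int
    reads_kept: int
    report: object = None  # ScanReport


def write_manifest(
    path: Path,
    subcommand: str,
    options: dict,
    inputs: List[dict],
    outputs: List[str],
    started: str,
    status: str,
    seed: Optional[int] = None,
) -> None:
    manifest = {
        "tool": "ccsfilt",
        "version": __version__,
        "subcommand": subcommand,
        "options": options,
        "inputs": inputs,
        "outputs": outputs,
        "started": started,
        "finished": _now(),
        "status": status,
        "seed": seed,
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_filter_one(
    input_path: str | Path,
    outdir: str | Path = ".",
    prefix: Optional[str] = None,
    adapters: Optional[Sequence[AdapterRecord]] = None,
    config: FilterConfig = FilterConfig(),
    scoring: AlignmentScoring = DEFAULT_SCORING,
    gzip_output: Optional[bool] = None,
    threads: int = 1,
) -> FilterRunResult:
    """Filter one read file; writes all per-file outputs into ``outdir``.

    ``gzip_output=None`` mirrors the input's compression (BAM inputs are
    written as gzipped FASTQ).  ``threads`` is recorded in the manifest;
    outputs are identical for any value.
    """
    started = _now()
    input_path = Path(input_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adapters = list(adapters) if adapters is not None else builtin_adapters()
    fmt = detect_format(input_path)
    if prefix is None:
        prefix = input_path.name
        for ext in (".gz", ".fastq", ".fq", ".fasta", ".fa", ".fna", ".bam"):
            if prefix.lower().endswith(ext):
                prefix = prefix[: -len(ext)]
    if gzip_output is None:
        gzip_output = True if fmt == "bam" else is_gzip(input_path)
    out_ext = {"fastq": "filt.fastq", "bam": "filt.fastq", "fasta": "filt.fasta"}[fmt]
    out = {
        "filtered": outdir / f"{prefix}.{out_ext}{'.gz' if gzip_output else ''}",
        "blocklist": outdir / f"{prefix}.blocklist",
        "hits": outdir / f"{prefix}.contaminant.tsv",
        "stats": outdir / f"{prefix}.stats",
        "stats_json": outdir / f"{prefix}.stats.json",
        "manifest": outdir / f"{prefix}.manifest.json",
    }
    options = {
        "min_match_length_override": config.min_match_length_override,
        "min_identity_override": config.min_identity_override,
        "end_zone_fraction": config.end_zone_fraction,
        "adapters": [a.name for a in adapters],
        "threads": threads,
        "gzip_output": gzip_output,
        "outdir": str(outdir),
        "prefix": prefix,
    }
    status = "failed"
    reads_total = kept = removed = 0
    report = None
    try:
        blocklist, hits, classifications = build_blocklist(
            read_sequences(input_path), adapters, scoring, config
        )
        ordered_ids = [c.read_id for c in classifications]
        write_blocklist(ordered_ids, out["blocklist"])
        write_hits_tsv(hits, out["hits"])
        report = summarize_scan(
            read_sequences(input_path), blocklist, hits, classifications
        )
        report.write_text(out["stats"])
        report.write_json(out["stats_json"])
        kept, removed = filter_reads(input_path, blocklist, out["filtered"], fmt)
        reads_total = kept + removed
        logger.info(
            "%s: %d reads, %d contaminated (%.4f%%), %d kept",
            input_path.name,
            reads_total,
            removed,
            100.0 * removed / reads_total if reads_total else 0.0,
            kept,
        )
        status = "ok"
    finally:
        write_manifest(
            out["manifest"],
            "filter",
            options,
            [{"path": str(input_path), "records": reads_total}],
            [str(p) for k, p in out.items() if k != "manifest"],
            started,
            status,
        )
    return FilterRunResult(
        input_path=input_path,
        output_paths=out,
        reads_total=reads_total,
        reads_removed=removed,
        reads_kept=kept,
        report=report,
    )


def run_screen(
    assembly: str | Path,
    outdir: str | Path = ".",
    prefix: Optional[str] = None,
    adapters: Optional[Sequence[AdapterRecord]] = None,
    config: FilterConfig = FilterConfig(),
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> List[ContigFinding]:
    """Screen an assembly FASTA; writes ``<prefix>.contigs.tsv`` + manifest."""
    started = _now()
    assembly = Path(assembly)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adapters = list(adapters) if adapters is not None else builtin_adapters()
    if prefix is None:
        prefix = assembly.stem
    tsv = outdir / f"{prefix}.contigs.tsv"
    manifest = outdir / f"{prefix}.manifest.json"
    options = {
        "min_match_length_override": config.min_match_length_override,
        "min_identity_override": config.min_identity_override,
        "adapters": [a.name for a in adapters],
        "outdir": str(outdir),
        "prefix": prefix,
    }
    status = "failed"
    findings: List[ContigFinding] = []
    try:
        findings = screen_contigs(assembly, adapters, scoring, config)
        write_contig_tsv(findings, tsv)
        status = "ok"
    finally:
        write_manifest(
            manifest,
            "screen",
            options,
            [{"path": str(assembly)}],
            [str(tsv)],
            started,
            status,
        )
    return findings
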