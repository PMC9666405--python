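"""Shared readers and writers: BED12 alignments, TSV tables, run manifests.

All outputs are plain tab-separated text with a deterministic column order so
reruns with identical inputs and seeds are byte-identical and diff-friendly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .longread import LongReadAlignment

log = logging.getLogger("isojunct")

__all__ = [
    "Bed12Error",
    "read_bed12",
    "write_bed12",
    "write_tables",
    "file_sha256",
]


class Bed12Error(ValueError):
    """A BED12 file had more malformed lines than allowed."""


def _parse_bed12_line(line: str, lineno: int) -> LongReadAlignment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
    contig, start, end, name, _score, strand = fields[:6]
    start, end = int(start), int(end)
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
    starts = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(
            f"line {lineno}: blockCount {n_blocks} does not match "
            f"blockSizes/blockStarts lengths {len(sizes)}/{len(starts)}"
        )
    blocks = tuple((start + off, size) for off, size in zip(starts, sizes))
    return LongReadAlignment(
        read_id=name, contig=contig, start=start, end=end, strand=strand, blocks=blocks
    )


def read_bed12(
    path: str | Path, max_bad_lines: int = 0
) -> tuple[list[LongReadAlignment], list[str]]:
    """Read blocked alignments from a 12-column BED file.

    Malformed lines are collected (with line numbers) rather than silently
    dropped; more than ``max_bad_lines`` of them aborts with
    :class:`Bed12Error`.  Returns ``(records, problems)``.
    """
    path = Path(path)
    records: list[LongReadAlignment] = []
    problems: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                records.append(_parse_bed12_line(line, lineno))
            except (ValueError, IndexError) as e:
                problems.append(f"{path.name}:{e}")
    if len(problems) > max_bad_lines:
        raise Bed12Error(
            f"{path}: {len(problems)} malformed BED12 line(s) "
            f"(limit {max_bad_lines}); first: {problems[0]}"
        )
    for p in problems:
        log.warning("rejected BED12 line: %s", p)
    return records, problems


def write_bed12(reads: Iterable[LongReadAlignment], path: str | Path) -> None:
    """Write alignments as BED12 (score 0, thick region = full span)."""
    with Path(path).open("w") as fh:
        for r in reads:
            sizes = ",".join(str(size) for _, size in r.blocks) + ","
            starts = ",".join(str(s - r.start) for s, _ in r.blocks) + ","
            fh.write(
                "\t".join(
                    [
                        r.contig,
                        str(r.start),
                        str(r.end),
                        r.read_id,
                        "0",
                        r.strand,
                        str(r.start),
                        str(r.end),
                        "0,0,0",
                        str(len(r.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
    inputs: Sequence[str | Path] = (),
    float_format: str = "%.10g",
) -> Path:
    """Write each result table as ``<name>.tsv`` plus a provenance manifest.

    The manifest (``manifest.json``) records a sha256 per output, a hash of
    the run configuration, the seed, and input-file checksums; it contains no
    timestamps, so identical runs yield identical manifests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}
    for name, frame in results.items():
        dest = out_dir / f"{name}.tsv"
        frame.to_csv(dest, sep="\t", index=False, float_format=float_format)
        hashes[dest.name] = file_sha256(dest)
    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "outputs": dict(sorted(hashes.items())),
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "inputs": {Path(p).name: file_sha256(p) for p in inputs},
    }
    dest = out_dir / "manifest.json"
    dest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return dest
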