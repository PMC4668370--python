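"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED is 0-based half-open and read as-is; GTF is 1-based closed and converted
to the internal half-open convention on read.  Peak tables are MACS-style
BED-like files with a per-peak tag count column.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, Peak

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_peaks",
    "write_peaks",
]


def read_chrom_sizes(path: str | os.PathLike) -> ChromSizes:
    """Read a two-column ``chrom<TAB>length`` file."""
    entries: Dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {i}: expected 'chrom length'")
            name, length = fields[0], fields[1]
            if name in entries:
                raise ValueError(f"{path}: line {i}: duplicate chromosome {name!r}")
            entries[name] = int(length)
    return ChromSizes(entries)


def write_chrom_sizes(sizes: ChromSizes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str | os.PathLike) -> List[GenomicInterval]:
    """Read BED3/BED6 intervals; strand taken from column 6 when present."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {i}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n")
            elif iv.strand != ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return None


def read_peaks(path: str | os.PathLike, tags_col: int = 4) -> List[Peak]:
    """Read a MACS-style peak table: BED intervals plus a tag-count column.

    ``tags_col`` is the 1-based column index holding the tag count
    (default 4, i.e. the column right after chrom/start/end).
    """
    if tags_col < 4:
        raise ValueError("tags_col must be >= 4 (after chrom/start/end)")
    out: List[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < tags_col:
                raise ValueError(f"{path}: line {i}: expected >= {tags_col} columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                tags = float(fields[tags_col - 1])
            except ValueError:
                raise ValueError(f"{path}: line {i}: malformed peak record") from None
            out.append(Peak(iv, tags))
    return out


def write_peaks(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    """Write peaks as ``chrom start end tags``."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            tags = int(p.tags) if float(p.tags).is_integer() else p.tags
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tags}\n")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _validate_gtf(path: str | os.PathLike) -> None:
    # gffutils skips some malformed lines silently; fail loudly with a line number
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: failed to parse GTF line {i}: expected 9 fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: failed to parse GTF line {i}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise ValueError(f"{path}: failed to parse GTF line {i}: bad coordinates")


def load_gtf_db(path: str | os.PathLike) -> gffutils.FeatureDB:
    """Build an in-memory gffutils database from a GTF file."""
    _validate_gtf(path)
    try:
        return gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc
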