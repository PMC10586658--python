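"""Readers and writers for the external text formats.

narrowPeak (ENCODE BED6+4), BED6/BED3, tab-separated matrices (header row =
sample ids, first column = feature id), plain-text gene lists (one id per
line) and JSON documents for network edges / enrichment results.

All readers emit 0-based half-open coordinates; all writers accept them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


class ParseError(ValueError):
    """Raised for malformed input lines; message names the file and line."""


@dataclass(frozen=True, slots=True)
class PeakRecord:
    """One narrowPeak row: interval, name, score and resolved summit."""

    interval: GenomicInterval
    name: str
    score: float
    summit: int


def read_narrowpeak(path) -> list[PeakRecord]:
    """Parse an ENCODE narrowPeak file.

    The summit is ``start + column-10 offset``; an offset of ``-1`` falls back
    to the interval midpoint ``floor((start + end) / 2)``. Input order is
    preserved.
    """
    path = Path(path)
    records: list[PeakRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak requires >= 10 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                chrom = cols[0]
                start, end = int(cols[1]), int(cols[2])
                name = cols[3]
                score = float(cols[4])
                strand = cols[5] if cols[5] in ("+", "-", ".") else "."
                offset = int(cols[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            interval = GenomicInterval(chrom, start, end, strand)
            if offset == -1:
                summit = (start + end) // 2
            else:
                if offset >= end - start:
                    raise ParseError(
                        f"{path}:{lineno}: summit offset {offset} >= peak "
                        f"length {end - start}"
                    )
                summit = start + offset
            records.append(PeakRecord(interval, name, score, summit))
    return records


def write_narrowpeak(records: list[PeakRecord], path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{rec.score:g}\t"
                f"{iv.strand}\t0\t-1\t-1\t{rec.summit - iv.start}\n"
            )


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene annotation as BED6 or 5-column TSV (gene, chrom, start, end, strand).

    Returns a DataFrame with columns ``gene, chrom, start, end, strand, tss``
    where the TSS is the 0-based first transcribed base: ``start`` on the
    ``+`` strand, ``end - 1`` on ``-``. Duplicate gene ids are rejected.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 6 and _is_int(cols[1]) and _is_int(cols[2]):
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                gene, strand = cols[3], cols[5]
            elif len(cols) >= 5 and _is_int(cols[2]) and _is_int(cols[3]):
                gene, chrom = cols[0], cols[1]
                start, end, strand = int(cols[2]), int(cols[3]), cols[4]
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected BED6 or (gene, chrom, start, "
                    f"end, strand) TSV"
                )
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: gene strand must be '+' or '-', got {strand!r}"
                )
            tss = start if strand == "+" else end - 1
            rows.append((gene, chrom, start, end, strand, tss))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand", "tss"])
    dupes = df["gene"][df["gene"].duplicated()].unique()
    if len(dupes):
        raise ParseError(f"{path}: duplicate gene ids: {', '.join(map(str, dupes[:5]))}")
    return df


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    """Write annotation as BED6 (score column 0)."""
    with Path(path).open("w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene}\t0\t{row.strand}\n")


def read_bed3(path) -> pd.DataFrame:
    """Read a minimal BED (chrom, start, end); extra columns ignored."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED requires >= 3 columns")
            try:
                rows.append((cols[0], int(cols[1]), int(cols[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed3(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix: header row = sample ids, first column = feature id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True
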