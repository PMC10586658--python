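"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open (BED convention).
Conversion to/from 1-based text formats happens only in :mod:`regcircuit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name. Must be non-empty.
    start : int
        Inclusive start, 0-based.
    end : int
        Exclusive end. Must satisfy ``start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-shared-base overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def summit_window(chrom: str, summit: int, window: int) -> GenomicInterval:
    """Window of ``window`` bp centred on a summit: ``[summit - w//2, summit + w - w//2)``.

    For even windows this places the summit at the left-center base, so the
    interval always has exactly ``window`` bases.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    half = window // 2
    start = summit - half
    end = start + window
    return GenomicInterval(chrom, max(0, start), end)
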