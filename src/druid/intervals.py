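"""Genomic interval primitives shared by the annotation and quantification layers.

All coordinates are 0-based, half-open ``[start, end)``. GTF input (1-based,
closed) is converted on read by :mod:`druid.annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval.

    Parameters
    ----------
    chrom:
        Chromosome name. In merged multi-genome references the name may carry
        a genome-label prefix (e.g. ``hg38_chr1``).
    start, end:
        0-based half-open coordinates, ``0 <= start < end``.
    strand:
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}: must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (same chromosome;
        strand is ignored — ambiguous read assignment is strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )
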