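"""Genomic coordinate primitives.

All in-memory coordinates in this package are 0-based, half-open
(BED convention). GFF3 I/O is the single place where 1-based closed
coordinates appear, and the conversion happens at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvariantError

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence.

    Parameters
    ----------
    chrom
        Sequence name; must be non-empty.
    start, end
        0-based half-open coordinates, ``0 <= start < end``.
    strand
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvariantError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise InvariantError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise InvariantError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def expanded(self, flank_bp: int) -> "GenomicInterval":
        """Interval extended by ``flank_bp`` on both sides (floored at 0)."""
        return GenomicInterval(
            self.chrom, max(0, self.start - flank_bp), self.end + flank_bp, self.strand
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"
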