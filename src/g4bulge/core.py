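"""Shared primitives: intervals, sequence helpers, coordinate conventions.

All coordinates are 0-based half-open throughout the package; conversion to
1-based inclusive coordinates (the convention used in printed tables of
genomics papers) happens only when formatting reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Motif model labels. CANONICAL is the classic four-tract G3+ motif; the
#: GxBy labels follow the field's convention: x intact (uninterrupted)
#: G-stems, y bulged (inserted non-G) nucleotides. Only G3B1/G3B2/G2B2 are
#: accepted bulged models; G1B3/G0B4 exist as negative-control labels.
MODELS = ("CANONICAL", "G3B1", "G3B2", "G2B2", "G1B3", "G0B4")
ACCEPTED_BS_MODELS = ("G3B1", "G3B2", "G2B2")

#: Preference when one genomic span admits several model decompositions:
#: fewer bulges and more intact stems imply higher structural stability.
MODEL_PREFERENCE = {"G3B1": 0, "G3B2": 1, "G2B2": 2, "CANONICAL": 3}


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A strand-aware genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        Half-open coordinates, ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.``.
    name : str
        Free-text label (model name, gene id, ...).
    score : float, optional
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval", stranded: bool = False) -> bool:
        """True iff the two intervals share at least one nucleotide.

        Half-open arithmetic: book-ended intervals do not overlap.
        """
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end
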