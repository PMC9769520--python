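"""Shared domain types for the Tn-Seq pipeline.

Coordinates are 1-based inclusive throughout the package, matching the
convention of GFF3 annotation. An insertion site is identified by the pair
(position, orientation): `position` is the base adjacent to the transposon
I end after correcting for the 9-bp target-site duplication, and
`orientation` is the direction (+/-) in which the transposon-borne promoter
transcribes on the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: ORF or structural-RNA feature.

    start/end are 1-based inclusive genome coordinates with start <= end
    regardless of strand.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    gene_type: str = "protein"  # "protein" or "RNA"
    essential: bool = False  # ground-truth label (simulated data only)
    operon: int = -1  # operon index in simulated annotations, -1 if unknown

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.gene_type not in ("protein", "RNA"):
            raise ValueError(f"{self.gene_id}: bad gene_type {self.gene_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InsertionSite:
    """A unique Tn5 insertion site.

    position: 1-based bp of the base adjacent to the Tn5 I end after
        duplication correction.
    orientation: direction of promoter-driven transcription on the genome.
    read_count: number of junction reads supporting the site.
    """

    position: int
    orientation: str
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class AlignmentHit:
    """Best genome placement of a trimmed junction fragment.

    contig_position: 1-based coordinate of the FIRST genomic base of the
        fragment (the base that was adjacent to the transposon O end).
    strand: genome strand the fragment aligns to.
    coverage: aligned fraction of the fragment.
    identity: matching fraction within the aligned region; the first
        seed_len bases are a perfect match by construction.
    ambiguous: True when two or more placements tie on (coverage, identity).
    """

    contig_position: int
    strand: str
    coverage: float
    identity: float
    ambiguous: bool = False


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(part: float, whole: float) -> int:
    """Integer percentage, rounded half away from zero."""
    return round_half_away(100.0 * part / whole)


def percent_loss(before: float, after: float) -> int:
    """Integer percent reduction from `before` to `after`."""
    return round_half_away(100.0 * (1.0 - after / before))
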