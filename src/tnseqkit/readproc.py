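"""Junction-read processing: from raw reads to a unique insertion-site table.

Stages, in the order they run:

1. ``filter_and_trim`` — keep reads carrying the transposon O-end marker,
   strip the marker and any trailing semiarbitrary-primer sequence; the
   first base of the surviving fragment is the genomic base adjacent to the
   O end.
2. ``align_fragment`` — seed-and-extend placement on the genome requiring a
   perfect match of the first 15 fragment bases; among multiple hits the one
   with the highest (coverage, identity) wins, exact ties are ambiguous and
   dropped.
3. ``to_insertion_site`` — shift the O-end-adjacent coordinate to the
   I-end-adjacent one across the 9-bp target duplication and flip the
   orientation, because the transposon-borne promoter sits at the I end.
4. ``unique_sites`` — collapse observations by (position, orientation) with
   read counts.

``library_stats`` and ``gap_stats`` summarise a site table the way Tn-Seq
library QC tables do (insertion density in bp/insertion, intragenic
fraction, gap-size distribution on the circular chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import AlignmentHit, GeneModel, percent, revcomp, round_half_away

SEED_LEN = 15  # perfect-match seed length reading out of the O end
DUP_LEN = 9    # Tn5 target-site duplication


# ------------------------------------------------------------ filter and trim

@dataclass
class AttritionCounts:
    """Per-stage read attrition, mirrored in pipeline logs."""

    n_raw: int = 0
    n_no_marker: int = 0
    n_too_short: int = 0
    n_filtered: int = 0       # fragments entering alignment
    n_unaligned: int = 0
    n_ambiguous: int = 0
    n_mapped: int = 0


def filter_and_trim(
    reads: Iterable[tuple[str, str]],
    oend_marker: str,
    primer_set: Sequence[str] = (),
    min_len: int = SEED_LEN,
    max_n_fraction: float = 0.1,
    counts: AttritionCounts | None = None,
) -> Iterable[tuple[str, str]]:
    """Yield (read_id, genomic fragment) for reads containing the marker.

    The fragment starts right after the O-end marker; if a configured primer
    sequence occurs downstream it (and everything after it) is removed.
    Reads lacking the marker, and fragments that end up shorter than
    ``min_len`` or too N-rich, are counted and dropped.
    """
    if not oend_marker:
        raise ValueError("oend_marker must be non-empty")
    counts = AttritionCounts() if counts is None else counts
    for read_id, seq in reads:
        counts.n_raw += 1
        idx = seq.find(oend_marker)
        if idx < 0:
            counts.n_no_marker += 1
            continue
        frag = seq[idx + len(oend_marker):]
        for primer in primer_set:
            j = frag.find(primer)
            if j >= 0:
                frag = frag[:j]
        if len(frag) < min_len or frag.count("N") > max_n_fraction * len(frag):
            counts.n_too_short += 1
            continue
        counts.n_filtered += 1
        yield read_id, frag


# ------------------------------------------------------------------ alignment

class GenomeAligner:
    """Exact-seed, ungapped-extension aligner.

    Indexes every ``seed_len``-mer of the genome once; a fragment is placed
    wherever its first ``seed_len`` bases match perfectly on either strand,
    then extended without gaps and scored by (coverage, identity).
    """

    def __init__(self, genome: str, seed_len: int = SEED_LEN):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.genome = genome.upper()
        self.seed_len = seed_len
        self._index: dict[str, list[int]] = {}
        g = self.genome
        for i in range(len(g) - seed_len + 1):
            self._index.setdefault(g[i:i + seed_len], []).append(i)

    def _extend_plus(self, frag: str, g0: int) -> tuple[int, float, float]:
        g = self.genome
        aln_len = min(len(frag), len(g) - g0)
        matches = sum(1 for a, b in zip(frag[:aln_len], g[g0:g0 + aln_len]) if a == b)
        return aln_len, aln_len / len(frag), matches / aln_len

    def _extend_minus(self, frag: str, c0: int) -> tuple[int, float, float]:
        # c0: 0-based genome index of the fragment's first base; the read
        # runs toward lower coordinates on the minus strand
        g = self.genome
        aln_len = min(len(frag), c0 + 1)
        segment = revcomp(g[c0 - aln_len + 1: c0 + 1])
        matches = sum(1 for a, b in zip(frag[:aln_len], segment) if a == b)
        return aln_len, aln_len / len(frag), matches / aln_len

    def align(self, fragment: str) -> AlignmentHit | None:
        """Best placement of a fragment, or None (no seed hit / too short),
        or a hit flagged ``ambiguous`` on an exact (coverage, identity) tie."""
        frag = fragment.upper()
        if len(frag) < self.seed_len:
            return None
        seed = frag[:self.seed_len]
        candidates: list[tuple[float, float, int, str]] = []
        for g0 in self._index.get(seed, ()):
            _, cov, ident = self._extend_plus(frag, g0)
            candidates.append((cov, ident, g0 + 1, "+"))
        for g0 in self._index.get(revcomp(seed), ()):
            c0 = g0 + self.seed_len - 1
            _, cov, ident = self._extend_minus(frag, c0)
            candidates.append((cov, ident, c0 + 1, "-"))
        if not candidates:
            return None
        candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
        best = candidates[0]
        tie = len(candidates) > 1 and candidates[1][:2] == best[:2]
        return AlignmentHit(contig_position=best[2], strand=best[3],
                            coverage=best[0], identity=best[1], ambiguous=tie)


def align_fragment(fragment: str, genome: str | GenomeAligner,
                   seed_len: int = SEED_LEN) -> AlignmentHit | None:
    """One-shot convenience wrapper; build a :class:`GenomeAligner` when
    aligning many fragments against the same genome."""
    aligner = genome if isinstance(genome, GenomeAligner) else GenomeAligner(genome, seed_len)
    return aligner.align(fragment)


# -------------------------------------------------- duplication correction

def to_insertion_site(hit: AlignmentHit, dup_len: int = DUP_LEN,
                      genome_length: int | None = None,
                      circular: bool = True) -> tuple[int, str]:
    """Convert an O-end-anchored alignment into the I-end insertion site.

    The read starts at the genomic base adjacent to the O end; the site is
    by definition the base adjacent to the I end on the other side of the
    ``dup_len``-bp target duplication, and the promoter orientation is the
    opposite of the read direction:

    * hit on strand '+': position = contig_position + dup_len - 1, orientation '-'
    * hit on strand '-': position = contig_position - dup_len + 1, orientation '+'

    Positions falling outside the genome wrap around for circular genomes
    and raise ValueError otherwise.
    """
    if hit.ambiguous:
        raise ValueError("cannot convert an ambiguous alignment")
    if hit.strand == "+":
        pos, orient = hit.contig_position + dup_len - 1, "-"
    else:
        pos, orient = hit.contig_position - dup_len + 1, "+"
    if genome_length is not None and not 1 <= pos <= genome_length:
        if not circular:
            raise ValueError(f"corrected position {pos} outside linear genome")
        pos = (pos - 1) % genome_length + 1
    return pos, orient


# ----------------------------------------------------------------- site table

def unique_sites(observations: Iterable[tuple[int, str]] | pd.DataFrame) -> pd.DataFrame:
    """Collapse (position, orientation) observations into a site table
    sorted by position with per-site read counts."""
    if isinstance(observations, pd.DataFrame):
        df = observations[["position", "orientation"]]
    else:
        df = pd.DataFrame(observations, columns=["position", "orientation"])
    if df.empty:
        return pd.DataFrame(columns=["position", "orientation", "read_count"])
    out = (
        df.groupby(["position", "orientation"], sort=False)
        .size()
        .rename("read_count")
        .reset_index()
        .sort_values(["position", "orientation"], ignore_index=True)
    )
    out["position"] = out["position"].astype(int)
    return out


def reads_to_sites(
    reads: Iterable[tuple[str, str]],
    aligner: GenomeAligner,
    oend_marker: str,
    primer_set: Sequence[str] = (),
    dup_len: int = DUP_LEN,
    circular: bool = True,
) -> tuple[pd.DataFrame, AttritionCounts]:
    """Full read-processing stage: filter/trim, align, correct coordinates,
    collapse to unique sites. Returns (site table, attrition counts)."""
    counts = AttritionCounts()
    observations: list[tuple[int, str]] = []
    for _, frag in filter_and_trim(reads, oend_marker, primer_set, counts=counts):
        hit = aligner.align(frag)
        if hit is None:
            counts.n_unaligned += 1
            continue
        if hit.ambiguous:
            counts.n_ambiguous += 1
            continue
        counts.n_mapped += 1
        observations.append(
            to_insertion_site(hit, dup_len, len(aligner.genome), circular)
        )
    return unique_sites(observations), counts


# ------------------------------------------------------------------ summaries

def insertion_density(genome_length: int, n_unique_sites: int) -> int:
    """Average bp per insertion, rounded half away from zero."""
    if n_unique_sites <= 0:
        raise ValueError("need at least one unique site")
    return round_half_away(genome_length / n_unique_sites)


@dataclass
class LibraryStats:
    n_raw: int
    n_filtered: int
    n_mapped: int
    n_unique_sites: int
    density_bp_per_insertion: int | None
    intragenic_fraction: int | None  # integer percent

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def library_stats(site_table: pd.DataFrame, genome_length: int,
                  annotation: Sequence[GeneModel] = (),
                  counts: AttritionCounts | None = None) -> LibraryStats:
    """Library-level QC: unique sites, insertion density, intragenic percent."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n_sites = len(site_table)
    density = insertion_density(genome_length, n_sites) if n_sites else None

    intragenic = None
    if n_sites and len(annotation):
        # merge gene spans, then test membership of each unique site
        spans = sorted((g.start, g.end) for g in annotation)
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        pos = site_table["position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        intragenic = percent(int(inside.sum()), n_sites)

    c = counts or AttritionCounts()
    return LibraryStats(
        n_raw=c.n_raw, n_filtered=c.n_filtered, n_mapped=c.n_mapped,
        n_unique_sites=n_sites, density_bp_per_insertion=density,
        intragenic_fraction=intragenic,
    )


@dataclass
class GapStats:
    gap_sizes: np.ndarray
    fraction_le_25bp: float  # percent
    largest_gap: int

    def fraction_le(self, threshold: int) -> float:
        return 100.0 * float(np.mean(self.gap_sizes <= threshold))


def gap_stats(site_table: pd.DataFrame, genome_length: int,
              circular: bool = True) -> GapStats:
    """Distribution of insertion-free gaps between consecutive sites.

    Sites are collapsed by position (both orientations of one position count
    once). A gap is the number of insertion-free bases between consecutive
    positions; circular genomes contribute the wrap-around gap, so the gaps
    sum to genome_length - n_positions.
    """
    pos = np.unique(site_table["position"].to_numpy())
    if pos.size == 0:
        raise ValueError("gap statistics need at least one site")
    gaps = np.diff(pos) - 1
    if circular:
        wrap = genome_length - pos[-1] + pos[0] - 1
        gaps = np.append(gaps, wrap)
    return GapStats(
        gap_sizes=gaps,
        fraction_le_25bp=100.0 * float(np.mean(gaps <= 25)),
        largest_gap=int(gaps.max()),
    )
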