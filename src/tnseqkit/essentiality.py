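"""Gene essentiality calling from an insertion-site table.

A gene is called putatively essential under deliberately stringent rules so
that read-through artefacts of the promoter-carrying transposon do not
produce false nonessential calls:

* insertions are first assigned to genes with a 5'-offset on the gene's own
  strand and a sense/antisense orientation;
* filtered: sense insertions in the +1 codon register (the transposon-borne
  promoter, Shine-Dalgarno and start codon can express the downstream ORF
  portion in frame), any insertion in the stop codon, sense insertions in
  the last 9 bp and antisense insertions in the first 9 bp of an ORF;
* classified: no surviving insertion -> non-hit (essential); all surviving
  insertions in the last 10% of the ORF -> essential; a largest
  insertion-free gap (gene-boundary flanks included) covering >= 80% of the
  ORF -> essential; anything else -> nonessential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, percent

VERDICTS = ("essential_non_hit", "essential_last10", "essential_gap80", "nonessential")


@dataclass(frozen=True)
class FilterPolicy:
    """Insertion filters and classification thresholds.

    ``plus1_frame_offset_mod3`` selects which codon register counts as the
    "+1 frame" whose sense insertions are discarded; offset 0 corresponds to
    an insertion right at a codon boundary, aligning the transposon ATG with
    the gene's reading frame.
    """

    drop_plus1_frame_sense: bool = True
    plus1_frame_offset_mod3: int = 0
    drop_stop_codon: bool = True
    edge_window: int = 9
    #: apply the edge window to both ends for both orientations (stricter)
    edge_both: bool = False
    last_fraction_rule: float = 0.10
    gap_fraction_rule: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.last_fraction_rule < 1.0:
            raise ValueError("last_fraction_rule must be in (0, 1)")
        if not 0.0 < self.gap_fraction_rule < 1.0:
            raise ValueError("gap_fraction_rule must be in (0, 1)")
        if self.edge_window < 0:
            raise ValueError("edge_window must be >= 0")
        if self.plus1_frame_offset_mod3 not in (0, 1, 2):
            raise ValueError("plus1_frame_offset_mod3 must be 0, 1 or 2")


@dataclass
class GeneInsertionProfile:
    """Insertions of one gene: (offset from the gene's 5' end on its own
    strand, sense flag, read count)."""

    gene_id: str
    gene_length: int
    insertions: list[tuple[int, bool, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for off, _, _ in self.insertions:
            if not 0 <= off < self.gene_length:
                raise ValueError(
                    f"{self.gene_id}: offset {off} outside gene of "
                    f"length {self.gene_length}"
                )


@dataclass
class EssentialityCall:
    gene_id: str
    verdict: str
    n_insertions_after_filter: int
    largest_gap_fraction: float
    gene_type: str = "protein"


# ----------------------------------------------------------------- assignment

def assign_to_genes(site_table: pd.DataFrame, annotation: Sequence[GeneModel]
                    ) -> tuple[dict[str, GeneInsertionProfile], int, int]:
    """Assign sites to genes.

    A site within [start, end] of a gene contributes an insertion at offset
    ``position - start`` (plus-strand gene) or ``end - position``
    (minus-strand gene); sense means the site orientation equals the gene
    strand. Overlapping genes each receive the site independently.

    Returns (profiles keyed by gene_id, intragenic site count, intergenic
    site count); every gene gets a profile, hit or not.
    """
    genes = sorted(annotation, key=lambda g: (g.start, g.gene_id))
    profiles = {g.gene_id: GeneInsertionProfile(g.gene_id, g.length) for g in genes}
    starts = np.array([g.start for g in genes])
    max_len = max((g.length for g in genes), default=0)

    intragenic = intergenic = 0
    positions = site_table["position"].to_numpy()
    orientations = site_table["orientation"].to_numpy()
    read_counts = (site_table["read_count"].to_numpy()
                   if "read_count" in site_table else np.ones(len(site_table), int))

    for pos, orient, rc in zip(positions, orientations, read_counts):
        hit_any = False
        # genes overlapping pos start within max_len bp to its left
        lo = int(np.searchsorted(starts, pos - max_len, side="left"))
        hi = int(np.searchsorted(starts, pos, side="right"))
        for g in genes[lo:hi]:
            if g.start <= pos <= g.end:
                offset = pos - g.start if g.strand == "+" else g.end - pos
                sense = orient == g.strand
                profiles[g.gene_id].insertions.append((int(offset), bool(sense), int(rc)))
                hit_any = True
        if hit_any:
            intragenic += 1
        else:
            intergenic += 1
    return profiles, intragenic, intergenic


# -------------------------------------------------------------------- filters

def apply_filters(profile: GeneInsertionProfile, policy: FilterPolicy,
                  gene: GeneModel) -> GeneInsertionProfile:
    """Drop read-through-prone and edge insertions from one gene profile.

    Protein-coding genes lose: sense insertions in the +1 codon register,
    any insertion in the stop codon (last 3 bp), sense insertions in the
    last ``edge_window`` bp and antisense insertions in the first
    ``edge_window`` bp. RNA genes have no reading frame, so only the edge
    windows apply. Idempotent by construction.
    """
    L = profile.gene_length
    coding = gene.gene_type == "protein"
    kept = []
    for off, sense, rc in profile.insertions:
        if coding and policy.drop_plus1_frame_sense and sense \
                and off % 3 == policy.plus1_frame_offset_mod3:
            continue
        if coding and policy.drop_stop_codon and off >= L - 3:
            continue
        w = policy.edge_window
        if policy.edge_both:
            if off < w or off >= L - w:
                continue
        else:
            if sense and off >= L - w:
                continue
            if not sense and off < w:
                continue
        kept.append((off, sense, rc))
    return GeneInsertionProfile(profile.gene_id, L, kept)


# -------------------------------------------------------------- classification

def largest_gap(offsets: Sequence[int], gene_length: int) -> int:
    """Largest insertion-free interval in bp, counting the flanks from the
    gene start to the first insertion and from the last insertion to the
    gene end."""
    if not len(offsets):
        return gene_length
    o = np.sort(np.unique(np.asarray(offsets, dtype=int)))
    candidates = [int(o[0]), int(gene_length - 1 - o[-1])]
    if o.size > 1:
        candidates.append(int((np.diff(o) - 1).max()))
    return max(candidates)


def classify_gene(filtered: GeneInsertionProfile, gene: GeneModel,
                  policy: FilterPolicy) -> EssentialityCall:
    """Classify one gene from its post-filter insertion profile.

    Precedence: non-hit > last-10% > gap-80% > nonessential.
    """
    L = filtered.gene_length
    offsets = [off for off, _, _ in filtered.insertions]
    gap = largest_gap(offsets, L)
    gap_fraction = gap / L

    if not offsets:
        verdict = "essential_non_hit"
    elif min(offsets) >= (1.0 - policy.last_fraction_rule) * L:
        verdict = "essential_last10"
    elif gap >= policy.gap_fraction_rule * L:
        verdict = "essential_gap80"
    else:
        verdict = "nonessential"
    return EssentialityCall(
        gene_id=filtered.gene_id, verdict=verdict,
        n_insertions_after_filter=len(filtered.insertions),
        largest_gap_fraction=gap_fraction, gene_type=gene.gene_type,
    )


def call_essentiality(site_table: pd.DataFrame, annotation: Sequence[GeneModel],
                      policy: FilterPolicy | None = None) -> pd.DataFrame:
    """Assign, filter and classify every gene; returns a tidy calls table
    (gene_id, verdict, essential flag, n_insertions, largest_gap_fraction,
    gene_type)."""
    policy = policy or FilterPolicy()
    by_id = {g.gene_id: g for g in annotation}
    profiles, _, _ = assign_to_genes(site_table, annotation)
    rows = []
    for gid, profile in profiles.items():
        gene = by_id[gid]
        call = classify_gene(apply_filters(profile, policy, gene), gene, policy)
        rows.append((
            gid, call.verdict, call.verdict != "nonessential",
            call.n_insertions_after_filter, call.largest_gap_fraction,
            gene.gene_type,
        ))
    return pd.DataFrame(rows, columns=[
        "gene_id", "verdict", "essential", "n_insertions",
        "largest_gap_fraction", "gene_type",
    ]).sort_values("gene_id", ignore_index=True)


# -------------------------------------------------------------------- summary

@dataclass
class EssentialitySummary:
    n_genes: int
    n_essential: int
    n_essential_protein: int
    n_essential_rna: int
    percent_essential: int
    by_verdict: dict
    essential_gc_percent: float | None = None
    essential_mean_length_bp: float | None = None

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_calls(calls: pd.DataFrame, annotation: Sequence[GeneModel],
                    genome: str | None = None) -> EssentialitySummary:
    """Headline numbers of an essentiality screen: verdict counts by gene
    type, percent essential, and GC/length summaries of the essential
    protein-coding set computed from the genome sequence."""
    by_id = {g.gene_id: g for g in annotation}
    ess = calls[calls["essential"]]
    ess_protein = ess[ess["gene_type"] == "protein"]

    gc = mean_len = None
    if genome is not None and len(ess_protein):
        lengths, gc_counts, total = [], 0, 0
        for gid in ess_protein["gene_id"]:
            g = by_id[gid]
            seq = genome[g.start - 1: g.end]
            gc_counts += seq.count("G") + seq.count("C")
            total += len(seq)
            lengths.append(g.length)
        gc = 100.0 * gc_counts / total
        mean_len = float(np.mean(lengths))

    return EssentialitySummary(
        n_genes=len(calls),
        n_essential=int(ess.shape[0]),
        n_essential_protein=int(ess_protein.shape[0]),
        n_essential_rna=int((ess["gene_type"] == "RNA").sum()),
        percent_essential=percent(len(ess), len(calls)) if len(calls) else 0,
        by_verdict=calls["verdict"].value_counts().to_dict(),
        essential_gc_percent=gc,
        essential_mean_length_bp=mean_len,
    )
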