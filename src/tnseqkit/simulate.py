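"""Synthetic Tn-Seq data with known ground truth.

Emulates a pooled Tn5 mutagenesis experiment in a high-GC bacterium:

* a genome with operon-organised, non-overlapping genes on alternating
  strands, a configurable fraction of which is essential (placed both as
  single genes and as contiguous operon runs, mirroring the clustering of
  essential genes in real bacterial genomes);
* uniform transposon insertion with a 9-bp target-site duplication and an
  orientation-dependent viability rule — the transposon carries an internal
  promoter at its I end, so sense insertions can drive transcription of
  downstream operon members while antisense insertions are purely
  disruptive;
* log-normal mutant abundances, discrete Wright-Fisher passage through a
  bottleneck, and multiplicative per-generation selection exp(s);
* junction reads that start with the transposon O-end marker followed by
  genomic sequence reading away from the transposon body, with iid
  substitution errors.

Every random choice flows from a single seed, so identical configurations
produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, revcomp

# Tn5 mosaic-end-like marker used as the default O-end junction tag; the
# real vector sequences are experiment-specific, so both the marker and the
# semiarbitrary primers are plain configuration values.
DEFAULT_OEND_MARKER = "CTGTCTCTTATACACATCT"
DEFAULT_PRIMERS = ("GACCACGAGACGCCACACTG",)

POOL_COLUMNS = ["position", "orientation", "gene_id", "offset", "sense", "abundance"]


@dataclass
class SimulationConfig:
    """Study-level parameters of the simulated Tn-Seq experiment."""

    genome_length: int = 200_000
    gc_content: float = 0.68
    n_genes: int = 200
    #: probability of operon sizes 1..6
    operon_size_weights: Sequence[float] = (0.35, 0.25, 0.17, 0.11, 0.07, 0.05)
    rna_gene_fraction: float = 0.05
    essential_fraction: float = 0.15
    n_insertions: int = 8_000
    duplication_length: int = 9
    read_length: int = 150
    oend_marker: str = DEFAULT_OEND_MARKER
    primer_set: Sequence[str] = DEFAULT_PRIMERS
    per_base_error: float = 0.001
    library_size: int = 50_000
    n_replicates: int = 3
    generations: int = 20
    bottleneck: int = 100_000
    abundance_sigma: float = 1.0
    #: viability rescue for sense insertions in essential genes (off: any
    #: insertion inside an essential gene is lethal)
    sense_rescue: bool = False
    rescue_frame_mod3: int = 0
    #: fraction of nonessential genes with a conditional fitness effect
    conditional_fraction: float = 0.05
    #: fold abundance change over the whole selection episode for affected genes
    effect_fold: float = 4.0
    depleted_share: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "essential_fraction", "rna_gene_fraction",
                     "per_base_error", "conditional_fraction", "depleted_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.duplication_length < 0:
            raise ValueError("duplication_length must be >= 0")
        if self.read_length <= len(self.oend_marker):
            raise ValueError("read_length must exceed the O-end marker length")
        if self.genome_length < self.read_length + self.duplication_length:
            raise ValueError("genome too short for the configured read length")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Ground truth of a simulated mutant pool, for recovery tests."""

    true_sites: list[tuple[int, str]]
    essential_gene_ids: set[str]
    fitness: dict[str, dict[str, float]] = field(default_factory=dict)
    initial_abundances: dict[tuple[int, str], float] = field(default_factory=dict)


# --------------------------------------------------------------------- genome

def _sample_gene_lengths(n: int, is_rna: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # protein genes: log-normal around a ~1 kb bacterial mean; RNA genes short
    lengths = np.exp(rng.normal(6.802, 0.40, size=n))
    lengths = np.maximum(150, lengths.astype(int))
    lengths -= lengths % 3  # whole codons
    rna_len = rng.integers(80, 400, size=n)
    return np.where(is_rna, rna_len, lengths)


def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[str, list[GeneModel]]:
    """Random genome sequence plus an operon-structured annotation.

    Returns the genome (upper-case string) and a list of non-overlapping
    genes grouped into single-strand operons separated by short intergenic
    spacers. A fraction of genes is labelled essential, some as whole
    operons (contiguous runs) and some singly.

    Raises ValueError when the requested genes cannot fit in the genome.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_genes

    # base composition first so the sequence is independent of gene layout
    p = np.array([config.gc_content / 2] * 2 + [(1 - config.gc_content) / 2] * 2)
    genome = "".join(np.array(list("GCAT"))[rng.choice(4, size=config.genome_length, p=p)])

    if n == 0:
        return genome, []

    is_rna = rng.random(n) < config.rna_gene_fraction
    lengths = _sample_gene_lengths(n, is_rna, rng)

    # operon sizes
    weights = np.asarray(config.operon_size_weights, dtype=float)
    weights = weights / weights.sum()
    sizes: list[int] = []
    while sum(sizes) < n:
        sizes.append(int(rng.choice(len(weights), p=weights)) + 1)
    sizes[-1] -= sum(sizes) - n

    intra = rng.integers(5, 51, size=n)          # spacers inside an operon
    inter = rng.integers(60, 301, size=len(sizes) + 1)  # spacers between operons

    needed = int(lengths.sum()) + int(intra.sum()) + int(inter.sum())
    if needed > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} too short for {n} genes "
            f"(needs >= {needed} bp)"
        )
    # spread the slack over the inter-operon gaps so sites span the genome
    slack = config.genome_length - needed
    inter = inter + rng.multinomial(slack, np.full(len(inter), 1.0 / len(inter)))

    genes: list[GeneModel] = []
    pos = 1
    gi = 0
    for op_idx, size in enumerate(sizes):
        pos += int(inter[op_idx])
        strand = "+" if rng.random() < 0.5 else "-"
        members = range(gi, gi + size) if strand == "+" else range(gi + size - 1, gi - 1, -1)
        for j in members:
            start = pos
            end = pos + int(lengths[j]) - 1
            genes.append(GeneModel(
                gene_id=f"g{j:04d}",
                start=start,
                end=end,
                strand=strand,
                gene_type="RNA" if is_rna[j] else "protein",
                operon=op_idx,
            ))
            pos = end + 1 + int(intra[j])
        gi += size

    genes.sort(key=lambda g: g.start)

    # essential labels: whole operons first (contiguous runs), then singles
    quota = int(round(config.essential_fraction * n))
    essential_ids: set[str] = set()
    by_operon: dict[int, list[GeneModel]] = {}
    for g in genes:
        by_operon.setdefault(g.operon, []).append(g)
    operon_order = rng.permutation(sorted(by_operon))
    run_quota = int(round(0.6 * quota))
    for op in operon_order:
        members = by_operon[int(op)]
        if len(members) >= 2 and len(essential_ids) + len(members) <= run_quota:
            essential_ids.update(g.gene_id for g in members)
    remaining = [g.gene_id for g in genes if g.gene_id not in essential_ids]
    n_single = quota - len(essential_ids)
    if n_single > 0:
        essential_ids.update(rng.choice(remaining, size=min(n_single, len(remaining)),
                                        replace=False))

    genes = [replace(g, essential=g.gene_id in essential_ids) for g in genes]
    return genome, genes


# ----------------------------------------------------------------------- pool

def is_viable(position: int, orientation: str, gene: GeneModel | None,
              config: SimulationConfig) -> bool:
    """Viability rule: disrupting an essential gene is lethal, except under
    the optional sense-rescue rule (sense insertion in the configured codon
    register, letting promoter read-through preserve the operon)."""
    if gene is None or not gene.essential:
        return True
    if not config.sense_rescue:
        return False
    sense = orientation == gene.strand
    offset = position - gene.start if gene.strand == "+" else gene.end - position
    return sense and offset % 3 == config.rescue_frame_mod3


def simulate_insertion_library(genome: str, annotation: list[GeneModel],
                               config: SimulationConfig,
                               rng: np.random.Generator | None = None
                               ) -> tuple[pd.DataFrame, TruthSet]:
    """Draw candidate insertions uniformly, apply the viability rule, and
    assign log-normal abundances to the surviving mutants.

    Returns a pool table (position, orientation, gene_id, offset, sense,
    abundance; abundances sum to 1) and the matching :class:`TruthSet`.
    Candidate positions keep one read length clear of the sequence ends so
    simulated junction reads never cross the origin.
    """
    rng = config.rng() if rng is None else rng
    L = len(genome)
    margin = config.read_length + config.duplication_length
    if L <= 2 * margin:
        raise ValueError("genome too short for the configured read length")

    genes = sorted(annotation, key=lambda g: g.start)
    starts = np.array([g.start for g in genes])

    positions = rng.integers(margin + 1, L - margin + 1, size=config.n_insertions)
    orients = np.where(rng.random(config.n_insertions) < 0.5, "+", "-")

    rows = []
    seen: set[tuple[int, str]] = set()
    for pos, orient in zip(positions.tolist(), orients.tolist()):
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        gene = genes[idx] if idx >= 0 and genes[idx].end >= pos else None
        if not is_viable(pos, orient, gene, config):
            continue
        key = (pos, orient)
        if key in seen:  # collapse coincident candidates into one mutant
            continue
        seen.add(key)
        if gene is None:
            rows.append((pos, orient, None, -1, False))
        else:
            offset = pos - gene.start if gene.strand == "+" else gene.end - pos
            rows.append((pos, orient, gene.gene_id, offset, orient == gene.strand))

    pool = pd.DataFrame(rows, columns=POOL_COLUMNS[:-1])
    ab = np.exp(rng.normal(0.0, config.abundance_sigma, size=len(pool)))
    pool["abundance"] = ab / ab.sum() if len(pool) else ab
    pool = pool.sort_values(["position", "orientation"], ignore_index=True)

    truth = TruthSet(
        true_sites=list(zip(pool["position"].tolist(), pool["orientation"].tolist())),
        essential_gene_ids={g.gene_id for g in genes if g.essential},
        initial_abundances=dict(zip(
            zip(pool["position"].tolist(), pool["orientation"].tolist()),
            pool["abundance"].tolist(),
        )),
    )
    return pool, truth


# ------------------------------------------------------------------ selection

def simulate_selection(pool: pd.DataFrame, fitness: dict[str, float],
                       generations: int, config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       bottleneck: int | None = None) -> pd.DataFrame:
    """Wright-Fisher passage with multiplicative per-generation weights.

    ``fitness`` maps gene_id -> selection coefficient s; mutants whose
    insertion is intergenic (or whose gene is absent from the map) are
    neutral (s = 0). Each generation the pool is reweighted by exp(s) and
    multinomially resampled at the bottleneck size; ``bottleneck=None``
    gives the deterministic infinite-population limit. Abundances sum to 1
    after every generation.
    """
    rng = config.rng() if rng is None else rng
    if bottleneck is None:
        bottleneck = config.bottleneck
    if len(pool) == 0:
        return pool.copy()

    s = pool["gene_id"].map(lambda g: fitness.get(g, 0.0) if g else 0.0).to_numpy(float)
    w = np.exp(s)
    freq = pool["abundance"].to_numpy(float).copy()
    for _ in range(generations):
        freq = freq * w
        total = freq.sum()
        if total == 0:
            raise ValueError("pool went extinct during selection")
        freq /= total
        if bottleneck and np.isfinite(bottleneck):
            freq = rng.multinomial(int(bottleneck), freq) / float(bottleneck)
    out = pool.copy()
    out["abundance"] = freq
    return out


def draw_fitness(annotation: list[GeneModel], config: SimulationConfig,
                 rng: np.random.Generator) -> dict[str, float]:
    """Assign conditional fitness effects to a random subset of
    nonessential genes: |s| = ln(effect_fold)/generations so an affected
    mutant changes abundance ~effect_fold-fold over the episode."""
    candidates = [g.gene_id for g in annotation if not g.essential]
    k = int(round(config.conditional_fraction * len(candidates)))
    chosen = rng.choice(candidates, size=k, replace=False) if k else []
    mag = np.log(config.effect_fold) / max(config.generations, 1)
    fitness = {}
    for gid in chosen:
        sign = -1.0 if rng.random() < config.depleted_share else 1.0
        fitness[str(gid)] = sign * mag
    return fitness


# ---------------------------------------------------------------------- reads

_BASES = np.array(list("ACGT"))


def _junction_fragment(genome: str, position: int, orientation: str,
                       dup_len: int, frag_len: int) -> str:
    """Genomic part of a junction read for a site (position, orientation).

    Reads are sequenced out of the transposon O end, away from the
    transposon body. The site coordinate refers to the I-end-adjacent base,
    which sits ``dup_len - 1`` bp away from the O-end-adjacent first read
    base because the target duplication flanks the element:

    * orientation '-' (promoter pointing left): the read runs left-to-right
      on the plus strand starting at position - dup_len + 1;
    * orientation '+': the read runs right-to-left, i.e. minus strand,
      starting at position + dup_len - 1.
    """
    if orientation == "-":
        c0 = position - dup_len + 1
        return genome[c0 - 1: c0 - 1 + frag_len]
    c0 = position + dup_len - 1
    return revcomp(genome[c0 - frag_len: c0])


def simulate_reads(pool: pd.DataFrame, genome: str, config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   library_size: int | None = None,
                   prefix: str = "read") -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Multinomial junction reads from a mutant pool.

    Returns (reads, truth) where reads are (id, sequence) pairs — sequence =
    O-end marker + genomic fragment with iid substitution errors — and truth
    is the per-read sidecar (read_id, position, orientation).

    Raises ValueError for an empty pool or a read longer than the genome.
    """
    rng = config.rng() if rng is None else rng
    if len(pool) == 0:
        raise ValueError("pool is empty")
    if config.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    n_reads = config.library_size if library_size is None else library_size
    frag_len = config.read_length - len(config.oend_marker)
    e = config.per_base_error

    counts = rng.multinomial(n_reads, pool["abundance"].to_numpy(float))
    reads: list[tuple[str, str]] = []
    truth_rows = []
    serial = 0
    for (pos, orient), c in zip(
        zip(pool["position"].tolist(), pool["orientation"].tolist()), counts.tolist()
    ):
        if c == 0:
            continue
        frag = _junction_fragment(genome, pos, orient,
                                  config.duplication_length, frag_len)
        for _ in range(c):
            seq = frag
            if e > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1")
                hit = np.flatnonzero(rng.random(len(seq)) < e)
                if hit.size:
                    arr = arr.copy()
                    subs = _BASES[rng.integers(0, 4, size=hit.size)]
                    # force a real substitution, never the same base
                    for i, b in zip(hit, subs):
                        arr[i] = b.encode() if b != arr[i].decode() else \
                            _BASES[(np.flatnonzero(_BASES == arr[i].decode())[0] + 1) % 4].encode()
                    seq = arr.tobytes().decode()
            read_id = f"{prefix}.{serial:07d}"
            reads.append((read_id, config.oend_marker + seq))
            truth_rows.append((read_id, pos, orient))
            serial += 1
    truth = pd.DataFrame(truth_rows, columns=["read_id", "position", "orientation"])
    return reads, truth


# ----------------------------------------------------------------- experiment

def simulate_experiment(config: SimulationConfig,
                        conditions: Sequence[str] = ("selection",),
                        ) -> dict:
    """Full study: master pool -> neutral bottleneck passage -> selective
    growth per condition -> replicate read libraries.

    Replicates are independent read samplings of the same selected pool
    (DNA-extraction replicates). Returns a dict with the genome, annotation,
    pools, per-sample reads/truth sidecars and the fitness ground truth.
    """
    rng = config.rng()
    genome, annotation = generate_genome(config, rng)
    master, truth = simulate_insertion_library(genome, annotation, config, rng)
    passaged = simulate_selection(master, {}, config.generations, config, rng)

    pools = {"master": master, "input": passaged}
    for cond in conditions:
        fit = draw_fitness(annotation, config, rng)
        truth.fitness[cond] = fit
        pools[cond] = simulate_selection(passaged, fit, config.generations, config, rng)

    samples: dict[str, tuple[list[tuple[str, str]], pd.DataFrame]] = {}
    empty_truth = pd.DataFrame(columns=["read_id", "position", "orientation"])
    for cond in ["input", *conditions]:
        live = pools[cond][pools[cond]["abundance"] > 0]
        for rep in range(1, config.n_replicates + 1):
            name = f"{cond}_rep{rep}"
            samples[name] = (
                simulate_reads(live, genome, config, rng, prefix=name)
                if len(live) else ([], empty_truth.copy())
            )

    return {
        "genome": genome,
        "annotation": annotation,
        "pools": pools,
        "samples": samples,
        "truth": truth,
        "conditions": list(conditions),
    }
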