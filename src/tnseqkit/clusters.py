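"""Run-length clustering of essential genes with a Monte-Carlo null.

Essential genes in bacteria tend to sit in operons, so runs of consecutive
putatively essential protein-coding genes along the chromosome are tested
against the null that essential labels are randomly ordered: the observed
binary label sequence is permuted ``n_perm`` times and, for each run length
n, p(n) estimates the probability that a random ordering contains at least
one run of >= n essential genes. One hypothesis is tested per distinct
observed cluster length, with step-down Holm control of the family-wise
error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ClusterResult:
    start_index: int  # 0-based index into the gene order
    length: int
    p_value: float
    holm_significant: bool


# ----------------------------------------------------------------------- runs

def find_clusters(labels: Sequence[int] | np.ndarray,
                  circular: bool = False) -> list[tuple[int, int]]:
    """Maximal runs of 1s as (start_index, length), in order of start.

    With ``circular=True`` a run crossing the end wraps around and is
    reported once, starting at its true first index.
    """
    x = np.asarray(labels, dtype=int)
    if x.size == 0:
        return []
    if not np.isin(x, (0, 1)).all():
        raise ValueError("labels must be binary")
    padded = np.concatenate(([0], x, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    if circular and len(runs) > 1 and x[0] == 1 and x[-1] == 1:
        first, last = runs[0], runs[-1]
        runs = [(last[0], last[1] + first[1])] + runs[1:-1]
    elif circular and len(runs) == 1 and x.all():
        pass  # a single all-ones run already covers the circle
    return runs


def max_run_length(labels: Sequence[int] | np.ndarray) -> int:
    runs = find_clusters(labels)
    return max((length for _, length in runs), default=0)


# ---------------------------------------------------------------- permutation

def _max_runs_null(n_genes: int, n_essential: int, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Maximal run length of each of ``n_perm`` uniform label shuffles.

    A shuffle is summarised by the sorted positions of the 1s; the longest
    run is one plus the longest streak of consecutive positions.
    """
    out = np.zeros(n_perm, dtype=np.int32)
    if n_essential == 0:
        return out
    for i in range(n_perm):
        pos = rng.permutation(n_genes)[:n_essential]
        pos.sort()
        if n_essential == 1:
            out[i] = 1
            continue
        consec = np.diff(pos) == 1
        if not consec.any():
            out[i] = 1
            continue
        padded = np.concatenate(([0], consec.view(np.int8), [0]))
        d = np.diff(padded)
        streak = (np.flatnonzero(d == -1) - np.flatnonzero(d == 1)).max()
        out[i] = streak + 1
    return out


def permutation_pvalues(n_genes: int, n_essential: int,
                        lengths: Iterable[int], n_perm: int = 100_000,
                        seed: int | np.random.Generator = 0) -> dict[int, float]:
    """Monte-Carlo p-values p(n) = P(some run of >= n under random order).

    Uses the add-one estimator (count + 1) / (n_perm + 1), which never
    returns 0 and counts the observed arrangement as one permutation.
    Lengths exceeding ``n_essential`` can never occur and get the add-one
    floor. p(n) is non-increasing in n.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lengths = sorted(set(int(n) for n in lengths))
    if any(n < 1 or n > n_genes for n in lengths):
        raise ValueError("run lengths must lie in 1..n_genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxruns = _max_runs_null(n_genes, n_essential, n_perm, rng)
    return {
        n: (int(np.count_nonzero(maxruns >= n)) + 1) / (n_perm + 1)
        for n in lengths
    }


# ----------------------------------------------------------------------- Holm

def holm_adjust(pvals: Mapping[int, float], alpha: float = 0.05) -> dict[int, bool]:
    """Step-down Holm decisions over one hypothesis per tested length.

    Sorted ascending, the i-th smallest p (1-based) is compared to
    alpha / (m - i + 1); rejection stops at the first failure.
    """
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    decisions: dict[int, bool] = {}
    failed = False
    for i, (length, p) in enumerate(items, start=1):
        if not failed and p <= alpha / (m - i + 1):
            decisions[length] = True
        else:
            failed = True
            decisions[length] = False
    return decisions


def call_significant_clusters(clusters: Sequence[tuple[int, int]],
                              pvals: Mapping[int, float],
                              significance: Mapping[int, bool]) -> list[ClusterResult]:
    """Flag each observed cluster by the Holm decision for its length."""
    return [
        ClusterResult(start_index=start, length=length,
                      p_value=pvals[length],
                      holm_significant=bool(significance[length]))
        for start, length in clusters
    ]


def min_significant_length(significance: Mapping[int, bool]) -> int | None:
    sig = [n for n, ok in significance.items() if ok]
    return min(sig) if sig else None


# ------------------------------------------------------------------- pipeline

def cluster_analysis(labels: Sequence[int], n_perm: int = 100_000,
                     alpha: float = 0.05,
                     seed: int | np.random.Generator = 0) -> dict:
    """End-to-end cluster significance for a binary essential-label sequence
    in genomic order (protein-coding genes only, by convention)."""
    x = np.asarray(labels, dtype=int)
    clusters = find_clusters(x)
    observed_lengths = sorted({length for _, length in clusters})
    if not observed_lengths:
        return {"clusters": [], "pvalues": {}, "significance": {},
                "min_significant_length": None}
    pvals = permutation_pvalues(len(x), int(x.sum()), observed_lengths,
                                n_perm=n_perm, seed=seed)
    significance = holm_adjust(pvals, alpha=alpha)
    results = call_significant_clusters(clusters, pvals, significance)
    return {
        "clusters": results,
        "pvalues": pvals,
        "significance": significance,
        "min_significant_length": min_significant_length(significance),
    }


def clusters_to_frame(results: Sequence[ClusterResult],
                      gene_ids: Sequence[str]) -> pd.DataFrame:
    rows = [
        (gene_ids[r.start_index], gene_ids[r.start_index + r.length - 1],
         r.length, r.p_value, r.holm_significant)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "start_gene", "end_gene", "length", "p_value", "significant",
    ])
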