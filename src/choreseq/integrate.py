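"""Linking binding to regulation: running-sum KS enrichment of ChIP targets
within a ranked expression list, its permutation/exact significance, the
up/down split of bound differentially expressed genes, and hypergeometric
over-representation against gene sets.

The enrichment walk visits the ranked list top to bottom, adding 1/Nh at each
target ("hit") and subtracting 1/(N-Nh) at each non-target, so the sum ends
exactly at 0; the enrichment score ES is the maximum prefix value (top
enrichment), with the minimum reported separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, islice
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DifferentialExpressionResults, de_gene_list


@dataclass
class EnrichmentResult:
    """Running-sum KS enrichment of a target set in a ranked gene list."""

    N: int
    Nh: int
    running_sum: np.ndarray  # prefix sums S_1..S_N; S_N == 0
    es: float
    es_min: float
    hit_ranks: np.ndarray  # 1-based ranks of the targets
    leading_edge: list[str]
    p_perm: float | None = None
    p_exact: float | None = None

    def summary(self) -> str:
        lines = [
            "Running-sum KS enrichment",
            f"  N = {self.N} ranked genes, Nh = {self.Nh} targets in list",
            f"  ES = {self.es:.4f} (min {self.es_min:.4f})",
            f"  leading edge: {len(self.leading_edge)} genes",
        ]
        if self.p_perm is not None:
            lines.append(f"  permutation p = {self.p_perm:.3g}")
        if self.p_exact is not None:
            lines.append(f"  exact p = {self.p_exact:.3g}")
        return "\n".join(lines)

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.N + 1),
                "running_sum": self.running_sum,
            }
        )


def ks_enrichment(
    ranked_list: Sequence[str], target_set: Iterable[str]
) -> EnrichmentResult:
    """Walk the ranked list: hit -> +1/Nh, miss -> -1/(N-Nh); ES = max prefix.

    The target set must intersect the list but not cover it (otherwise the
    step sizes are undefined).
    """
    ranked = list(ranked_list)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicate gene ids")
    targets = set(target_set)
    N = len(ranked)
    is_hit = np.array([g in targets for g in ranked])
    Nh = int(is_hit.sum())
    if Nh == 0:
        raise ValueError("no target gene appears in the ranked list")
    if Nh == N:
        raise ValueError("target set covers the entire ranked list")
    steps = np.where(is_hit, 1.0 / Nh, -1.0 / (N - Nh))
    running = np.cumsum(steps)
    es = float(max(running.max(), 0.0))
    es_min = float(min(running.min(), 0.0))
    hit_ranks = np.flatnonzero(is_hit) + 1
    if es > 0:
        k_max = int(np.argmax(running)) + 1  # first argmax, 1-based
        leading = [g for g, h, r in zip(ranked, is_hit, range(1, N + 1)) if h and r <= k_max]
    else:
        leading = []
    return EnrichmentResult(
        N=N, Nh=Nh, running_sum=running, es=es, es_min=es_min,
        hit_ranks=hit_ranks, leading_edge=leading,
    )


def _es_from_hit_ranks(hit_ranks: np.ndarray, N: int, Nh: int) -> np.ndarray:
    """Vectorised ES for batches of hit-rank sets, shape (batch, Nh).

    The running sum attains its maximum immediately after a hit (or at 0), so
    ES = max(0, max_i(i/Nh - (r_(i) - i)/(N - Nh))) over sorted hit ranks.
    """
    r = np.sort(hit_ranks, axis=-1)
    i = np.arange(1, Nh + 1, dtype=float)
    vals = i / Nh - (r - i) / (N - Nh)
    return np.maximum(vals.max(axis=-1), 0.0)


def ks_significance(
    result: EnrichmentResult,
    n_perm: int = 10_000,
    seed: int = 0,
    exact_limit: float = 1e6,
) -> EnrichmentResult:
    """Permutation and (when feasible) exact p-values for the observed ES.

    The null places the Nh targets uniformly at random among the N ranks
    (gene-label permutation).  p_perm uses the add-one estimator
    (1 + #{ES* >= ES}) / (1 + n_perm); p_exact enumerates all C(N, Nh)
    placements when that count is at most ``exact_limit``.  The result object
    is updated in place and returned.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    N, Nh, es = result.N, result.Nh, result.es
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, int(5e6) // max(N, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        noise = rng.random((b, N))
        ranks = np.argpartition(noise, Nh - 1, axis=1)[:, :Nh] + 1
        es_null = _es_from_hit_ranks(ranks, N, Nh)
        count += int((es_null >= es - 1e-12).sum())
        done += b
    result.p_perm = (1 + count) / (1 + n_perm)
    total = math.comb(N, Nh)
    if total <= exact_limit:
        n_ge = 0
        it = combinations(range(1, N + 1), Nh)
        while True:
            block = list(islice(it, 20_000))
            if not block:
                break
            arr = np.asarray(block, dtype=np.int64)
            n_ge += int((_es_from_hit_ranks(arr, N, Nh) >= es - 1e-12).sum())
        result.p_exact = n_ge / total
    return result


def split_targets_by_direction(
    target_genes: Iterable[str],
    de_results: DifferentialExpressionResults,
    ppde_cutoff: float = 0.95,
) -> tuple[int, int, set[str], set[str]]:
    """Among targets that are significantly differentially expressed, count
    how many go up and how many go down (the activator/repressor split)."""
    up_all, down_all = de_gene_list(de_results, ppde_cutoff=ppde_cutoff)
    targets = set(target_genes)
    up = targets & up_all
    down = targets & down_all
    return len(up), len(down), up, down


def ora_hypergeometric(
    target_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of targets in each set.

    Sets are intersected with the universe; the returned table has one row
    per set with overlap count, expected overlap, upper-tail p-value and
    Benjamini-Hochberg FDR.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_genes) & universe
    n = len(targets)
    M = len(universe)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & universe)
        k = len(set(members) & targets)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": k,
                "expected": n * K / M,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "expected", "p"])
    if len(table):
        table["fdr"] = stats.false_discovery_control(table["p"], method="bh")
    else:
        table["fdr"] = []
    return table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
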