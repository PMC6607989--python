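"""Gene-set burden statistics for low-frequency variants.

Two bespoke statistics:

1. A permutation enrichment test: the observed gene set's low-frequency
   variant density (variants per base of the longest isoform's exons) is
   compared against the null distribution obtained by drawing random gene
   sets of the same size from the annotated universe.
2. A null-variant (loss-of-function: stop-gain or frameshift) proportion
   comparison between two variant collections, tested by the
   maximum-likelihood (G) chi-square on the 2x2 table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import Consequence, GeneModel, Variant

__all__ = [
    "TieRule",
    "PermutationConfig",
    "PermutationResult",
    "longest_isoform_length",
    "variant_density",
    "permutation_enrichment",
    "classify_null",
    "gtest_2x2",
]

#: Consequences abolishing the protein product.
NULL_CONSEQUENCES = frozenset({Consequence.stop_gained, Consequence.frameshift})


class TieRule(str, enum.Enum):
    """How replicates tying the observed statistic enter the empirical p.

    ``strictly_greater`` counts only replicates exceeding the observation
    (can return p = 0); ``greater_or_equal`` counts ties as extreme;
    ``plus_one`` is the (r + 1) / (n + 1) estimator with r the number of
    replicates >= the observation, which never returns 0 and is uniform
    under the null.
    """

    strictly_greater = "strictly_greater"
    greater_or_equal = "greater_or_equal"
    plus_one = "plus_one"


class Statistic(str, enum.Enum):
    density = "density"  # variants per exonic base (length-normalized)
    count = "count"      # raw variant count


@dataclass
class PermutationConfig:
    set_size: int = 107
    n_perm: int = 1000
    tie_rule: TieRule = TieRule.strictly_greater
    statistic: Statistic = Statistic.density
    exclude_observed_genes: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")


@dataclass
class PermutationResult:
    observed_density: float
    null_densities: np.ndarray
    empirical_p: float
    tie_rule: TieRule
    statistic: Statistic
    seed: int | None

    def summary(self) -> dict:
        nd = np.asarray(self.null_densities, dtype=float)
        return {
            "observed": self.observed_density,
            "empirical_p": self.empirical_p,
            "tie_rule": self.tie_rule.value,
            "statistic": self.statistic.value,
            "n_perm": int(nd.size),
            "null_mean": float(nd.mean()),
            "null_sd": float(nd.std(ddof=1)) if nd.size > 1 else 0.0,
            "seed": self.seed,
        }


def longest_isoform_length(gene_model: GeneModel) -> int:
    """Total exon length of the isoform maximizing total exonic length.

    Ties are broken deterministically toward the lexicographically lowest
    isoform id.
    """
    if not gene_model.isoforms:
        raise ValueError(f"gene {gene_model.gene} has no isoforms")
    best = min(
        gene_model.isoforms,
        key=lambda iso: (-sum(e - s for s, e in iso[2]), iso[0]),
    )
    return sum(e - s for s, e in best[2])


def variant_density(
    variant_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    gene_set: Sequence[str],
) -> float:
    """Low-frequency variants per exonic base over a gene set.

    Sum of per-gene variant counts divided by the sum of longest-isoform
    exon lengths across the set.
    """
    total_len = 0
    total_count = 0
    for g in gene_set:
        if g not in lengths:
            raise KeyError(f"gene {g!r} has no exon length")
        total_len += lengths[g]
        total_count += variant_counts.get(g, 0)
    if total_len <= 0:
        raise ValueError("zero total exon length in gene set")
    return total_count / total_len


def empirical_pvalue(observed: float, null: np.ndarray, tie_rule: TieRule) -> float:
    null = np.asarray(null, dtype=float)
    n = null.size
    if tie_rule is TieRule.strictly_greater:
        return float(np.count_nonzero(null > observed) / n)
    if tie_rule is TieRule.greater_or_equal:
        return float(np.count_nonzero(null >= observed) / n)
    return float((np.count_nonzero(null >= observed) + 1) / (n + 1))


def permutation_enrichment(
    observed_set: Sequence[str],
    universe: Sequence[GeneModel],
    variant_counts: Mapping[str, int],
    config: PermutationConfig | None = None,
) -> PermutationResult:
    """Permutation test of variant burden in a gene set against random sets.

    Draws ``n_perm`` uniform random gene subsets of size ``set_size``
    without replacement (independently across replicates), computes the
    burden statistic for each, and returns the empirical p-value of the
    observed set's statistic under the configured tie rule.
    """
    config = config or PermutationConfig()
    lengths = {gm.gene: longest_isoform_length(gm) for gm in universe}
    observed = list(observed_set)
    unknown = [g for g in observed if g not in lengths]
    if unknown:
        raise KeyError(f"observed genes not in universe: {unknown[:5]}")

    pool = list(lengths)
    if config.exclude_observed_genes:
        obs_set = set(observed)
        pool = [g for g in pool if g not in obs_set]
    if config.set_size > len(pool):
        raise ValueError(
            f"set_size {config.set_size} exceeds available universe ({len(pool)})"
        )

    if config.statistic is Statistic.density:
        observed_stat = variant_density(variant_counts, lengths, observed)
    else:
        observed_stat = float(sum(variant_counts.get(g, 0) for g in observed))

    rng = np.random.default_rng(config.seed)
    count_arr = np.array([variant_counts.get(g, 0) for g in pool], dtype=float)
    len_arr = np.array([lengths[g] for g in pool], dtype=float)
    null = np.empty(config.n_perm, dtype=float)
    for i in range(config.n_perm):
        idx = rng.choice(len(pool), size=config.set_size, replace=False)
        if config.statistic is Statistic.density:
            null[i] = count_arr[idx].sum() / len_arr[idx].sum()
        else:
            null[i] = count_arr[idx].sum()
    p = empirical_pvalue(observed_stat, null, config.tie_rule)
    return PermutationResult(
        observed_density=observed_stat,
        null_densities=null,
        empirical_p=p,
        tie_rule=config.tie_rule,
        statistic=config.statistic,
        seed=config.seed,
    )


def classify_null(variant: Variant) -> bool:
    """True iff the variant abolishes the protein (stop-gain or frameshift).

    Start-loss is not counted: it removes initiation from one transcript
    model rather than truncating the product, and is screened with the
    missense set.
    """
    return variant.consequence in NULL_CONSEQUENCES


def gtest_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Maximum-likelihood (G) chi-square test of independence on a 2x2 table.

    ``G = 2 * sum O * ln(O / E)`` with expected counts from the margins;
    the p-value is the upper chi-square tail with 1 df.  Zero cells
    contribute nothing (0 * ln 0 = 0); degenerate margins raise.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate margins in 2x2 table")
    expected = np.outer(row, col) / n
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    p = float(stats.chi2.sf(g, df=1))
    return g, p
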