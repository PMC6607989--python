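"""Permutation burden test, isoform lengths, null classification, G-test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rarevar.burden import (
    PermutationConfig,
    Statistic,
    TieRule,
    classify_null,
    empirical_pvalue,
    gtest_2x2,
    longest_isoform_length,
    permutation_enrichment,
    variant_density,
)
from rarevar.io_formats import Consequence, GeneModel, Variant
from rarevar.synthetic_data import load_fixture


def _gm(gene, lengths_by_iso):
    isoforms = []
    for iso, L in lengths_by_iso.items():
        isoforms.append((iso, "+", [(0, L)]))
    return GeneModel(gene, isoforms)


class TestLongestIsoform:
    def test_maximum_over_isoforms(self):
        gm = GeneModel(
            "G",
            [
                ("a", "+", [(0, 100), (200, 250), (300, 325)]),  # 175
                ("b", "+", [(0, 300)]),
            ],
        )
        assert longest_isoform_length(gm) == 300

    def test_single_exon(self):
        assert longest_isoform_length(_gm("G", {"a": 538})) == 538

    def test_tie_breaks_to_lowest_isoform_id(self):
        gm = GeneModel("G", [("b", "+", [(0, 100)]), ("a", "+", [(50, 150)])])
        best = min(gm.isoforms, key=lambda iso: (-sum(e - s for s, e in iso[2]), iso[0]))
        assert best[0] == "a" and longest_isoform_length(gm) == 100


class TestVariantDensity:
    def test_sum_counts_over_sum_lengths(self):
        assert variant_density({"g1": 3, "g2": 0}, {"g1": 100, "g2": 100}, ["g1", "g2"]) == pytest.approx(0.015)

    def test_genes_without_counts_contribute_zero(self):
        assert variant_density({}, {"g1": 100}, ["g1"]) == 0.0

    def test_single_gene(self):
        assert variant_density({"g1": 2}, {"g1": 538}, ["g1"]) == pytest.approx(2 / 538)

    def test_zero_length_is_error(self):
        with pytest.raises(KeyError):
            variant_density({}, {}, ["g1"])


def _tiny_universe():
    # four genes, equal exon length 100
    models = [_gm(f"g{i}", {f"g{i}.1": 100}) for i in range(1, 5)]
    counts = {"g1": 3, "g2": 1, "g3": 0, "g4": 2}
    return models, counts


def _exhaustive_p(counts, lengths, observed, set_size, tie_rule):
    """Enumeration oracle: every subset of the universe, equally likely."""
    obs = sum(counts[g] for g in observed) / sum(lengths[g] for g in observed)
    null = [
        sum(counts[g] for g in combo) / sum(lengths[g] for g in combo)
        for combo in itertools.combinations(sorted(lengths), set_size)
    ]
    null = np.array(null)
    if tie_rule is TieRule.strictly_greater:
        return float((null > obs).mean())
    # plus_one converges to the tie-inclusive proportion as n_perm grows
    return float((null >= obs).mean())


class TestPermutation:
    def test_exhaustive_oracle_small_universe(self):
        models, counts = _tiny_universe()
        cfg = PermutationConfig(set_size=2, n_perm=1000, seed=11)
        res = permutation_enrichment(["g2", "g3"], models, counts, cfg)
        assert res.observed_density == pytest.approx(1 / 200)
        exact = 5 / 6  # 5 of the 6 two-gene subsets have higher density
        sd = math.sqrt(exact * (1 - exact) / cfg.n_perm)
        assert abs(res.empirical_p - exact) <= 3 * sd

    @pytest.mark.parametrize("tie_rule", list(TieRule))
    def test_monte_carlo_converges_to_enumeration_all_rules(self, tie_rule, rng):
        for trial in range(5):
            n_genes = int(rng.integers(4, 8))
            lengths = {f"g{i}": int(rng.integers(50, 500)) for i in range(n_genes)}
            counts = {f"g{i}": int(rng.integers(0, 5)) for i in range(n_genes)}
            models = [_gm(g, {f"{g}.1": L}) for g, L in lengths.items()]
            k = int(rng.integers(1, n_genes))
            observed = list(rng.choice(sorted(lengths), size=k, replace=False))
            exact = _exhaustive_p(counts, lengths, observed, k, tie_rule)
            cfg = PermutationConfig(
                set_size=k, n_perm=2000, tie_rule=tie_rule, seed=int(rng.integers(2**31))
            )
            res = permutation_enrichment(observed, models, counts, cfg)
            tol = 3 * math.sqrt(max(exact * (1 - exact), 1e-4) / cfg.n_perm)
            if tie_rule is TieRule.plus_one:
                tol += 1.0 / (cfg.n_perm + 1)  # finite-sample offset of (r+1)/(n+1)
            assert abs(res.empirical_p - exact) <= tol

    def test_unique_maximum_gives_zero_under_strict_rule(self):
        models, counts = _tiny_universe()
        cfg = PermutationConfig(set_size=2, n_perm=500, seed=3)
        res = permutation_enrichment(["g1", "g4"], models, counts, cfg)  # density 5/200, max
        assert res.empirical_p == 0.0

    def test_degenerate_universe_gives_zero_under_strict_rule(self):
        models = [_gm(f"g{i}", {f"g{i}.1": 100}) for i in range(6)]
        counts = {f"g{i}": 2 for i in range(6)}
        cfg = PermutationConfig(set_size=3, n_perm=200, seed=1)
        res = permutation_enrichment(["g0", "g1", "g2"], models, counts, cfg)
        assert res.empirical_p == 0.0
        assert empirical_pvalue(res.observed_density, res.null_densities, TieRule.plus_one) == 1.0

    def test_seed_determinism(self):
        models, counts = _tiny_universe()
        cfg = PermutationConfig(set_size=2, n_perm=300, seed=42)
        a = permutation_enrichment(["g2", "g3"], models, counts, cfg)
        b = permutation_enrichment(["g2", "g3"], models, counts, cfg)
        assert np.array_equal(a.null_densities, b.null_densities)
        assert a.empirical_p == b.empirical_p

    def test_set_size_larger_than_universe_is_error(self):
        models, counts = _tiny_universe()
        with pytest.raises(ValueError, match="set_size"):
            permutation_enrichment(
                ["g1"], models, counts, PermutationConfig(set_size=10, n_perm=10)
            )

    def test_exclude_observed_genes_shrinks_pool(self):
        models, counts = _tiny_universe()
        cfg = PermutationConfig(set_size=2, n_perm=400, seed=5, exclude_observed_genes=True)
        res = permutation_enrichment(["g1", "g4"], models, counts, cfg)
        # remaining pool is {g2, g3}: the only draw has density 1/200 < 5/200
        assert res.empirical_p == 0.0
        assert set(np.unique(res.null_densities)) == {1 / 200}

    def test_raw_count_statistic(self):
        models, counts = _tiny_universe()
        cfg = PermutationConfig(set_size=2, n_perm=200, seed=9, statistic=Statistic.count)
        res = permutation_enrichment(["g2", "g3"], models, counts, cfg)
        assert res.observed_density == 1.0  # raw count of variants in the set


class TestClassifyNull:
    def test_table_of_c6orf10_variants_has_four_nulls(self):
        records = load_fixture("table7_c6orf10")
        nulls = [r["aa_change"] for r in records if classify_null(r["variant"])]
        assert sorted(nulls) == ["Gly451stop", "Lys457stop", "Ser389Xfr", "Ser454Xfr"]

    @pytest.mark.parametrize(
        "csq,expected",
        [
            (Consequence.missense, False),
            (Consequence.stop_gained, True),
            (Consequence.frameshift, True),
            (Consequence.start_lost, False),  # screened with the missense set
            (Consequence.synonymous, False),
        ],
    )
    def test_consequence_classes(self, csq, expected):
        v = Variant("1", 10, "A", "G", consequence=csq)
        assert classify_null(v) is expected


class TestGTest:
    def _oracle(self, a, b, c, d):
        obs = np.array([[a, b], [c, d]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        g = 2 * sum(
            o * math.log(o / e) for o, e in zip(obs.ravel(), exp.ravel()) if o > 0
        )
        # chi-square(1) upper tail via the normal tail identity
        p = math.erfc(math.sqrt(g / 2.0))
        return g, p

    @pytest.mark.parametrize("table", [(4, 10, 24, 277), (4, 10, 20, 251)])
    def test_against_closed_form_oracle(self, table):
        g, p = gtest_2x2(*table)
        g0, p0 = self._oracle(*table)
        assert g == pytest.approx(g0) and p == pytest.approx(p0)

    def test_published_style_tables(self):
        g1, p1 = gtest_2x2(4, 10, 24, 277)
        assert g1 == pytest.approx(4.80, abs=0.01) and p1 == pytest.approx(0.029, abs=0.001)
        g2, p2 = gtest_2x2(4, 10, 20, 251)
        assert g2 == pytest.approx(5.20, abs=0.01) and p2 == pytest.approx(0.023, abs=0.001)

    def test_proportional_table_is_independent(self):
        g, p = gtest_2x2(1, 1, 10, 10)
        assert g == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_cell_handled_degenerate_margin_raises(self):
        g, p = gtest_2x2(0, 10, 5, 5)  # zero cell ok
        assert g > 0
        with pytest.raises(ValueError, match="margin"):
            gtest_2x2(0, 0, 5, 5)

    def test_close_to_pearson_on_large_near_independent_tables(self, rng):
        # under (approximate) independence with all cells large, G and
        # Pearson's chi-square agree closely
        for _ in range(10):
            pr, pc = rng.uniform(0.3, 0.7, size=2)
            probs = np.outer([pr, 1 - pr], [pc, 1 - pc]).ravel()
            table = rng.multinomial(5000, probs)
            assert table.min() >= 100
            g, _ = gtest_2x2(*table)
            chi2 = stats.chi2_contingency(table.reshape(2, 2), correction=False)[0]
            if chi2 > 0.05:
                assert abs(g - chi2) / max(chi2, g) < 0.02
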