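"""Family filtering cascade: read-fraction calling, MAF filter, segregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarevar.family_filter import (
    FilterConfig,
    assess_segregation,
    call_from_reads,
    filter_low_frequency,
    select_candidates,
)
from rarevar.io_formats import Consequence, Genotype, Individual, Pedigree, Variant
from rarevar.synthetic_data import (
    SimSpec,
    gen_families,
    load_fixture,
    table4_genotype_map,
)


class TestCallFromReads:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (30, 20, Genotype.het),      # 40% boundary is inclusive
            (30, 0, Genotype.hom_ref),
            (2, 38, Genotype.hom_alt),   # 95% >= hom-alt boundary 0.85
            (61, 39, Genotype.hom_ref),  # just below 40%
            (15, 85, Genotype.hom_alt),  # exactly at 0.85
        ],
    )
    def test_fraction_thresholds(self, ref, alt, expected):
        assert call_from_reads(ref, alt) is expected

    def test_zero_total_reads_is_missing_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert call_from_reads(0, 0) is Genotype.missing
        assert "zero total reads" in caplog.text

    @given(
        ref=st.integers(0, 500),
        alt=st.integers(0, 500),
        lo=st.floats(0.1, 0.5),
        hi=st.floats(0.55, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_raising_het_threshold_never_adds_carriers(self, ref, alt, lo, hi):
        if ref + alt == 0:
            return
        loose = FilterConfig(het_fraction_min=lo, hom_alt_fraction_min=hi)
        strict = FilterConfig(het_fraction_min=min(lo + 0.1, hi - 1e-6), hom_alt_fraction_min=hi)
        if call_from_reads(ref, alt, strict).is_carrier:
            assert call_from_reads(ref, alt, loose).is_carrier


def _variant(gene="MALT1", maf_pct=None, csq=Consequence.missense):
    freqs = {} if maf_pct is None else {"dbsnp": maf_pct / 100.0}
    return Variant("1", 100, "A", "G", gene=gene, consequence=csq, ref_freqs=freqs)


class TestLowFrequencyFilter:
    def test_threshold_keeps_and_removes(self):
        kept = filter_low_frequency(
            [
                _variant("MALT1", 3.734),          # below 4% -> kept
                _variant("MALT1", 5.0),            # above -> removed
                _variant("STAT4", None),           # novel -> kept
                _variant("MALT1", 1.0, Consequence.intronic),  # wrong class
                _variant("NOTCAND", 1.0),          # not a candidate gene
            ],
            {"MALT1", "STAT4"},
        )
        assert [v.gene for v in kept] == ["MALT1", "STAT4"]
        assert kept[0].ref_freqs["dbsnp"] == pytest.approx(0.03734)

    def test_empty_candidate_set_is_config_error(self):
        with pytest.raises(ValueError, match="candidate"):
            filter_low_frequency([_variant()], set())

    def test_raising_maf_max_is_monotone(self):
        variants = [_variant(maf_pct=p) for p in (0.5, 2.0, 3.9, 4.5, 8.0)]
        kept_tight = filter_low_frequency(variants, {"MALT1"}, FilterConfig(maf_max=0.02))
        kept_loose = filter_low_frequency(variants, {"MALT1"}, FilterConfig(maf_max=0.05))
        assert set(id(v) for v in kept_tight) <= set(id(v) for v in kept_loose)


def _fig1():
    return load_fixture("fig1_pedigree_derived")


class TestSegregation:
    def test_affected_parent_child_pair_is_transmitted(self):
        ped = _fig1()
        rep = assess_segregation(
            _variant("C6orf10"),
            {"B-I-2": Genotype.het, "B-II-3": Genotype.het},
            ped,
        )
        assert rep.affected_only and rep.transmitted
        assert rep.n_affected_carriers == 2

    def test_carriers_without_parent_child_pair_not_transmitted(self):
        ped = _fig1()
        rep = assess_segregation(
            _variant("BTNL2"),
            {s: Genotype.het for s in ("B-I-1", "C-I-1", "C-I-2")},
            ped,
        )
        assert not rep.transmitted
        assert not rep.affected_only  # B-I-1 and C-I-1 are unaffected

    def test_single_carrier_never_transmitted(self):
        ped = _fig1()
        rep = assess_segregation(_variant(), {"A-II-3": Genotype.het}, ped)
        assert not rep.transmitted and rep.n_affected_carriers <= 1

    def test_zero_carriers_reported_not_error(self):
        rep = assess_segregation(_variant(), {}, _fig1())
        assert rep.carriers == [] and not rep.affected_only and not rep.transmitted

    def test_brute_force_agreement_on_random_pedigrees(self, rng):
        """Pairwise brute force over all carrier pairs matches the implementation."""
        for _ in range(30):
            n = int(rng.integers(4, 21))
            n_founders = max(2, n // 3)
            members = []
            ids = [f"i{k}" for k in range(n)]
            for k, iid in enumerate(ids):
                if k < n_founders:
                    father = mother = None
                else:
                    father, mother = rng.choice(k, size=2, replace=False)
                    father, mother = ids[father], ids[mother]
                members.append(
                    Individual(iid, "F", father, mother, 0, bool(rng.random() < 0.5))
                )
            try:
                ped = Pedigree(members)
            except Exception:
                continue
            carriers = [iid for iid in ids if rng.random() < 0.4]
            rep = assess_segregation(
                _variant(), {c: Genotype.het for c in carriers}, ped
            )
            affected = ped.affected_ids
            bf_transmitted = any(
                a in affected and b in affected and ped.is_parent_child(a, b)
                for a, b in itertools.combinations(carriers, 2)
            )
            bf_affected_only = bool(carriers) and all(c in affected for c in carriers)
            assert rep.transmitted == bf_transmitted
            assert rep.affected_only == bf_affected_only

    def test_recovers_planted_labels_from_generator(self, small_spec):
        variants, genotypes, ped, truth = gen_families(small_spec)
        for vi, v in enumerate(variants):
            calls = {s: genotypes[s][vi] for s in genotypes}
            rep = assess_segregation(v, calls, ped)
            assert rep.transmitted == bool(truth.loc[vi, "transmitted"])
            assert rep.affected_only == bool(truth.loc[vi, "affected_only"])
            assert set(rep.carriers) == set(
                filter(None, str(truth.loc[vi, "carriers"]).split(","))
            )


class TestSelectCandidates:
    def _reports(self, pedigree=None):
        records = [r for r in load_fixture("table4_family_variants") if not r["ambiguous"]]
        ped = pedigree or _fig1()
        return [
            assess_segregation(rec["variant"], gmap, ped)
            for rec, gmap in zip(records, table4_genotype_map(records))
        ]

    def test_transmitted_plus_private_new_is_fifteen(self):
        selected = select_candidates(self._reports(), keep_private_new=True)
        assert len(selected) == 15
        genes = {v.gene for v in selected}
        assert "ADAMTS3" in genes and "RRAS2" not in genes

    def test_transmitted_only_is_fourteen(self):
        assert len(select_candidates(self._reports(), keep_private_new=False)) == 14

    def test_all_unaffected_pedigree_selects_nothing(self):
        ped = _fig1()
        unaffected = Pedigree(
            [
                Individual(m.individual_id, m.family_id, m.father_id, m.mother_id, m.sex, False)
                for m in ped.members
            ]
        )
        assert select_candidates(self._reports(unaffected)) == []
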