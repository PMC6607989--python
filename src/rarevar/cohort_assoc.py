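"""Cohort allele-frequency estimation and comparison against reference panels.

Implements the screening stage of the pipeline: per-variant minor allele
frequency in an unrelated patient cohort, a z-test of that frequency against
each reference panel, Bonferroni correction across variants, odds ratios
with Woolf confidence intervals when full counts are available, and the
per-patient tabulation of carried variant combinations.

The default test treats the reference MAF as a known population proportion
(``fixed_reference``): z = (p_hat - p0) / sqrt(p0 (1 - p0) / n).  The
classical pooled two-sample z-test is available as ``pooled_two_sample``
when the reference allele count is known; the two converge as the reference
sample grows.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import Genotype, GenotypeCall, ReferencePanel, Variant

__all__ = [
    "VarianceMode",
    "TestConfig",
    "PanelTest",
    "AssociationResult",
    "cohort_frequency",
    "freq_z_test",
    "bonferroni_threshold",
    "odds_ratio",
    "combination_table",
    "associate",
]


class VarianceMode(str, enum.Enum):
    fixed_reference = "fixed_reference"
    pooled_two_sample = "pooled_two_sample"


@dataclass
class TestConfig:
    """Configuration of the frequency comparison.

    ``n_tests`` is the Bonferroni divisor — by convention the number of
    variants with a computable test, not the number screened.
    """

    __test__ = False  # keep pytest from collecting this dataclass

    alpha: float = 0.05
    n_tests: int = 1
    two_sided: bool = True
    variance_mode: VarianceMode = VarianceMode.fixed_reference

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass
class PanelTest:
    panel: str
    ref_maf: float
    z: float
    p_value: float
    significant_nominal: bool
    significant_bonferroni: bool


@dataclass
class AssociationResult:
    variant: Variant
    cohort_alt_alleles: int
    cohort_n_alleles: int
    cohort_maf: float
    panel_tests: list[PanelTest] = field(default_factory=list)
    odds_ratio: dict[str, float] = field(default_factory=dict)
    odds_ratio_ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def cohort_frequency(
    genotypes: Sequence[GenotypeCall | Genotype],
) -> tuple[int, int, float]:
    """Alt-allele count, total allele count and MAF for one variant.

    Each non-missing genotype contributes two alleles; heterozygotes one
    alternate allele, homozygous-alternate two.
    """
    alt = 0
    n_nonmissing = 0
    for call in genotypes:
        gt = call.genotype if isinstance(call, GenotypeCall) else call
        if gt is Genotype.missing:
            continue
        n_nonmissing += 1
        alt += gt.alt_dose
    if n_nonmissing == 0:
        raise ValueError("all genotypes missing: cohort frequency undefined")
    n_alleles = 2 * n_nonmissing
    return alt, n_alleles, alt / n_alleles


def freq_z_test(
    alt_alleles: int,
    n_alleles: int,
    ref_maf: float,
    ref_n_alleles: int | None = None,
    config: TestConfig | None = None,
) -> tuple[float, float]:
    """z-test of the cohort allele frequency against a reference proportion.

    Returns ``(z, p)``.  In ``fixed_reference`` mode the reference MAF is a
    known proportion and the variance is p0 (1 - p0) / n.  In
    ``pooled_two_sample`` mode the classical pooled-variance two-proportion
    z statistic is used and ``ref_n_alleles`` is required.
    """
    config = config or TestConfig()
    if n_alleles <= 0:
        raise ValueError("n_alleles must be positive")
    if not 0 < ref_maf < 1:
        raise ValueError("ref_maf must be in (0, 1)")
    p_hat = alt_alleles / n_alleles
    if config.variance_mode is VarianceMode.fixed_reference:
        se = math.sqrt(ref_maf * (1.0 - ref_maf) / n_alleles)
    else:
        if ref_n_alleles is None:
            raise ValueError("pooled_two_sample mode requires ref_n_alleles")
        ref_count = ref_maf * ref_n_alleles
        pooled = (alt_alleles + ref_count) / (n_alleles + ref_n_alleles)
        se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n_alleles + 1.0 / ref_n_alleles))
    if se == 0.0:
        raise ValueError("degenerate variance in z-test")
    z = (p_hat - ref_maf) / se
    if config.two_sided:
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(z)
    return z, float(min(p, 1.0))


def bonferroni_threshold(config: TestConfig) -> float:
    """Per-test significance threshold alpha / n_tests (reports show 4 decimals)."""
    return config.alpha / config.n_tests


def odds_ratio(
    p1: float,
    p0: float,
    counts: tuple[int, int, int, int] | None = None,
) -> tuple[float, tuple[float, float] | None, bool]:
    """Allelic odds ratio of cohort vs reference frequency.

    OR = [p1 / (1 - p1)] / [p0 / (1 - p0)].  When the full 2x2 allele counts
    ``(case_alt, case_ref, ctrl_alt, ctrl_ref)`` are given, a Woolf 95% CI is
    computed as exp(ln OR +/- 1.96 sqrt(sum 1/cell)); zero cells trigger the
    Haldane-Anscombe 0.5 correction, flagged in the third return value.
    """
    if counts is None:
        if not (0 < p0 < 1 and 0 < p1 < 1):
            raise ValueError("frequencies must be in (0, 1) without counts")
        return (p1 / (1 - p1)) / (p0 / (1 - p0)), None, False
    a, b, c, d = counts
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return or_, (lo, hi), corrected


@dataclass
class CombinationReport:
    """Per-patient carried variants plus the counts-of-counts histogram."""

    per_patient: dict[str, list[tuple[str, Genotype]]]
    histogram: dict[int, int]
    homozygous: list[tuple[str, str]]  # (patient, variant label)

    @property
    def n_multi_carriers(self) -> int:
        return sum(n for k, n in self.histogram.items() if k >= 2)


def combination_table(
    genotype_matrix: Mapping[str, Mapping[str, GenotypeCall | Genotype]],
) -> CombinationReport:
    """Tabulate which variants each patient carries.

    ``genotype_matrix[patient][variant_label]`` is the call of *patient* at
    that variant.  Returns per-patient carried-variant lists (het/hom
    flagged), the histogram of patients by number of distinct carried
    variants, and the list of homozygous carriages.
    """
    per_patient: dict[str, list[tuple[str, Genotype]]] = {}
    homozygous: list[tuple[str, str]] = []
    histogram: dict[int, int] = {}
    for patient, row in genotype_matrix.items():
        carried = []
        for label, call in row.items():
            gt = call.genotype if isinstance(call, GenotypeCall) else call
            if gt.is_carrier:
                carried.append((label, gt))
                if gt is Genotype.hom_alt:
                    homozygous.append((patient, label))
        if carried:
            per_patient[patient] = carried
            k = len(carried)
            histogram[k] = histogram.get(k, 0) + 1
    return CombinationReport(per_patient=per_patient, histogram=histogram, homozygous=homozygous)


def associate(
    variants: Sequence[Variant],
    genotype_columns: Sequence[Sequence[GenotypeCall | Genotype]],
    panels: Sequence[ReferencePanel],
    config: TestConfig | None = None,
    matched_panel: str | None = None,
) -> list[AssociationResult]:
    """Run the full frequency comparison for each variant against each panel.

    ``genotype_columns[i]`` holds the cohort calls at ``variants[i]``.
    A variant enters the multiple-testing family when at least one panel
    reports it at a frequency in (0, 1) and the variant segregates locally —
    carried by the cohort, or present in the ancestry-matched panel
    (``matched_panel``, default the first panel).  A cohort-absent variant
    that the matched panel also lacks has nothing to test.  When ``config``
    is None, ``n_tests`` defaults to the size of that family.
    """
    if matched_panel is None and panels:
        matched_panel = panels[0].name
    matched = next((p for p in panels if p.name == matched_panel), None)
    testable = 0
    rows = []
    for v, calls in zip(variants, genotype_columns):
        try:
            alt, n, maf = cohort_frequency(calls)
        except ValueError:
            continue
        any_ref = any(0 < p.freqs.get(v.key, 0) < 1 for p in panels)
        local = alt > 0 or (matched is not None and matched.freqs.get(v.key, 0) > 0)
        has_test = any_ref and local
        rows.append((v, alt, n, maf, has_test))
        testable += has_test
    if config is None:
        config = TestConfig(n_tests=max(testable, 1))
    threshold = bonferroni_threshold(config)

    results = []
    for v, alt, n, maf, has_test in rows:
        res = AssociationResult(v, alt, n, maf)
        for panel in panels:
            ref_maf = panel.freqs.get(v.key)
            if not has_test or ref_maf is None or not 0 < ref_maf < 1:
                continue
            z, p = freq_z_test(alt, n, ref_maf, panel.n_alleles, config)
            res.panel_tests.append(
                PanelTest(
                    panel=panel.name,
                    ref_maf=ref_maf,
                    z=z,
                    p_value=p,
                    significant_nominal=p < config.alpha,
                    significant_bonferroni=p < threshold,
                )
            )
            if 0 < maf < 1:
                or_, _, _ = odds_ratio(maf, ref_maf)
                res.odds_ratio[panel.name] = or_
                if panel.n_alleles:
                    ctrl_alt = int(round(ref_maf * panel.n_alleles))
                    cnt = (alt, n - alt, ctrl_alt, panel.n_alleles - ctrl_alt)
                    orc, ci, _ = odds_ratio(maf, ref_maf, counts=cnt)
                    res.odds_ratio_ci[panel.name] = ci
        results.append(res)
    return results


def association_frame(results: Sequence[AssociationResult]):
    """Flatten association results into a report table (one row per variant)."""
    import pandas as pd

    panel_names: list[str] = []
    for r in results:
        for t in r.panel_tests:
            if t.panel not in panel_names:
                panel_names.append(t.panel)
    rows = []
    for r in results:
        v = r.variant
        row: dict = {
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "id": v.variant_id or "-",
            "maf_pct_cohort": round(100.0 * r.cohort_maf, 2),
            "alt_alleles": r.cohort_alt_alleles,
            "n_alleles": r.cohort_n_alleles,
        }
        by_panel = {t.panel: t for t in r.panel_tests}
        for name in panel_names:
            t = by_panel.get(name)
            row[f"maf_pct_{name}"] = round(100.0 * t.ref_maf, 2) if t else None
            row[f"p_{name}"] = t.p_value if t else None
            row[f"sig_bonf_{name}"] = t.significant_bonferroni if t else None
        rows.append(row)
    return pd.DataFrame(rows)
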