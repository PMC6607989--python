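"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates the full input bundle — family VCF with read depths, PED,
unrelated cohort VCF, reference-panel frequency tables and a BED12 gene
universe — under a single seeded specification, plus loaders for the
machine-readable copies of the published tables shipped with the package.

Defaults mirror the published study's scale: three nuclear families with
eleven sequenced members, a 120-patient cohort (240 alleles) genotyped at
~15 low-frequency sites, an ancestry-matched reference panel of 214
alleles, and a candidate set of 107 genes.  Sites are independent (no
linkage disequilibrium) and there is no sequencing-error model; see the
methods note for what that implies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Consequence,
    GeneModel,
    Genotype,
    GenotypeCall,
    Individual,
    Pedigree,
    ReferencePanel,
    Variant,
    variant_key,
)

__all__ = [
    "SimSpec",
    "PanelSpec",
    "gen_universe",
    "gen_families",
    "gen_cohort",
    "gen_panels",
    "load_fixture",
    "FIXTURE_NAMES",
]


@dataclass
class PanelSpec:
    name: str
    n_alleles: int
    drop_zero_prob: float = 1.0  # probability a zero-count entry is rendered absent


@dataclass
class SimSpec:
    """Parameters of the synthetic study.

    ``variant_freqs`` are true population MAFs of the simulated sites;
    ``planted_or`` optionally inflates selected cohort frequencies by an
    allelic odds ratio (keyed by site index); ``planted_density_factor``
    multiplies the per-base variant rate in ``planted_genes`` of the
    universe.
    """

    n_families: int = 3
    n_offspring: int = 2
    affected_prob: float = 0.6
    cohort_n: int = 120
    variant_freqs: tuple[float, ...] = tuple([0.012, 0.02, 0.008, 0.03, 0.015,
                                              0.004, 0.025, 0.018, 0.01, 0.035,
                                              0.006, 0.022, 0.016, 0.009, 0.028])
    panels: tuple[PanelSpec, ...] = (
        PanelSpec("tuscany", 214),
        PanelSpec("dbsnp", 50000),
        PanelSpec("exac", 66000),
        PanelSpec("gnomad", 21000),
    )
    n_genes: int = 20000
    candidate_set_size: int = 107
    exon_count_mean: float = 5.0
    exon_len_log_mean: float = 5.0  # log-scale; median exon ~148 bp
    exon_len_log_sd: float = 0.6
    mean_depth: float = 100.0
    planted_or: dict[int, float] = field(default_factory=dict)
    planted_genes: tuple[str, ...] = ()
    planted_density_factor: float = 1.0
    base_variant_rate: float = 5e-4  # low-frequency variants per exonic base
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cohort_n <= 0:
            raise ValueError("cohort_n must be positive")
        for f in self.variant_freqs:
            if not 0 < f <= 0.5:
                raise ValueError(f"variant frequency {f} outside (0, 0.5]")


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

def gen_universe(spec: SimSpec, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Draw a gene universe: one isoform per gene, Poisson exon counts,
    log-normal exon lengths."""
    rng = rng or np.random.default_rng(spec.seed)
    models = []
    cursor = 1000
    for i in range(spec.n_genes):
        n_exons = int(rng.poisson(spec.exon_count_mean)) + 1
        lengths = np.maximum(
            1,
            np.rint(
                rng.lognormal(spec.exon_len_log_mean, spec.exon_len_log_sd, n_exons)
            ).astype(int),
        )
        exons = []
        pos = cursor
        for L in lengths:
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(rng.integers(50, 500))  # intron gap
        cursor = pos + 1000
        models.append(GeneModel(f"G{i:05d}", [(f"G{i:05d}.1", "+", exons)]))
    return models


def gen_gene_variant_counts(
    spec: SimSpec,
    universe: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Poisson low-frequency variant counts per gene, proportional to
    longest-isoform exon length, with a planted density multiplier."""
    from .burden import longest_isoform_length

    rng = rng or np.random.default_rng(spec.seed)
    planted = set(spec.planted_genes)
    counts = {}
    for gm in universe:
        rate = spec.base_variant_rate * longest_isoform_length(gm)
        if gm.gene in planted:
            rate *= spec.planted_density_factor
        counts[gm.gene] = int(rng.poisson(rate))
    return counts


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def _draw_reads(gt: Genotype, depth: int, rng: np.random.Generator) -> tuple[int, int]:
    if gt is Genotype.het:
        alt = int(rng.binomial(depth, 0.5))
    elif gt is Genotype.hom_alt:
        alt = depth
    else:
        alt = 0
    return depth - alt, alt


def gen_families(
    spec: SimSpec,
    variants: Sequence[Variant] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Variant], dict[str, list[GenotypeCall]], Pedigree, pd.DataFrame]:
    """Simulate nuclear families with Mendelian transmission and read depths.

    Founder genotypes are binomial draws at the true MAFs; each offspring
    inherits one allele from each parent.  Returns the variants, the
    per-sample call lists (with AD-style read counts), the pedigree, and a
    ground-truth table with per-variant carrier lists and a
    ``transmitted`` label (affected parent-child carrier pair exists).
    """
    rng = rng or np.random.default_rng(spec.seed)
    if variants is None:
        variants = default_variants(spec)
    members: list[Individual] = []
    for fi in range(spec.n_families):
        fam = chr(ord("A") + fi) if fi < 26 else f"F{fi}"
        father, mother = f"{fam}-I-1", f"{fam}-I-2"
        aff = rng.random(2 + spec.n_offspring) < spec.affected_prob
        members.append(Individual(father, fam, None, None, 1, bool(aff[0])))
        members.append(Individual(mother, fam, None, None, 2, bool(aff[1])))
        for ci in range(spec.n_offspring):
            members.append(
                Individual(f"{fam}-II-{ci + 1}", fam, father, mother, 0, bool(aff[2 + ci]))
            )
    pedigree = Pedigree(members)

    doses: dict[str, np.ndarray] = {}
    for fi in range(spec.n_families):
        fam = chr(ord("A") + fi) if fi < 26 else f"F{fi}"
        f_dose = rng.binomial(2, np.asarray(spec.variant_freqs))
        m_dose = rng.binomial(2, np.asarray(spec.variant_freqs))
        doses[f"{fam}-I-1"] = f_dose
        doses[f"{fam}-I-2"] = m_dose
        for ci in range(spec.n_offspring):
            # one allele from each parent: P(transmit alt) = dose / 2
            child = rng.binomial(1, f_dose / 2.0) + rng.binomial(1, m_dose / 2.0)
            doses[f"{fam}-II-{ci + 1}"] = child

    dose_to_gt = {0: Genotype.hom_ref, 1: Genotype.het, 2: Genotype.hom_alt}
    genotypes: dict[str, list[GenotypeCall]] = {}
    for m in members:
        calls = []
        for vi in range(len(variants)):
            gt = dose_to_gt[int(doses[m.individual_id][vi])]
            depth = max(1, int(rng.poisson(spec.mean_depth)))
            ref_r, alt_r = _draw_reads(gt, depth, rng)
            calls.append(GenotypeCall(m.individual_id, gt, ref_r, alt_r))
        genotypes[m.individual_id] = calls

    truth_rows = []
    affected = pedigree.affected_ids
    for vi, v in enumerate(variants):
        carriers = [m.individual_id for m in members if doses[m.individual_id][vi] > 0]
        aff_car = [c for c in carriers if c in affected]
        transmitted = any(
            p in aff_car for c in aff_car for p in pedigree.parents_of(c)
        )
        truth_rows.append(
            {
                "variant": f"{v.chrom}:{v.pos}",
                "carriers": ",".join(carriers),
                "n_affected_carriers": len(aff_car),
                "transmitted": transmitted,
                "affected_only": bool(carriers) and all(c in affected for c in carriers),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return list(variants), genotypes, pedigree, truth


def default_variants(spec: SimSpec) -> list[Variant]:
    """Deterministic site layout for the simulated low-frequency variants."""
    variants = []
    csq_cycle = [
        Consequence.missense,
        Consequence.synonymous,
        Consequence.utr3,
        Consequence.missense,
        Consequence.utr5,
    ]
    for i, f in enumerate(spec.variant_freqs):
        variants.append(
            Variant(
                chrom=str(1 + (i % 5)),
                pos=10_000 + 1_000 * i,
                ref_allele="A",
                alt_allele="G",
                variant_id=f"sim{i}",
                gene=f"GENE{i}",
                consequence=csq_cycle[i % len(csq_cycle)],
            )
        )
    return variants


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _inflate(freq: float, odds_ratio: float) -> float:
    odds = freq / (1.0 - freq) * odds_ratio
    return odds / (1.0 + odds)


def gen_cohort(
    spec: SimSpec,
    variants: Sequence[Variant] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Variant], dict[str, list[GenotypeCall]]]:
    """Simulate unrelated cohort genotypes under Hardy-Weinberg equilibrium.

    Per-site cohort frequency equals the true MAF, optionally inflated by a
    planted allelic odds ratio; sites and patients are independent.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if variants is None:
        variants = default_variants(spec)
    freqs = np.asarray(spec.variant_freqs, dtype=float)
    for idx, or_ in spec.planted_or.items():
        freqs[idx] = _inflate(freqs[idx], or_)
    dose_to_gt = {0: Genotype.hom_ref, 1: Genotype.het, 2: Genotype.hom_alt}
    genotypes: dict[str, list[GenotypeCall]] = {}
    doses = rng.binomial(2, freqs, size=(spec.cohort_n, len(freqs)))
    for pi in range(spec.cohort_n):
        sid = f"P{pi:04d}"
        genotypes[sid] = [
            GenotypeCall(sid, dose_to_gt[int(d)]) for d in doses[pi]
        ]
    return list(variants), genotypes


# ---------------------------------------------------------------------------
# Reference panels
# ---------------------------------------------------------------------------

def gen_panels(
    spec: SimSpec,
    variants: Sequence[Variant] | None = None,
    true_freqs: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReferencePanel]:
    """Sample per-panel MAFs: binomial allele counts at the true frequency.

    Zero-count entries are rendered absent with the panel's
    ``drop_zero_prob`` to emulate dash cells in published tables.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if variants is None:
        variants = default_variants(spec)
    if true_freqs is None:
        true_freqs = spec.variant_freqs
    panels = []
    for ps in spec.panels:
        freqs = {}
        for v, f in zip(variants, true_freqs):
            count = int(rng.binomial(ps.n_alleles, f))
            if count == 0 and rng.random() < ps.drop_zero_prob:
                continue
            freqs[v.key] = count / ps.n_alleles
        panels.append(ReferencePanel(ps.name, ps.n_alleles, freqs))
    return panels


# ---------------------------------------------------------------------------
# Packaged fixtures (machine-readable copies of the published tables)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "table4_family_variants",
    "table5_cohort",
    "table6_combinations",
    "table7_c6orf10",
    "table8_c6orf10_genotypes",
    "fig1_pedigree_derived",
)

_PANEL_COLS = ("tuscany", "dbsnp", "exac", "gnomad")


def _fixture_path(filename: str) -> Path:
    return Path(importlib.resources.files("rarevar") / "fixtures" / filename)


def load_fixture(name: str):
    """Load one of the packaged study tables as typed records.

    ``fig1_pedigree_derived`` carries back-derived affection labels (the
    unique assignment consistent with the published carrier lists and
    variant counts); see the file header and the methods note.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    if name == "fig1_pedigree_derived":
        from .io_formats import read_ped

        return read_ped(_fixture_path("fig1_pedigree_derived.ped"))
    df = pd.read_csv(_fixture_path(f"{name}.tsv"), sep="\t", comment="#", dtype=str)
    if name == "table4_family_variants":
        return _parse_table4(df)
    if name == "table5_cohort":
        return _parse_table5(df)
    if name == "table6_combinations":
        return df
    if name == "table7_c6orf10":
        return _parse_table7(df)
    return df  # table8: per-patient genotype strings


def _maybe_pct(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", "-", "–"):
        return None
    return float(s) / 100.0


def _panel_freqs(row) -> dict[str, float]:
    freqs = {}
    for p in _PANEL_COLS:
        col = f"maf_pct_{p}"
        if col in row:
            f = _maybe_pct(row[col])
            if f is not None:
                freqs[p] = f
    return freqs


def _parse_table4(df: pd.DataFrame) -> list[dict]:
    records = []
    for _, row in df.iterrows():
        v = Variant(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_allele="N",
            alt_allele="V",
            variant_id=None if row["variant_id"] == "-" else row["variant_id"],
            gene=row["gene"],
            consequence=Consequence(row["consequence"]),
            ref_freqs=_panel_freqs(row),
        )
        records.append(
            {
                "variant": v,
                "carriers": row["carriers"].split(","),
                "ambiguous": row["ambiguous"] == "1",
            }
        )
    return records


def _parse_table5(df: pd.DataFrame) -> list[dict]:
    records = []
    for _, row in df.iterrows():
        v = Variant(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_allele="N",
            alt_allele="V",
            variant_id=None if row["variant_id"] == "-" else row["variant_id"],
            gene=row["gene"],
            consequence=Consequence(row["consequence"]),
            ref_freqs=_panel_freqs(row),
        )
        records.append(
            {
                "variant": v,
                "alt_alleles": int(row["alt_alleles"]),
                "n_alleles": int(row["n_alleles"]),
            }
        )
    return records


def _parse_table7(df: pd.DataFrame) -> list[dict]:
    records = []
    for _, row in df.iterrows():
        v = Variant(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_allele="N",
            alt_allele="V",
            variant_id=None if row["variant_id"] == "-" else row["variant_id"],
            gene="C6orf10",
            consequence=Consequence(row["consequence"]),
            ref_freqs=_panel_freqs(row),
        )
        records.append(
            {
                "variant": v,
                "aa_change": row["aa_change"],
                "alt_alleles": int(row["alt_alleles"]),
                "n_alleles": int(row["n_alleles"]),
            }
        )
    return records


def table5_panels() -> list[ReferencePanel]:
    """Reference panels reconstructed from the cohort screening table."""
    df = pd.read_csv(
        _fixture_path("table5_cohort.tsv"), sep="\t", comment="#", dtype=str
    )
    n_alleles = {"tuscany": 214}
    panels = []
    for p in _PANEL_COLS:
        freqs = {}
        for _, row in df.iterrows():
            f = _maybe_pct(row.get(f"maf_pct_{p}"))
            if f is not None:
                freqs[variant_key(row["chrom"], int(row["pos"]), "N", "V")] = f
        panels.append(ReferencePanel(p, n_alleles.get(p), freqs))
    return panels


def counts_to_genotypes(alt_alleles: int, n_alleles: int) -> list[Genotype]:
    """Build a genotype column realizing the given allele counts.

    Alternate alleles are spread as heterozygotes (requires
    ``alt_alleles <= n_alleles / 2``); the remaining patients are
    homozygous reference.  Only allele counts matter to the frequency
    tests, so any realization is equivalent there.
    """
    n_patients = n_alleles // 2
    if alt_alleles > n_patients:
        raise ValueError("more alternate alleles than patients to carry them as het")
    return [Genotype.het] * alt_alleles + [Genotype.hom_ref] * (n_patients - alt_alleles)


def table4_genotype_map(records: Sequence[dict]) -> list[dict[str, Genotype]]:
    """Expand carrier lists into per-sample genotype dicts (carriers are het)."""
    out = []
    for rec in records:
        out.append({c: Genotype.het for c in rec["carriers"]})
    return out
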