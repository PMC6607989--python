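"""Family-based filtering cascade for low-frequency candidate variants.

The cascade mirrors a WES prioritization design for disease families:
restrict to candidate genes, keep exonic/UTR variants with MAF at or below
a low-frequency threshold in a primary reference panel (novel variants with
no reported frequency pass), call genotypes from read fractions, and score
each variant for affected carriers, affected-only status and affected
parent-child transmission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    EXONIC_CONSEQUENCES,
    Consequence,
    Genotype,
    GenotypeCall,
    Pedigree,
    Variant,
)

__all__ = [
    "FilterConfig",
    "FamilyVariantReport",
    "call_from_reads",
    "filter_low_frequency",
    "assess_segregation",
    "select_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the family filtering cascade.

    ``het_fraction_min`` is the minimum alternate-read fraction for a true
    heterozygous call (default 0.40, boundary inclusive);
    ``hom_alt_fraction_min`` the minimum fraction for a homozygous-alternate
    call (default 0.85).  ``maf_max`` is the low-frequency cutoff applied to
    the ``primary_freq_panel`` column.
    """

    maf_max: float = 0.04
    primary_freq_panel: str = "dbsnp"
    allowed_consequences: frozenset = field(default_factory=lambda: EXONIC_CONSEQUENCES)
    het_fraction_min: float = 0.40
    hom_alt_fraction_min: float = 0.85
    require_gene_in_candidates: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.het_fraction_min < self.hom_alt_fraction_min <= 1:
            raise ValueError(
                "need 0 < het_fraction_min < hom_alt_fraction_min <= 1"
            )
        if not 0 < self.maf_max < 0.5:
            raise ValueError("maf_max must be in (0, 0.5)")


@dataclass
class FamilyVariantReport:
    """Segregation assessment of one variant across the sequenced families."""

    variant: Variant
    carriers: list[str]
    affected_carriers: list[str]
    affected_only: bool
    transmitted: bool
    selected: bool = False

    @property
    def n_affected_carriers(self) -> int:
        return len(self.affected_carriers)


def call_from_reads(
    ref_reads: int, alt_reads: int, config: FilterConfig | None = None
) -> Genotype:
    """Call a genotype from ref/alt read counts by alternate-read fraction.

    A site is heterozygous when the alternate allele reaches the
    ``het_fraction_min`` share of total reads (boundary inclusive) and
    homozygous-alternate from ``hom_alt_fraction_min`` upward.  Zero total
    reads yield a missing call with a logged warning.
    """
    config = config or FilterConfig()
    total = ref_reads + alt_reads
    if total <= 0:
        logger.warning("zero total reads: genotype set to missing")
        return Genotype.missing
    f = alt_reads / total
    if f < config.het_fraction_min:
        return Genotype.hom_ref
    if f < config.hom_alt_fraction_min:
        return Genotype.het
    return Genotype.hom_alt


def filter_low_frequency(
    variants: Iterable[Variant],
    candidate_genes: set[str],
    config: FilterConfig | None = None,
) -> list[Variant]:
    """Keep candidate-gene, exonic/UTR variants at low frequency.

    A variant passes when its gene is in the candidate set, its consequence
    is allowed, and its MAF in the primary panel is <= ``maf_max`` — or it
    has no frequency in that panel at all (novel variants pass).
    """
    config = config or FilterConfig()
    if config.require_gene_in_candidates and not candidate_genes:
        raise ValueError("empty candidate gene set with require_gene_in_candidates")
    kept = []
    for v in variants:
        if config.require_gene_in_candidates and v.gene not in candidate_genes:
            continue
        if v.consequence not in config.allowed_consequences:
            continue
        maf = v.ref_freqs.get(config.primary_freq_panel)
        if maf is not None and maf > config.maf_max:
            continue
        kept.append(v)
    return kept


def assess_segregation(
    variant: Variant,
    genotypes: Mapping[str, GenotypeCall | Genotype],
    pedigree: Pedigree,
) -> FamilyVariantReport:
    """Score one variant for carriers, affected-only status and transmission.

    ``transmitted`` requires a carrier pair (parent, child) with both
    affected.  ``affected_only`` means every sequenced carrier with a known
    phenotype is affected (false for zero carriers).  Missing genotypes are
    non-carriers.
    """
    carriers = []
    for sample_id, call in genotypes.items():
        gt = call.genotype if isinstance(call, GenotypeCall) else call
        if gt.is_carrier:
            if sample_id not in pedigree:
                raise KeyError(f"carrier {sample_id!r} not in pedigree")
            carriers.append(sample_id)
    affected = pedigree.affected_ids
    sequenced = pedigree.sequenced_ids
    affected_carriers = [c for c in carriers if c in affected]
    seq_carriers = [c for c in carriers if c in sequenced]
    # unknown-phenotype carriers are not affected, so they break affected-only
    affected_only = bool(seq_carriers) and all(c in affected for c in seq_carriers)
    transmitted = any(
        parent in affected_carriers
        for child in affected_carriers
        for parent in pedigree.parents_of(child)
    )
    return FamilyVariantReport(
        variant=variant,
        carriers=carriers,
        affected_carriers=affected_carriers,
        affected_only=affected_only,
        transmitted=transmitted,
    )


#: Protein-altering classes eligible for the private-new rescue.
PROTEIN_ALTERING = frozenset(
    {
        Consequence.missense,
        Consequence.stop_gained,
        Consequence.frameshift,
        Consequence.start_lost,
    }
)


def select_candidates(
    reports: Sequence[FamilyVariantReport],
    keep_private_new: bool = True,
    private_new_consequences: frozenset = PROTEIN_ALTERING,
) -> list[Variant]:
    """Select variants for cohort follow-up.

    Keeps every transmitted variant and, when ``keep_private_new`` is set,
    also novel variants (absent from all reference panels) carried by at
    least one affected member, restricted to protein-altering consequence
    classes — a family-private variant of unknown frequency is only worth
    cohort follow-up when it can plausibly change the protein.  Sets the
    ``selected`` flag on the reports.
    """
    selected: list[Variant] = []
    for r in reports:
        keep = r.transmitted or (
            keep_private_new
            and r.variant.is_novel
            and r.variant.consequence in private_new_consequences
            and r.n_affected_carriers >= 1
        )
        r.selected = keep
        if keep:
            selected.append(r.variant)
    return selected
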