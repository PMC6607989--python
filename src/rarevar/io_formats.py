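"""Domain types and readers/writers for the file formats the pipeline touches.

Conventions
-----------
* VCF positions are 1-based (the VCF standard); all annotation intervals
  (exons) are stored 0-based half-open (the BED standard).  The single
  audited conversion between the two lives in :func:`vcf_pos_in_interval`.
* Allele frequencies are stored as fractions in [0, 1] internally; reports
  render them as 2-decimal percents.
* Multi-allelic VCF records are split into biallelic variants.  Per-allele
  AD counts are kept: the split variant's ``alt_reads`` is the depth of its
  own allele, and every other read (reference plus other alternates) counts
  toward the total in the read-fraction calling rule.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "Consequence",
    "Genotype",
    "Variant",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "GeneModel",
    "ReferencePanel",
    "FormatError",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_gene_models",
    "write_bed12",
    "read_reference_freqs",
    "write_reference_freqs",
    "vcf_pos_in_interval",
    "variant_key",
]


class FormatError(ValueError):
    """Malformed input file (bad header, inconsistent record, out-of-range value)."""


class Consequence(str, enum.Enum):
    """Coding-impact class of a variant, as annotated upstream."""

    missense = "missense"
    synonymous = "synonymous"
    stop_gained = "stop_gained"
    frameshift = "frameshift"
    start_lost = "start_lost"
    utr5 = "utr5"
    utr3 = "utr3"
    intronic = "intronic"
    other = "other"


#: Consequence classes counted as exonic/UTR in the low-frequency filter.
EXONIC_CONSEQUENCES = frozenset(
    {
        Consequence.missense,
        Consequence.synonymous,
        Consequence.stop_gained,
        Consequence.frameshift,
        Consequence.start_lost,
        Consequence.utr5,
        Consequence.utr3,
    }
)


class Genotype(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.het, Genotype.hom_alt)

    @property
    def alt_dose(self) -> int:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": 0}[self.value]


@dataclass
class Variant:
    """One biallelic site with gene assignment and per-panel reference MAFs."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    variant_id: str | None = None
    gene: str | None = None
    consequence: Consequence = Consequence.other
    ref_freqs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for panel, f in self.ref_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for panel {panel!r} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_novel(self) -> bool:
        """True when no reference panel reports the variant at positive frequency.

        A reported frequency of exactly zero means the panel does not carry
        the allele, so it does not disqualify novelty.
        """
        return not any(f > 0 for f in self.ref_freqs.values())

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        label = self.variant_id or "."
        return f"{self.gene or '?'} {self.chrom}:{self.pos} {self.ref_allele}>{self.alt_allele} ({label})"


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    return (str(chrom), int(pos), ref, alt)


@dataclass
class GenotypeCall:
    """Per-sample call at one variant, optionally backed by read counts."""

    sample_id: str
    genotype: Genotype
    ref_reads: int | None = None
    alt_reads: int | None = None


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affected: bool
    known_phenotype: bool = True
    sequenced: bool = True


class Pedigree:
    """Individuals with family membership, parental links and affection status."""

    def __init__(self, members: Iterable[Individual]):
        self.members: list[Individual] = list(members)
        self._by_id: dict[str, Individual] = {m.individual_id: m for m in self.members}
        self._validate()

    def _validate(self) -> None:
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise FormatError(
                        f"individual {m.individual_id!r} references missing parent {pid!r}"
                    )
                if parent.family_id != m.family_id:
                    raise FormatError(
                        f"parent {pid!r} of {m.individual_id!r} is in a different family"
                    )
        # no individual may be its own ancestor
        for m in self.members:
            seen: set[str] = set()
            stack = [p for p in (m.father_id, m.mother_id) if p]
            while stack:
                pid = stack.pop()
                if pid == m.individual_id:
                    raise FormatError(f"pedigree cycle through {m.individual_id!r}")
                if pid in seen:
                    continue
                seen.add(pid)
                anc = self._by_id[pid]
                stack.extend(p for p in (anc.father_id, anc.mother_id) if p)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def get(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def affected_ids(self) -> set[str]:
        return {m.individual_id for m in self.members if m.affected}

    @property
    def sequenced_ids(self) -> set[str]:
        return {m.individual_id for m in self.members if m.sequenced}

    def parents_of(self, individual_id: str) -> set[str]:
        m = self._by_id[individual_id]
        return {p for p in (m.father_id, m.mother_id) if p}

    def is_parent_child(self, a: str, b: str) -> bool:
        """True when one of *a*, *b* is a parent of the other."""
        return a in self.parents_of(b) or b in self.parents_of(a)


@dataclass
class GeneModel:
    """Gene with one or more isoforms, each a sorted list of 0-based half-open exons."""

    gene: str
    isoforms: list[tuple[str, str, list[tuple[int, int]]]]
    # each isoform: (isoform_id, strand, exons)

    def __post_init__(self) -> None:
        for iso_id, _strand, exons in self.isoforms:
            total = 0
            prev_end = None
            for start, end in exons:
                if end <= start:
                    raise FormatError(
                        f"{self.gene}/{iso_id}: empty or inverted exon [{start}, {end})"
                    )
                if prev_end is not None and start < prev_end:
                    raise FormatError(
                        f"{self.gene}/{iso_id}: overlapping or unsorted exons"
                    )
                prev_end = end
                total += end - start
            if total <= 0:
                raise FormatError(f"{self.gene}/{iso_id}: zero total exon length")


@dataclass
class ReferencePanel:
    """A population allele-frequency resource used as the comparison proportion."""

    name: str
    n_alleles: int | None = None
    freqs: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"panel {self.name!r}: frequency {f} at {k} outside [0, 1]")


def vcf_pos_in_interval(pos: int, start: int, end: int) -> bool:
    """Whether a 1-based VCF position falls inside a 0-based half-open interval.

    The 1-based position ``p`` occupies the 0-based point ``p - 1``, so
    ``p`` lies in ``[start, end)`` iff ``start < p <= end``.
    """
    return start < pos <= end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {0: Genotype.hom_ref, 1: Genotype.het, 2: Genotype.hom_alt}


def read_vcf(path: str | Path) -> tuple[list[Variant], dict[str, list[GenotypeCall]]]:
    """Read a VCF into variants plus a sample -> per-variant call matrix.

    Multi-allelic records are split into one biallelic variant per alternate
    allele.  Returns ``(variants, genotypes)`` where ``genotypes[sample][i]``
    is the call of *sample* at ``variants[i]``.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header ({exc})") from exc

    samples = list(vcf.header.samples)
    n_header_lines = str(vcf.header).count("\n")
    panel_keys = [
        k
        for k in vcf.header.info.keys()
        if k.startswith("MAF_")
    ]

    variants: list[Variant] = []
    genotypes: dict[str, list[GenotypeCall]] = {s: [] for s in samples}
    last_pos: dict[str, int] = {}
    for rec_idx, rec in enumerate(vcf):
        line_no = n_header_lines + rec_idx + 1
        prev = last_pos.get(rec.chrom)
        if prev is not None and rec.pos < prev:
            raise FormatError(
                f"{path}:{line_no}: non-monotone position {rec.chrom}:{rec.pos} after {prev}"
            )
        last_pos[rec.chrom] = rec.pos
        alts = rec.alts or ()
        gene = rec.info.get("GENE")
        csq_raw = rec.info.get("CSQ_CLASS")
        for alt_idx, alt in enumerate(alts):
            csq = _nth(csq_raw, alt_idx)
            ref_freqs = {}
            for k in panel_keys:
                val = _nth(rec.info.get(k), alt_idx)
                if val is not None:
                    ref_freqs[k[len("MAF_"):]] = float(val)
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    variant_id=rec.id,
                    gene=_nth(gene, alt_idx) if isinstance(gene, tuple) else gene,
                    consequence=Consequence(csq) if csq else Consequence.other,
                    ref_freqs=ref_freqs,
                )
            )
            for s in samples:
                sample = rec.samples[s]
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotype = Genotype.missing
                else:
                    dose = sum(1 for a in gt if a == alt_idx + 1)
                    genotype = _GT_MAP[dose]
                ad = sample.get("AD")
                ref_reads = alt_reads = None
                if ad is not None and all(a is not None for a in ad):
                    alt_reads = int(ad[alt_idx + 1])
                    # other alternate reads count toward the calling total
                    ref_reads = int(sum(ad) - alt_reads)
                genotypes[s].append(
                    GenotypeCall(s, genotype, ref_reads=ref_reads, alt_reads=alt_reads)
                )
    return variants, genotypes


def _nth(value, idx):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[idx] if idx < len(value) else None
    return value if idx == 0 else value


def write_vcf(
    path: str | Path,
    variants: Sequence[Variant],
    genotypes: Mapping[str, Sequence[GenotypeCall]],
    panel_names: Sequence[str] = (),
) -> None:
    """Write biallelic variants and calls as a minimal VCF 4.2 text file."""
    samples = list(genotypes)
    contigs: list[str] = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    gt_code = {
        Genotype.hom_ref: "0/0",
        Genotype.het: "0/1",
        Genotype.hom_alt: "1/1",
        Genotype.missing: "./.",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write(
            '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">\n'
        )
        for p in panel_names:
            fh.write(
                f'##INFO=<ID=MAF_{p},Number=1,Type=Float,Description="Reference MAF fraction, panel {p}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
            + "FORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        order = sorted(range(len(variants)), key=lambda i: (contigs.index(variants[i].chrom), variants[i].pos))
        for i in order:
            v = variants[i]
            info_parts = []
            if v.gene:
                info_parts.append(f"GENE={v.gene}")
            info_parts.append(f"CSQ_CLASS={v.consequence.value}")
            for p in panel_names:
                if p in v.ref_freqs:
                    info_parts.append(f"MAF_{p}={v.ref_freqs[p]:.6g}")
            has_ad = any(
                genotypes[s][i].ref_reads is not None for s in samples
            )
            fmt = "GT:AD" if has_ad else "GT"
            cols = [
                v.chrom,
                str(v.pos),
                v.variant_id or ".",
                v.ref_allele,
                v.alt_allele,
                ".",
                "PASS",
                ";".join(info_parts) or ".",
                fmt,
            ]
            for s in samples:
                call = genotypes[s][i]
                cell = gt_code[call.genotype]
                if has_ad:
                    if call.ref_reads is None:
                        cell += ":.,."
                    else:
                        cell += f":{call.ref_reads},{call.alt_reads}"
                cols.append(cell)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PLINK-style PED pedigree file.

    Phenotype coding: 1 = unaffected, 2 = affected, 0 or -9 = unknown.
    Unknown-phenotype individuals are flagged not-affected and excluded from
    affected-only logic via ``known_phenotype=False``.
    """
    members: list[Individual] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{line_no}: expected 6 columns, got {len(fields)}")
            fam, iid, father, mother, sex, pheno = fields[:6]
            members.append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if father in ("0", ".") else father,
                    mother_id=None if mother in ("0", ".") else mother,
                    sex=int(sex) if sex in ("0", "1", "2") else 0,
                    affected=pheno == "2",
                    known_phenotype=pheno in ("1", "2"),
                )
            )
    return Pedigree(members)


def write_ped(path: str | Path, pedigree: Pedigree) -> None:
    with open(path, "w") as fh:
        for m in pedigree.members:
            pheno = ("2" if m.affected else "1") if m.known_phenotype else "0"
            fh.write(
                "\t".join(
                    [
                        m.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        str(m.sex),
                        pheno,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models: BED12 and GTF-lite
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GTF dialect (exon lines).

    In BED12 the *name* column is interpreted as ``gene|isoform`` (or the
    gene symbol alone for single-isoform genes).  In GTF, exon features are
    grouped by ``transcript_id`` within ``gene_id``.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    is_gtf = path.suffix.lower() in (".gtf", ".gff") or (
        len(first.rstrip("\n").split("\t")) == 9 and "_id" in first
    )
    return _read_gtf(path) if is_gtf else _read_bed12(path)


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: dict[str, list[tuple[str, str, list[tuple[int, int]]]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{line_no}: BED12 needs 12 columns, got {len(f)}")
            chrom_start = int(f[1])
            name = f[3]
            strand = f[5] if f[5] in ("+", "-") else "+"
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{line_no}: blockSizes/blockStarts length mismatch"
                )
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            gene, _, iso = name.partition("|")
            iso = iso or f"{gene}.1"
            genes.setdefault(gene, []).append((iso, strand, exons))
    return [GeneModel(g, isoforms) for g, isoforms in genes.items()]


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: Path) -> list[GeneModel]:
    tx: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{line_no}: GTF needs 9 columns")
            if f[2] != "exon":
                continue
            start_1b, end = int(f[3]), int(f[4])
            if end < start_1b:
                raise FormatError(f"{path}:{line_no}: exon end {end} < start {start_1b}")
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gene = attrs.get("gene_id") or attrs.get("gene_name")
            tid = attrs.get("transcript_id")
            if not gene or not tid:
                raise FormatError(f"{path}:{line_no}: missing gene_id/transcript_id")
            rec = tx.setdefault((gene, tid), {"strand": f[6], "exons": []})
            rec["exons"].append((start_1b - 1, end))  # GTF is 1-based inclusive
    genes: dict[str, list[tuple[str, str, list[tuple[int, int]]]]] = {}
    for (gene, tid), rec in tx.items():
        exons = sorted(rec["exons"])
        genes.setdefault(gene, []).append((tid, rec["strand"], exons))
    return [GeneModel(g, isoforms) for g, isoforms in genes.items()]


def write_bed12(path: str | Path, models: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for gm in models:
            for iso_id, strand, exons in gm.isoforms:
                start = exons[0][0]
                end = exons[-1][1]
                sizes = ",".join(str(e - s) for s, e in exons)
                starts = ",".join(str(s - start) for s, e in exons)
                fh.write(
                    "\t".join(
                        [
                            "chrS",
                            str(start),
                            str(end),
                            f"{gm.gene}|{iso_id}",
                            "0",
                            strand,
                            str(start),
                            str(end),
                            "0",
                            str(len(exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Reference frequency tables
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "-", "–", ".", "na", "NA", "n.a."}
_PANEL_META = re.compile(r"#\s*(\S+)\s+n_alleles\s*=\s*(\d+)")


def read_reference_freqs(path: str | Path) -> list[ReferencePanel]:
    """Read a TSV of per-panel MAF percents keyed by (chrom, pos, ref, alt).

    Header comments of the form ``#<panel> n_alleles=<N>`` attach allele
    counts to panels.  Percent values are converted to fractions; ``-``/empty
    cells mean the variant is absent from that panel.
    """
    path = Path(path)
    n_alleles: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _PANEL_META.match(line)
            if m:
                n_alleles[m.group(1)] = int(m.group(2))
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    key_cols = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing key columns {missing}")
    panels: list[ReferencePanel] = []
    for col in df.columns:
        if col in key_cols:
            continue
        freqs: dict[tuple[str, int, str, str], float] = {}
        for _, row in df.iterrows():
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() in _NA_TOKENS:
                continue
            pct = float(raw)
            if not 0.0 <= pct <= 100.0:
                raise FormatError(f"{path}: MAF percent {pct} outside [0, 100] in {col}")
            freqs[variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = (
                pct / 100.0
            )
        panels.append(ReferencePanel(name=col, n_alleles=n_alleles.get(col), freqs=freqs))
    return panels


def write_reference_freqs(path: str | Path, panels: Sequence[ReferencePanel]) -> None:
    keys = sorted({k for p in panels for k in p.freqs}, key=lambda k: (k[0], k[1], k[2], k[3]))
    with open(path, "w") as fh:
        for p in panels:
            if p.n_alleles is not None:
                fh.write(f"#{p.name} n_alleles={p.n_alleles}\n")
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(p.name for p in panels) + "\n")
        for k in keys:
            cells = []
            for p in panels:
                f = p.freqs.get(k)
                cells.append("-" if f is None else f"{100.0 * f:.6g}")
            fh.write("\t".join([k[0], str(k[1]), k[2], k[3], *cells]) + "\n")
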