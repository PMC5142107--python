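"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline consumes a small, well-behaved dialect of each format:

* multi-sample VCF 4.x in which only the ``GT`` subfield is required;
* 6-column whitespace-delimited PED pedigrees;
* a TSV annotation table keyed by ``(chrom, pos, ref, alt)`` carrying the
  gene symbol, HGVS c. change, consequence class, per-database allele
  counts and in-silico scores;
* BED-style per-sample coverage intervals;
* TSV/JSON pipeline reports.

Coordinates are 1-based inclusive internally (VCF convention); coverage
intervals are 0-based half-open (BED convention). Conversions happen only
in this module.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "Genotype",
    "Sex",
    "ConsequenceClass",
    "FrequencySource",
    "PedigreeSample",
    "FrequencyRecord",
    "VariantRecord",
    "CoverageMask",
    "read_ped",
    "write_ped",
    "read_vcf",
    "write_vcf",
    "read_annotations",
    "read_gene_list",
    "default_asd_genes",
    "write_coverage_bed",
    "read_coverage_bed",
    "write_report",
    "normalize_variant",
]


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class FrequencySource(str, enum.Enum):
    THOUSAND_GENOMES = "thousand_genomes"
    EVS = "evs"
    EXAC = "exac"
    INTERNAL = "internal"


FOUNDER = "0"

#: Genes previously associated with anterior segment dysgenesis; shipped as a
#: plain-text fixture and used by the known-gene cross-reference step.
_ASD_GENE_FILE = "asd_genes.txt"


@dataclass(frozen=True, slots=True)
class PedigreeSample:
    """One individual of a family: parental links, sex and affection status."""

    family_id: str
    individual_id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: Sex = Sex.UNKNOWN
    affected: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER


@dataclass(frozen=True, slots=True)
class FrequencyRecord:
    """Allele counts of one variant in one population database."""

    source: FrequencySource
    alt_allele_count: int
    total_alleles: int
    homozygote_count: int = 0

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ValueError("total_alleles must be positive")
        if not 0 <= self.alt_allele_count <= self.total_alleles:
            raise ValueError("alt_allele_count out of range")
        if self.homozygote_count < 0 or 2 * self.homozygote_count > self.alt_allele_count:
            raise ValueError("homozygote_count inconsistent with alt_allele_count")


@dataclass(slots=True)
class VariantRecord:
    """One annotated exonic variant with per-sample genotypes."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene: Optional[str] = None
    cdna_change: Optional[str] = None
    consequence_class: ConsequenceClass = ConsequenceClass.OTHER
    genotypes: dict = field(default_factory=dict)  # individual_id -> Genotype
    frequencies: list = field(default_factory=list)  # list[FrequencyRecord]
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    phylop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    @property
    def is_x(self) -> bool:
        return self.chromosome.removeprefix("chr") == "X"

    def genotype(self, individual_id: str) -> Genotype:
        return self.genotypes.get(individual_id, Genotype.MISSING)

    def max_frequency(self) -> float:
        """Highest alternate-allele frequency across all attached databases.

        A database with no record contributes frequency 0 (databases report
        explicit zero counts for unseen alleles).
        """
        if not self.frequencies:
            return 0.0
        return max(f.alt_allele_count / f.total_alleles for f in self.frequencies)

    def population_homozygotes(self) -> int:
        return sum(f.homozygote_count for f in self.frequencies)


@dataclass(slots=True)
class CoverageMask:
    """Per-sample covered genomic intervals over one gene.

    ``covered_intervals`` maps sample id -> sorted, non-overlapping 0-based
    half-open intervals; ``exon_intervals`` maps exon index -> the exon's
    genomic interval (same convention) so uncovered coding exons can be
    reported.
    """

    gene: str
    covered_intervals: dict = field(default_factory=dict)
    exon_intervals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, ivs in self.covered_intervals.items():
            ivs = sorted(tuple(iv) for iv in ivs)
            for (a0, b0), (a1, _b1) in zip(ivs, ivs[1:]):
                if a1 < b0:
                    raise ValueError(f"overlapping coverage intervals for {sample}")
            self.covered_intervals[sample] = ivs


# ---------------------------------------------------------------------------
# PED


def read_ped(path) -> list[PedigreeSample]:
    """Read a 6-column PED file; raises on cyclic parentage."""
    samples: list[PedigreeSample] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has {len(fields)} columns, expected 6: {line!r}")
        fam, iid, fid, mid, sex, pheno = fields[:6]
        fid = FOUNDER if fid in ("0", "-9", ".") else fid
        mid = FOUNDER if mid in ("0", "-9", ".") else mid
        samples.append(
            PedigreeSample(
                family_id=fam,
                individual_id=iid,
                father_id=fid,
                mother_id=mid,
                sex={"1": Sex.MALE, "2": Sex.FEMALE}.get(sex, Sex.UNKNOWN),
                affected=pheno == "2",
            )
        )
    _check_pedigree(samples)
    return samples


def _check_pedigree(samples: Sequence[PedigreeSample]) -> None:
    by_fam: dict[str, dict[str, PedigreeSample]] = {}
    for s in by_family(samples).items():
        by_fam[s[0]] = {x.individual_id: x for x in s[1]}
    for fam, members in by_fam.items():
        # walk ancestors of each individual; a repeat on the path is a cycle
        def parents(iid: str) -> list[str]:
            s = members.get(iid)
            if s is None:
                return []
            return [p for p in (s.father_id, s.mother_id) if p != FOUNDER]

        for iid in members:
            stack = [(iid, frozenset({iid}))]
            while stack:
                node, seen = stack.pop()
                for p in parents(node):
                    if p in seen:
                        raise ValueError(f"cyclic parentage in family {fam} at {p}")
                    stack.append((p, seen | {p}))


def by_family(samples: Iterable[PedigreeSample]) -> dict[str, list[PedigreeSample]]:
    out: dict[str, list[PedigreeSample]] = {}
    for s in samples:
        out.setdefault(s.family_id, []).append(s)
    return out


def write_ped(samples: Iterable[PedigreeSample], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            sex = {Sex.MALE: "1", Sex.FEMALE: "2"}.get(s.sex, "0")
            fh.write(
                f"{s.family_id}\t{s.individual_id}\t{s.father_id}\t{s.mother_id}\t"
                f"{sex}\t{'2' if s.affected else '1'}\n"
            )


# ---------------------------------------------------------------------------
# variant normalization

def normalize_variant(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and trim a biallelic variant (parsimonious representation).

    Shared suffix is trimmed first, then the shared prefix, keeping at least
    one base on each allele. Annotation keys must match regardless of VCF
    padding conventions.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


# ---------------------------------------------------------------------------
# annotation table

_SOURCE_COLS = {
    FrequencySource.THOUSAND_GENOMES: ("kg_ac", "kg_an", "kg_hom"),
    FrequencySource.EVS: ("evs_ac", "evs_an", "evs_hom"),
    FrequencySource.EXAC: ("exac_ac", "exac_an", "exac_hom"),
    FrequencySource.INTERNAL: ("internal_ac", "internal_an", "internal_hom"),
}

ANNOTATION_COLUMNS = (
    ["chrom", "pos", "ref", "alt", "gene", "cdna_change", "consequence_class"]
    + [c for cols in _SOURCE_COLS.values() for c in cols]
    + ["sift", "polyphen", "phylop"]
)


def read_annotations(path) -> dict[tuple, dict]:
    """Read the per-variant annotation TSV into a dict keyed by variant key."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table: dict[tuple, dict] = {}
    for row in df.to_dict("records"):
        pos, ref, alt = normalize_variant(int(row["pos"]), str(row["ref"]), str(row["alt"]))
        table[(str(row["chrom"]), pos, ref, alt)] = row
    return table


def _frequencies_from_row(row: Mapping) -> list[FrequencyRecord]:
    out = []
    for source, (ac_c, an_c, hom_c) in _SOURCE_COLS.items():
        an = row.get(an_c)
        if an is None or pd.isna(an):
            continue
        out.append(
            FrequencyRecord(
                source=source,
                alt_allele_count=int(row.get(ac_c) or 0),
                total_alleles=int(an),
                homozygote_count=int(row.get(hom_c) or 0),
            )
        )
    return out


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


# ---------------------------------------------------------------------------
# VCF


_GT_CODE = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.HEMI: "1",
    Genotype.MISSING: "./.",
}


def _genotype_from_gt(gt: tuple, alt_index: int) -> Genotype:
    """Map a pysam GT tuple to the genotype relative to one ALT allele."""
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    alleles = [a for a in gt if a is not None]
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:  # haploid call (male X) -> hemizygous if alt
        return Genotype.HEMI if n_alt else Genotype.HOM_REF
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_ALT


def read_vcf(path, annotation_table=None) -> list[VariantRecord]:
    """Read a multi-sample VCF into annotated :class:`VariantRecord` objects.

    Multi-allelic sites are decomposed into one record per ALT allele and
    indels are left-normalized before the annotation join. Phased separators
    are read as unphased. Sites whose key is missing from the annotation
    table produce a warning and an unannotated record.
    """
    if annotation_table is not None and not isinstance(annotation_table, dict):
        annotation_table = read_annotations(annotation_table)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError("VCF lacks the GT FORMAT field")
        sample_names = list(vcf.header.samples)
        for site in vcf:
            alts = site.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or set(alt) - set("ACGTN"):
                    continue  # symbolic / SV alleles out of scope
                pos, ref, alt_n = normalize_variant(site.pos, site.ref, alt)
                genotypes = {
                    name: _genotype_from_gt(site.samples[name].get("GT"), alt_index)
                    for name in sample_names
                }
                rec = VariantRecord(
                    chromosome=site.chrom,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt_n,
                    genotypes=genotypes,
                )
                if annotation_table is not None:
                    row = annotation_table.get(rec.key)
                    if row is None:
                        warnings.warn(f"no annotation for variant {rec.key}", stacklevel=2)
                    else:
                        gene = row.get("gene")
                        rec.gene = None if gene is None or pd.isna(gene) else str(gene)
                        cdna = row.get("cdna_change")
                        rec.cdna_change = (
                            None if cdna is None or (isinstance(cdna, float) and pd.isna(cdna)) or cdna == "" else str(cdna)
                        )
                        rec.consequence_class = ConsequenceClass(row.get("consequence_class", "other"))
                        rec.frequencies = _frequencies_from_row(row)
                        rec.sift = _opt_float(row.get("sift"))
                        rec.polyphen = _opt_float(row.get("polyphen"))
                        rec.phylop = _opt_float(row.get("phylop"))
                records.append(rec)
    return records


def write_vcf(variants: Sequence[VariantRecord], sample_names: Sequence[str], path) -> None:
    """Write decomposed biallelic records as a minimal VCF 4.2 text file."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    for rec in sorted(variants, key=lambda r: (r.chromosome, r.position, r.ref_allele, r.alt_allele)):
        gts = "\t".join(_GT_CODE[rec.genotype(s)] for s in sample_names)
        lines.append(
            f"{rec.chromosome}\t{rec.position}\t.\t{rec.ref_allele}\t{rec.alt_allele}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene lists, coverage, reports


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = line.split("#")[0].strip()
        if sym:
            out.append(sym)
    return out


def default_asd_genes() -> list[str]:
    """The packaged list of genes previously associated with ASD."""
    text = resources.files("excavar.data").joinpath(_ASD_GENE_FILE).read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def write_coverage_bed(mask: CoverageMask, path) -> None:
    with open(path, "w") as fh:
        for sample, ivs in sorted(mask.covered_intervals.items()):
            for start, end in ivs:
                fh.write(f"{mask.gene}\t{start}\t{end}\t{sample}\n")


def read_coverage_bed(path, exon_intervals: Optional[dict] = None) -> CoverageMask:
    covered: dict[str, list] = {}
    gene = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        g, start, end, sample = line.split("\t")[:4]
        gene = g
        covered.setdefault(sample, []).append((int(start), int(end)))
    return CoverageMask(gene=gene or "", covered_intervals=covered, exon_intervals=exon_intervals or {})


def write_report(candidates, trace, tsv_path, trace_path=None) -> None:
    """Write the candidate-gene TSV plus a JSON trace of per-step counts.

    ``candidates`` is a list of (gene, family_id, model, variant) tuples or a
    :class:`pandas.DataFrame` with those columns; ``trace`` is any object with
    a ``to_dict()`` (a :class:`excavar.prioritize.FilterTrace`) or a plain
    mapping.
    """
    if isinstance(candidates, pd.DataFrame):
        df = candidates
    else:
        rows = []
        for gene, family_id, model, variant in candidates:
            rows.append(
                {
                    "gene": gene,
                    "family": family_id,
                    "model": model,
                    "chrom": variant.chromosome,
                    "pos": variant.position,
                    "ref": variant.ref_allele,
                    "alt": variant.alt_allele,
                    "cdna_change": variant.cdna_change or "",
                    "zygosity": "/".join(
                        f"{iid}:{gt.value}" for iid, gt in sorted(variant.genotypes.items()) if gt.carries_alt
                    ),
                }
            )
        df = pd.DataFrame(
            rows,
            columns=["gene", "family", "model", "chrom", "pos", "ref", "alt", "cdna_change", "zygosity"],
        )
    df.to_csv(tsv_path, sep="\t", index=False)
    if trace_path is not None:
        payload = trace.to_dict() if hasattr(trace, "to_dict") else trace
        Path(trace_path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
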