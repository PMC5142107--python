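"""Synthetic multi-family exome cohorts with planted causal configurations.

The generator emulates the inputs of a three-family recessive gene hunt:
per-proband exonic variant tables of realistic size (~25,000 variants), a
pedigree file, per-database frequency annotations and per-sample coverage
intervals. Three planted scenarios mirror the canonical family structures —
a consanguineous family with a homozygous missense variant, a trio with a
compound-heterozygous frameshift + splice pair, and a partially genotyped
family (father unavailable) compound heterozygous for two splice variants,
one of which can be hidden behind an exome coverage gap.

Background variants draw their true allele frequency from a two-mode
mixture (common: uniform 0.01-0.5; rare: exponential with mean 0.001) and
their per-database counts binomially at four fixed database depths, so the
rarity filter produces the familiar attrition from ~25,000 variants to a
hundred-odd rare ones. Deterministic given a seed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ANNOTATION_COLUMNS,
    ConsequenceClass,
    CoverageMask,
    FrequencyRecord,
    FrequencySource,
    Genotype,
    PedigreeSample,
    Sex,
    by_family,
    write_coverage_bed,
    write_ped,
    write_vcf,
)
from .cpamd8_fixture import cpamd8_transcript
from .splicing import TranscriptModel, parse_cdna_change

__all__ = [
    "Inheritance",
    "CausalVariantSpec",
    "CohortScenario",
    "BackgroundModel",
    "GeneLayout",
    "Cohort",
    "paper_analogue_pedigree",
    "paper_analogue_scenarios",
    "generate_cohort",
    "mask_coverage",
]

#: Simulated database depths (total alleles) for the four frequency sources.
SOURCE_DEPTHS = {
    FrequencySource.INTERNAL: 1_980,
    FrequencySource.EVS: 12_000,
    FrequencySource.EXAC: 120_000,
    FrequencySource.THOUSAND_GENOMES: 5_008,
}

#: Published-style database counts for the five planted causal variants:
#: (source -> (alt count, total alleles)); homozygote counts are all zero.
PLANTED_COUNTS = {
    "c.4351T>C": {"internal": (0, 1980), "thousand_genomes": (0, 5008), "evs": (0, 12378), "exac": (0, 116178)},
    "c.2352_2353insC": {"internal": (0, 1980), "thousand_genomes": (0, 5008), "evs": (21, 11520), "exac": (47, 115670)},
    "c.4549-1G>A": {"internal": (0, 1980), "thousand_genomes": (0, 5008), "evs": (1, 12356), "exac": (1, 120688)},
    "c.700+1G>T": {"internal": (0, 1980), "thousand_genomes": (0, 5008), "evs": (0, 12140), "exac": (0, 120212)},
    "c.4002+1G>A": {"internal": (0, 1980), "thousand_genomes": (0, 5008), "evs": (0, 12350), "exac": (0, 120350)},
}

_KNOWN_GENE_CHROMS = {
    "FOXC1": "6", "PITX2": "4", "PAX6": "11", "PITX3": "10", "FOXE3": "1",
    "BMP4": "14", "CHRDL1": "X", "LTBP2": "14", "CYP1B1": "2",
}
_SPECIAL_GENE_CHROMS = {"CPAMD8": "19", "DECOYAB": "5", "CKAP2": "13", "ARMCX4": "X"}

_AUTOSOMES = [str(c) for c in range(1, 23)]
_CHROM_CYCLE = _AUTOSOMES + ["X"]  # background genes; ~4% land on X


class Inheritance(str, enum.Enum):
    HOMOZYGOUS_CONSANGUINEOUS = "homozygous_consanguineous"
    COMPOUND_HET_FULL_TRIO = "compound_het_full_trio"
    COMPOUND_HET_PARTIAL_GENOTYPING = "compound_het_partial_genotyping"


@dataclass(frozen=True, slots=True)
class CausalVariantSpec:
    cdna_change: str
    consequence_class: ConsequenceClass
    genotypes: dict  # individual_id -> Genotype (planted exactly)


@dataclass(slots=True)
class CohortScenario:
    scenario_id: str
    inheritance: Inheritance
    causal_gene: str
    causal_variant_specs: list
    coverage_gap_exons: tuple = ()

    def __post_init__(self) -> None:
        n = len(self.causal_variant_specs)
        if self.inheritance == Inheritance.HOMOZYGOUS_CONSANGUINEOUS and n != 1:
            raise ValueError("homozygous scenario plants exactly 1 causal variant")
        if self.inheritance != Inheritance.HOMOZYGOUS_CONSANGUINEOUS and n != 2:
            raise ValueError("compound-het scenarios plant exactly 2 causal variants")


@dataclass(slots=True)
class BackgroundModel:
    """Parameters of the exome-scale background variant generator."""

    n_variants_per_proband: int = 25_000
    fraction_rare: float = 0.005
    common_af_range: tuple = (0.01, 0.5)
    rare_af_mean: float = 0.001
    n_genes: int = 18_000


@dataclass(slots=True)
class GeneLayout:
    """Toy genomic projection of a transcript: fixed-length introns."""

    transcript: TranscriptModel
    chromosome: str
    offset: int
    intron_length: int = 200

    def genomic(self, c_position: int) -> int:
        introns_before = sum(1 for e in self.transcript.exons if e.c_end < c_position)
        return self.offset + (c_position - 1) + self.intron_length * introns_before

    def genomic_of_change(self, cdna_change: str) -> int:
        var = parse_cdna_change(cdna_change)
        if var.kind == "intronic_sub":
            return self.genomic(var.start) + var.offset
        return self.genomic(var.start)

    def exon_interval(self, index: int) -> tuple[int, int]:
        """0-based half-open genomic interval of one exon."""
        e = self.transcript.exon(index)
        return (self.genomic(e.c_start) - 1, self.genomic(e.c_end))


@dataclass(slots=True)
class Cohort:
    variants: list
    pedigree: list
    vcf_samples: list
    transcript: TranscriptModel
    layout: GeneLayout
    scenarios: list
    background: BackgroundModel
    causal_gene: str
    planted_causal: list
    masks: dict = field(default_factory=dict)  # (gene, sample) -> CoverageMask
    rescue_records: list = field(default_factory=list)

    @property
    def probands(self) -> dict:
        out = {}
        for fam, members in by_family(self.pedigree).items():
            affected = [s for s in members if s.affected]
            if affected:
                out[fam] = affected[0].individual_id
        return out

    def write(self, directory) -> dict:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": directory / "cohort.vcf",
            "ped": directory / "cohort.ped",
            "annotations": directory / "annotations.tsv",
        }
        write_vcf(self.variants, self.vcf_samples, paths["vcf"])
        write_ped(self.pedigree, paths["ped"])
        self.annotation_table().to_csv(paths["annotations"], sep="\t", index=False)
        for i, mask in enumerate(self.masks.values()):
            p = directory / f"coverage_{i}.bed"
            write_coverage_bed(mask, p)
            paths[f"coverage_{i}"] = p
        return paths

    def annotation_table(self) -> pd.DataFrame:
        rows = []
        for v in sorted(self.variants + self.rescue_records, key=lambda r: r.key):
            row = {
                "chrom": v.chromosome, "pos": v.position, "ref": v.ref_allele,
                "alt": v.alt_allele, "gene": v.gene, "cdna_change": v.cdna_change or "",
                "consequence_class": v.consequence_class.value,
                "sift": v.sift, "polyphen": v.polyphen, "phylop": v.phylop,
            }
            prefix = {
                FrequencySource.THOUSAND_GENOMES: "kg", FrequencySource.EVS: "evs",
                FrequencySource.EXAC: "exac", FrequencySource.INTERNAL: "internal",
            }
            for f in v.frequencies:
                p = prefix[f.source]
                row[f"{p}_ac"] = f.alt_allele_count
                row[f"{p}_an"] = f.total_alleles
                row[f"{p}_hom"] = f.homozygote_count
            rows.append(row)
        df = pd.DataFrame(rows)
        seen = df.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
        return seen.reindex(columns=ANNOTATION_COLUMNS)


def paper_analogue_pedigree() -> tuple[list[PedigreeSample], list[str]]:
    """The three-family pedigree template and the genotyped-sample list.

    Family 1: consanguineous trio; family 2: trio with a male proband;
    family 3: parents, one unaffected child with a daughter, and two
    affected siblings — the father and the unaffected child are not
    genotyped (no DNA available).
    """
    P = PedigreeSample
    ped = [
        P("F1", "F1-I1", sex=Sex.MALE), P("F1", "F1-I2", sex=Sex.FEMALE),
        P("F1", "F1-II1", "F1-I1", "F1-I2", Sex.FEMALE, affected=True),
        P("F2", "F2-I1", sex=Sex.MALE), P("F2", "F2-I2", sex=Sex.FEMALE),
        P("F2", "F2-II1", "F2-I1", "F2-I2", Sex.MALE, affected=True),
        P("F3", "F3-I1", sex=Sex.MALE), P("F3", "F3-I2", sex=Sex.FEMALE),
        P("F3", "F3-II1", "F3-I1", "F3-I2", Sex.FEMALE),
        P("F3", "F3-II2", "F3-I1", "F3-I2", Sex.FEMALE, affected=True),
        P("F3", "F3-II3", "F3-I1", "F3-I2", Sex.MALE, affected=True),
        P("F3", "F3-III1", "0", "F3-II1", Sex.FEMALE),
    ]
    genotyped = [s.individual_id for s in ped if s.individual_id not in ("F3-I1", "F3-II1")]
    return ped, genotyped


def paper_analogue_scenarios(causal_gene: str = "CPAMD8") -> list[CohortScenario]:
    """The three planted scenarios mirroring the study's family configurations."""
    C = CausalVariantSpec
    G = Genotype
    return [
        CohortScenario(
            "family1", Inheritance.HOMOZYGOUS_CONSANGUINEOUS, causal_gene,
            [C("c.4351T>C", ConsequenceClass.MISSENSE,
               {"F1-II1": G.HOM_ALT, "F1-I1": G.HET, "F1-I2": G.HET})],
        ),
        CohortScenario(
            "family2", Inheritance.COMPOUND_HET_FULL_TRIO, causal_gene,
            [C("c.2352_2353insC", ConsequenceClass.FRAMESHIFT,
               {"F2-II1": G.HET, "F2-I1": G.HET, "F2-I2": G.HOM_REF}),
             C("c.4549-1G>A", ConsequenceClass.SPLICE_SITE,
               {"F2-II1": G.HET, "F2-I1": G.HOM_REF, "F2-I2": G.HET})],
        ),
        CohortScenario(
            "family3", Inheritance.COMPOUND_HET_PARTIAL_GENOTYPING, causal_gene,
            [C("c.4002+1G>A", ConsequenceClass.SPLICE_SITE,
               {"F3-II2": G.HET, "F3-II3": G.HET, "F3-I2": G.HOM_REF, "F3-III1": G.HOM_REF}),
             C("c.700+1G>T", ConsequenceClass.SPLICE_SITE,
               {"F3-II2": G.HET, "F3-II3": G.HET, "F3-I2": G.HET, "F3-III1": G.HET})],
            coverage_gap_exons=(3, 7, 11, 18, 24, 30),
        ),
    ]


# ---------------------------------------------------------------------------
# generation internals


def _gene_pool(n_genes: int) -> tuple[list[str], dict]:
    specials = list(_SPECIAL_GENE_CHROMS) + list(_KNOWN_GENE_CHROMS)
    names = specials + [f"G{i:05d}" for i in range(n_genes)]
    chroms = dict(_SPECIAL_GENE_CHROMS) | dict(_KNOWN_GENE_CHROMS)
    for i in range(n_genes):
        chroms[f"G{i:05d}"] = _CHROM_CYCLE[i % len(_CHROM_CYCLE)]
    return names, chroms


def _vcf_ref_alt(transcript: TranscriptModel, cdna_change: str) -> tuple[str, str]:
    """VCF-style REF/ALT for a planted HGVS change on the causal transcript."""
    var = parse_cdna_change(cdna_change)
    cds = transcript.coding_sequence
    if var.kind == "sub":
        return var.ref, var.alt
    if var.kind == "intronic_sub":
        return var.ref, var.alt
    if var.kind == "ins":
        anchor = cds[var.start - 1]
        return anchor, anchor + var.alt
    anchor = cds[var.start - 2] if var.start > 1 else cds[var.end]
    return anchor + cds[var.start - 1 : var.end], anchor


def _draw_frequencies(rng: np.random.Generator, afs: np.ndarray) -> list[list[FrequencyRecord]]:
    """Binomial per-database counts at the fixed depths, per variant."""
    n = len(afs)
    cols = []
    for source, depth in SOURCE_DEPTHS.items():
        ac = rng.binomial(depth, afs)
        hom = np.minimum(rng.binomial(depth // 2, afs**2), ac // 2)
        cols.append((source, depth, ac.tolist(), hom.tolist()))
    return [
        [FrequencyRecord(src, ac[i], depth, hom[i]) for src, depth, ac, hom in cols]
        for i in range(n)
    ]


def _planted_frequencies(cdna_change: str) -> list[FrequencyRecord]:
    counts = PLANTED_COUNTS.get(cdna_change)
    if counts is None:  # unseen planted change: absent everywhere
        return [FrequencyRecord(src, 0, depth, 0) for src, depth in SOURCE_DEPTHS.items()]
    return [
        FrequencyRecord(FrequencySource(src), ac, an, 0) for src, (ac, an) in counts.items()
    ]


from .core_io import VariantRecord  # noqa: E402  (after dataclass deps)


def generate_cohort(
    scenarios: Optional[Sequence[CohortScenario]] = None,
    background: Optional[BackgroundModel] = None,
    seed: int = 0,
) -> Cohort:
    """Generate the multi-family cohort: planted causal variants, decoys and
    exome-scale background. Deterministic given ``seed``."""
    scenarios = list(scenarios) if scenarios is not None else paper_analogue_scenarios()
    background = background or BackgroundModel()
    rng = np.random.default_rng(seed)
    pedigree, vcf_samples = paper_analogue_pedigree()
    sample_by_id = {s.individual_id: s for s in pedigree}
    transcript = cpamd8_transcript()
    layout = GeneLayout(transcript, chromosome=_SPECIAL_GENE_CHROMS["CPAMD8"], offset=10_000_000)
    gene_names, gene_chroms = _gene_pool(background.n_genes)
    n_special = len(_SPECIAL_GENE_CHROMS) + len(_KNOWN_GENE_CHROMS)
    gene_offsets = {g: 1_000_000 + 50_000 * i for i, g in enumerate(gene_names)}

    variants: list[VariantRecord] = []
    planted: list[VariantRecord] = []

    # --- planted causal variants -----------------------------------------
    for scenario in scenarios:
        if scenario.causal_gene != transcript.gene:
            raise ValueError(f"no transcript model for causal gene {scenario.causal_gene!r}")
        for spec in scenario.causal_variant_specs:
            for iid, gt in spec.genotypes.items():
                s = sample_by_id.get(iid)
                if s is None:
                    raise ValueError(f"planted genotype for unknown sample {iid!r}")
                if gt in (Genotype.HOM_ALT, Genotype.HEMI) and not s.affected:
                    raise ValueError(
                        f"scenario {scenario.scenario_id}: biallelic genotype planted in "
                        f"unaffected sample {iid}"
                    )
            ref, alt = _vcf_ref_alt(transcript, spec.cdna_change)
            family = sample_by_id[next(iter(spec.genotypes))].family_id
            genotypes = {
                s.individual_id: Genotype.HOM_REF
                for s in pedigree
                if s.family_id == family and s.individual_id in vcf_samples
            }
            genotypes.update(spec.genotypes)
            rec = VariantRecord(
                chromosome=layout.chromosome,
                position=layout.genomic_of_change(spec.cdna_change),
                ref_allele=ref,
                alt_allele=alt,
                gene=scenario.causal_gene,
                cdna_change=spec.cdna_change,
                consequence_class=spec.consequence_class,
                genotypes=genotypes,
                frequencies=_planted_frequencies(spec.cdna_change),
                sift=0.01 if spec.consequence_class == ConsequenceClass.MISSENSE else None,
                polyphen=0.948 if spec.consequence_class == ConsequenceClass.MISSENSE else None,
                phylop=0.98 if spec.consequence_class == ConsequenceClass.MISSENSE else None,
            )
            variants.append(rec)
            planted.append(rec)

    # --- deterministic decoys ---------------------------------------------
    families = sorted(by_family(pedigree))
    probands = {
        fam: next(s.individual_id for s in members if s.affected)
        for fam, members in by_family(pedigree).items()
    }

    def add_decoy(gene, pos_offset, genotypes, af, conseq, sift=None, polyphen=None, phylop=None, cdna=None):
        ref, alt = "A", "G"
        afs = np.array([af])
        rec = VariantRecord(
            chromosome=gene_chroms[gene],
            position=gene_offsets[gene] + pos_offset,
            ref_allele=ref, alt_allele=alt, gene=gene, cdna_change=cdna,
            consequence_class=conseq, genotypes=dict(genotypes),
            frequencies=_draw_frequencies(rng, afs)[0],
            sift=sift, polyphen=polyphen, phylop=phylop,
        )
        variants.append(rec)
        return rec

    G = Genotype
    # common decoys inside the causal gene (filtered at step 1)
    for f_idx, fam in enumerate(families):
        pid = probands[fam]
        for k, c_pos in enumerate((150, 1500)):
            rec = add_decoy(
                "CPAMD8", 0, {pid: G.HET}, af=0.2, conseq=ConsequenceClass.SYNONYMOUS,
            )
            rec.position = layout.genomic(c_pos) + k + f_idx  # keys distinct per family
    # a rare compound-het-looking pair shared by families 1 and 2 only
    for fam in ("F1", "F2"):
        pid = probands[fam]
        father = next(s.father_id for s in pedigree if s.individual_id == pid)
        mother = next(s.mother_id for s in pedigree if s.individual_id == pid)
        add_decoy("DECOYAB", 100, {pid: G.HET, father: G.HET, mother: G.HOM_REF},
                  af=1e-4, conseq=ConsequenceClass.MISSENSE, sift=0.4, polyphen=0.3, phylop=0.2)
        add_decoy("DECOYAB", 200, {pid: G.HET, father: G.HOM_REF, mother: G.HET},
                  af=1e-4, conseq=ConsequenceClass.MISSENSE, sift=0.5, polyphen=0.2, phylop=0.1)
    # benign-looking compound-het pair private to family 3 (in cis in the mother)
    add_decoy("CKAP2", 100, {"F3-II2": G.HET, "F3-II3": G.HET, "F3-I2": G.HET, "F3-III1": G.HOM_REF},
              af=1e-4, conseq=ConsequenceClass.MISSENSE, sift=0.8, polyphen=0.1, phylop=0.3)
    add_decoy("CKAP2", 200, {"F3-II2": G.HET, "F3-II3": G.HET, "F3-I2": G.HET, "F3-III1": G.HOM_REF},
              af=1e-4, conseq=ConsequenceClass.MISSENSE, sift=0.6, polyphen=0.2, phylop=0.4)
    # rare hemizygous X missense in the family-2 male proband (benign scores)
    add_decoy("ARMCX4", 979, {"F2-II1": G.HEMI, "F2-I2": G.HET},
              af=1e-4, conseq=ConsequenceClass.MISSENSE, sift=0.6, polyphen=0.05, phylop=0.2,
              cdna="c.979A>G")

    # --- exome-scale background -------------------------------------------
    n = background.n_variants_per_proband
    lo, hi = background.common_af_range
    conseq_classes = np.array(
        [ConsequenceClass.MISSENSE, ConsequenceClass.SYNONYMOUS, ConsequenceClass.OTHER,
         ConsequenceClass.FRAMESHIFT, ConsequenceClass.SPLICE_SITE],
        dtype=object,
    )
    conseq_p = np.array([0.5, 0.3, 0.15, 0.03, 0.02])
    for fam in families:
        members = [
            s for s in by_family(pedigree)[fam] if s.individual_id in vcf_samples
        ]
        pid = probands[fam]
        proband = sample_by_id[pid]
        is_rare = rng.random(n) < background.fraction_rare
        afs = np.where(
            is_rare,
            np.clip(rng.exponential(background.rare_af_mean, n), 1e-5, 0.05),
            rng.uniform(lo, hi, n),
        )
        # rare variants avoid the special/known genes and the X chromosome
        # (the X-linked screen is exercised by the planted hemizygous decoy);
        # common variants may hit any gene
        rare_pool = np.array(
            [i for i in range(n_special, len(gene_names)) if gene_chroms[gene_names[i]] != "X"]
        )
        gene_idx = rng.integers(0, len(gene_names), n)
        gene_idx[is_rare] = rng.choice(rare_pool, int(is_rare.sum()))
        positions = rng.integers(0, 40_000, n).tolist()
        ref_i = rng.integers(0, 4, n)
        alt_i = ((ref_i + rng.integers(1, 4, n)) % 4).tolist()
        ref_i = ref_i.tolist()
        classes = rng.choice(conseq_classes, size=n, p=conseq_p).tolist()
        freqs = _draw_frequencies(rng, afs)
        sift = np.round(rng.random(n), 3).tolist()
        polyphen = np.round(rng.random(n), 3).tolist()
        phylop = np.round(rng.random(n), 3).tolist()
        # genotype draws, vectorized: proband conditioned on carrying;
        # relatives at Hardy-Weinberg for the drawn frequency
        proband_hom = (rng.random(n) < afs / (2.0 - afs)).tolist()
        rel_u = {
            s.individual_id: rng.random(n).tolist() for s in members if s.individual_id != pid
        }
        p_rr = ((1.0 - afs) ** 2).tolist()
        p_rr_or_het = (1.0 - afs**2).tolist()
        afs_list = afs.tolist()
        gene_idx = gene_idx.tolist()
        bases = "ACGT"

        seen_keys = set()
        for i in range(n):
            gene = gene_names[gene_idx[i]]
            chrom = gene_chroms[gene]
            pos = gene_offsets[gene] + positions[i]
            ref, alt = bases[ref_i[i]], bases[alt_i[i]]
            key = (chrom, pos, ref, alt)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            on_x = chrom == "X"
            genotypes = {pid: (
                Genotype.HEMI if on_x and proband.sex == Sex.MALE
                else (Genotype.HOM_ALT if proband_hom[i] else Genotype.HET)
            )}
            for s in members:
                sid = s.individual_id
                if sid == pid:
                    continue
                u = rel_u[sid][i]
                if on_x and s.sex == Sex.MALE:
                    genotypes[sid] = Genotype.HEMI if u < afs_list[i] else Genotype.HOM_REF
                elif u < p_rr[i]:
                    genotypes[sid] = Genotype.HOM_REF
                elif u < p_rr_or_het[i]:
                    genotypes[sid] = Genotype.HET
                else:
                    genotypes[sid] = Genotype.HOM_ALT
            variants.append(
                VariantRecord(
                    chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt,
                    gene=gene, consequence_class=classes[i],
                    genotypes=genotypes, frequencies=freqs[i],
                    sift=sift[i], polyphen=polyphen[i], phylop=phylop[i],
                )
            )

    return Cohort(
        variants=variants,
        pedigree=pedigree,
        vcf_samples=vcf_samples,
        transcript=transcript,
        layout=layout,
        scenarios=scenarios,
        background=background,
        causal_gene=transcript.gene,
        planted_causal=planted,
    )


def mask_coverage(
    cohort: Cohort,
    gene: str,
    exon_indices: Sequence[int],
    sample: str,
    flank: int = 8,
) -> CoverageMask:
    """Apply an exome coverage gap over some exons of a gene for one sample.

    The sample's covered intervals become every exon *not* in
    ``exon_indices`` (each padded by ``flank`` bases, so splice-site
    variants at exon edges belong to their exon's capture interval). Any
    variant of the gene inside a masked interval that the sample carries is
    set to missing in the cohort and stashed as a targeted-sequencing rescue
    record. Masking a gene without a transcript model is allowed but only
    produces a warning (nothing to mask).
    """
    if gene != cohort.causal_gene:
        warnings.warn(f"masking exons of non-causal gene {gene!r}: no transcript, no-op", stacklevel=2)
        return CoverageMask(gene=gene)
    layout = cohort.layout
    n_exons = cohort.transcript.n_exons
    for k in exon_indices:
        cohort.transcript.exon(k)  # validates the index
    masked = set(exon_indices)
    covered = [
        (max(0, layout.exon_interval(k)[0] - flank), layout.exon_interval(k)[1] + flank)
        for k in range(1, n_exons + 1)
        if k not in masked
    ]
    exon_intervals = {k: layout.exon_interval(k) for k in range(1, n_exons + 1)}
    mask = CoverageMask(gene=gene, covered_intervals={sample: covered}, exon_intervals=exon_intervals)

    masked_spans = [
        (max(0, layout.exon_interval(k)[0] - flank), layout.exon_interval(k)[1] + flank)
        for k in sorted(masked)
    ]
    for v in cohort.variants:
        if v.gene != gene:
            continue
        p0 = v.position - 1  # 0-based
        if any(a <= p0 < b for a, b in masked_spans) and v.genotype(sample).carries_alt:
            rescue = replace(v, genotypes=dict(v.genotypes), frequencies=list(v.frequencies))
            cohort.rescue_records.append(rescue)
            v.genotypes[sample] = Genotype.MISSING
    cohort.masks[(gene, sample)] = mask
    return mask
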