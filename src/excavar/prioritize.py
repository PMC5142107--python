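"""The four-step exome filtering cascade plus the coverage-gap rescue.

The cascade mirrors how rare recessive disease genes are found from
per-proband exome variant tables:

1. **Rarity** — drop every variant whose minor allele frequency exceeds a
   threshold (default 0.005, inclusive) in *any* population database
   attached to it, then cross-reference survivors against genes already
   known to cause the phenotype.
2. **X-linked screen** — for male probands, list rare hemizygous X variants
   for manual review.
3. **Recessive models** — per family, keep genes with a homozygous rare
   variant or with two or more distinct rare heterozygous variants
   (potential compound heterozygotes).
4. **Cross-family intersection** — keep genes qualifying in every family.

When the intersection is empty (or survivors are implausible on in-silico
grounds), a singleton-heterozygote fallback re-ranks genes qualifying in
all families but one, provided the remaining family carries at least one
rare heterozygous variant in the gene — formalizing the manual re-analysis
that rescues a second allele hiding in an exome coverage gap, which the
coverage-gap report then pinpoints for targeted (Sanger) follow-up.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .core_io import (
    ConsequenceClass,
    CoverageMask,
    FrequencyRecord,
    Genotype,
    PedigreeSample,
    Sex,
    VariantRecord,
    by_family,
)
from .splicing import TranscriptModel

__all__ = [
    "FilterTrace",
    "GeneModel",
    "FamilyCandidate",
    "allele_frequency",
    "filter_rare",
    "homozygote_screen",
    "partition_zygosity",
    "known_gene_crossref",
    "xlinked_step",
    "recessive_step",
    "intersect_step",
    "singleton_het_fallback",
    "plausibility_score",
    "coverage_gap_report",
    "run_pipeline",
    "PipelineResult",
]

MAF_THRESHOLD = Fraction(1, 200)  # 0.005

# in-silico support thresholds (ranking evidence only, never a hard filter)
SIFT_DAMAGING_BELOW = 0.05
POLYPHEN_DAMAGING_AT_LEAST = 0.85
PHYLOP_CONSERVED_ABOVE = 0.95


@dataclass(slots=True)
class FilterTrace:
    """Per-step record of the cascade: label, input/retained counts and keys."""

    steps: list = field(default_factory=list)

    def add(self, label: str, input_variants: Sequence, retained: Sequence) -> None:
        retained_keys = {v.key for v in retained}
        input_keys = {v.key for v in input_variants}
        if not retained_keys <= input_keys:
            raise ValueError(f"step {label!r} retained variants not in its input")
        self.steps.append(
            {
                "label": label,
                "n_input": len(input_keys),
                "n_retained": len(retained_keys),
                "retained_keys": sorted(retained_keys),
            }
        )

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s["label"], s["n_input"], s["n_retained"]) for s in self.steps]

    def to_dict(self) -> dict:
        return {"steps": [dict(s, retained_keys=[list(k) for k in s["retained_keys"]]) for s in self.steps]}


class GeneModel(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    POTENTIAL_COMPOUND_HET = "potential_compound_het"


@dataclass(slots=True)
class FamilyCandidate:
    """One gene qualifying under one recessive model in one family."""

    gene: str
    family_id: str
    proband_id: str
    model: GeneModel
    variants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model == GeneModel.POTENTIAL_COMPOUND_HET and len({v.key for v in self.variants}) < 2:
            raise ValueError("potential compound het requires >= 2 distinct variants")


def allele_frequency(rec: FrequencyRecord) -> Fraction:
    """Exact alternate-allele frequency of one database record."""
    if rec.total_alleles <= 0:
        raise ValueError("total_alleles must be positive")
    return Fraction(rec.alt_allele_count, rec.total_alleles)


def _max_af(variant: VariantRecord) -> Fraction:
    if not variant.frequencies:
        return Fraction(0)
    return max(allele_frequency(f) for f in variant.frequencies)


def filter_rare(
    variants: Sequence[VariantRecord],
    threshold: float = 0.005,
    trace: Optional[FilterTrace] = None,
    label: str = "step1_rare",
) -> list[VariantRecord]:
    """Retain variants rare (MAF <= threshold, inclusive) in every database.

    A variant common in *any* source is filtered; a source with no record
    contributes frequency zero. The comparison is exact rational arithmetic,
    so a variant at exactly the threshold is retained.
    """
    cutoff = Fraction(str(threshold))
    retained = [v for v in variants if _max_af(v) <= cutoff]
    if trace is not None:
        trace.add(label, variants, retained)
    return retained


def homozygote_screen(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Flag (not remove) variants with homozygotes in any population database.

    A recessive candidate seen homozygous in population controls is suspect;
    the flagged subset is returned as an annotation, the input is untouched.
    """
    return [v for v in variants if v.population_homozygotes() > 0]


def partition_zygosity(
    variants: Sequence[VariantRecord], proband_id: str
) -> dict[Genotype, list[VariantRecord]]:
    """Partition the proband's non-reference variants by zygosity."""
    parts: dict[Genotype, list[VariantRecord]] = {
        Genotype.HOM_ALT: [],
        Genotype.HET: [],
        Genotype.HEMI: [],
    }
    for v in variants:
        if proband_id not in v.genotypes:
            raise ValueError(f"proband {proband_id!r} missing from genotype map of {v.key}")
        g = v.genotype(proband_id)
        if g in parts:
            parts[g].append(v)
    return parts


def known_gene_crossref(
    retained: Sequence[VariantRecord], known_genes: Iterable[str]
) -> list[VariantRecord]:
    """Rare variants falling in genes already associated with the phenotype."""
    known = set(known_genes)
    return [v for v in retained if v.gene in known]


def xlinked_step(
    retained: Sequence[VariantRecord], proband: PedigreeSample
) -> list[VariantRecord]:
    """Rare hemizygous X-chromosome candidates for a male proband."""
    if proband.sex != Sex.MALE:
        warnings.warn(
            f"X-linked step applied to non-male proband {proband.individual_id}", stacklevel=2
        )
        return []
    return [
        v
        for v in retained
        if v.is_x and v.genotype(proband.individual_id) in (Genotype.HEMI, Genotype.HOM_ALT)
    ]


def recessive_step(
    retained: Sequence[VariantRecord],
    proband: PedigreeSample,
    trace: Optional[FilterTrace] = None,
) -> list[FamilyCandidate]:
    """Autosomal recessive candidate genes for one family.

    A gene qualifies with one homozygous rare variant (model ``homozygous``)
    or with >= 2 distinct rare heterozygous variants (model
    ``potential_compound_het``). X-chromosome variants are excluded here
    (see :func:`xlinked_step`).
    """
    pid = proband.individual_id
    parts = partition_zygosity(retained, pid)
    autosomal_hom = [v for v in parts[Genotype.HOM_ALT] if not v.is_x and v.gene]
    autosomal_het = [v for v in parts[Genotype.HET] if not v.is_x and v.gene]

    candidates: list[FamilyCandidate] = []
    by_gene_hom: dict[str, list] = {}
    for v in autosomal_hom:
        by_gene_hom.setdefault(v.gene, []).append(v)
    for gene, vs in sorted(by_gene_hom.items()):
        candidates.append(FamilyCandidate(gene, proband.family_id, pid, GeneModel.HOMOZYGOUS, vs))
    by_gene_het: dict[str, list] = {}
    for v in autosomal_het:
        by_gene_het.setdefault(v.gene, []).append(v)
    for gene, vs in sorted(by_gene_het.items()):
        if len({v.key for v in vs}) >= 2:
            candidates.append(
                FamilyCandidate(gene, proband.family_id, pid, GeneModel.POTENTIAL_COMPOUND_HET, vs)
            )
    if trace is not None:
        kept = [v for c in candidates for v in c.variants]
        trace.add("step3_recessive", retained, kept)
    return candidates


def intersect_step(per_family_candidates: dict[str, list[FamilyCandidate]]) -> set[str]:
    """Genes qualifying under some recessive model in every family."""
    if len(per_family_candidates) < 2:
        warnings.warn("intersection over a single family is the identity", stacklevel=2)
    gene_sets = [
        {c.gene for c in candidates} for candidates in per_family_candidates.values()
    ]
    shared = set.intersection(*gene_sets) if gene_sets else set()
    return shared


def singleton_het_fallback(
    per_family_candidates: dict[str, list[FamilyCandidate]],
    retained_by_family: dict[str, list[VariantRecord]],
    probands: dict[str, str],
) -> list[dict]:
    """Re-rank genes qualifying in all families but one.

    For each such gene, the remaining family must contribute at least one
    rare heterozygous variant (a "singleton het") in the gene — the
    signature of a second allele hidden by a coverage gap. Returns one row
    per (gene, missing family) with the singleton variants.
    """
    families = list(per_family_candidates)
    out: list[dict] = []
    for missing in families:
        others = [f for f in families if f != missing]
        if not others:
            continue
        shared_elsewhere = set.intersection(
            *({c.gene for c in per_family_candidates[f]} for f in others)
        )
        already = {c.gene for c in per_family_candidates[missing]}
        for gene in sorted(shared_elsewhere - already):
            pid = probands[missing]
            singles = [
                v
                for v in retained_by_family[missing]
                if v.gene == gene and v.genotype(pid) == Genotype.HET
            ]
            if singles:
                out.append({"gene": gene, "missing_family": missing, "singleton_hets": singles})
    return out


def plausibility_score(variants: Sequence[VariantRecord]) -> float:
    """Fraction of a gene's candidate variants with damaging support.

    Loss-of-function classes (frameshift, splice site) count as damaging by
    nature; missense variants count when SIFT < 0.05, PolyPhen-2 >= 0.85 or
    PhyloP > 0.95. Used to *rank* candidate genes, never to filter them.
    """
    if not variants:
        return 0.0
    damaging = 0
    for v in variants:
        if v.consequence_class in (ConsequenceClass.FRAMESHIFT, ConsequenceClass.SPLICE_SITE):
            damaging += 1
            continue
        if (
            (v.sift is not None and v.sift < SIFT_DAMAGING_BELOW)
            or (v.polyphen is not None and v.polyphen >= POLYPHEN_DAMAGING_AT_LEAST)
            or (v.phylop is not None and v.phylop > PHYLOP_CONSERVED_ABOVE)
        ):
            damaging += 1
    return damaging / len(variants)


def coverage_gap_report(
    candidate_gene: str,
    transcript: TranscriptModel,
    mask: CoverageMask,
    sample: str,
) -> list[int]:
    """Coding exons of a candidate gene with zero coverage in one sample.

    An exon counts as uncovered when none of the sample's covered intervals
    overlaps its genomic interval; uncovered exons are flagged for targeted
    (Sanger) follow-up.
    """
    if transcript is None:
        raise ValueError(f"no transcript model available for {candidate_gene}")
    if mask.gene != candidate_gene:
        raise ValueError(f"mask is for {mask.gene!r}, not {candidate_gene!r}")
    covered = mask.covered_intervals.get(sample, [])
    gaps: list[int] = []
    for exon in transcript.exons:
        interval = mask.exon_intervals.get(exon.index)
        if interval is None:
            continue
        a, b = interval
        if not any(s < b and a < e for s, e in covered):
            gaps.append(exon.index)
    return gaps


@dataclass(slots=True)
class PipelineResult:
    traces: dict  # family_id -> FilterTrace
    retained_by_family: dict
    candidates_by_family: dict  # family_id -> list[FamilyCandidate]
    known_gene_hits: dict
    xlinked_candidates: dict
    shared_genes: set
    fallback: list
    verdicts: list
    probands: dict

    @property
    def final_genes(self) -> set[str]:
        """Shared genes, or the fallback genes when the intersection fails."""
        if self.shared_genes:
            return set(self.shared_genes)
        return {row["gene"] for row in self.fallback}

    def candidate_rows(self) -> list[tuple]:
        rows = []
        for fam, cands in sorted(self.candidates_by_family.items()):
            for c in cands:
                if c.gene in self.final_genes:
                    for v in c.variants:
                        rows.append((c.gene, fam, c.model.value, v))
        for row in self.fallback:
            for v in row["singleton_hets"]:
                rows.append((row["gene"], row["missing_family"], "singleton_het", v))
        return rows

    def trace_dict(self) -> dict:
        return {fam: t.to_dict() for fam, t in self.traces.items()}


def run_pipeline(
    variants: Sequence[VariantRecord],
    pedigree: Sequence[PedigreeSample],
    known_genes: Iterable[str] = (),
    maf_threshold: float = 0.005,
    rescue_variants: Sequence[VariantRecord] = (),
    xlinked_families: Optional[set] = None,
    run_segregation: bool = True,
) -> PipelineResult:
    """Run the full cascade over a multi-family cohort.

    ``rescue_variants`` are targeted-sequencing records (e.g. Sanger results
    covering exome gaps) merged into their carrier families' retained sets
    before the recessive step. ``xlinked_families`` limits the X-linked
    screen to specific families (default: every family with a male proband).
    """
    families = by_family(pedigree)
    probands: dict[str, str] = {}
    for fam, members in families.items():
        affected = [s for s in members if s.affected]
        if not affected:
            continue
        probands[fam] = affected[0].individual_id

    traces: dict[str, FilterTrace] = {}
    retained_by_family: dict[str, list[VariantRecord]] = {}
    candidates_by_family: dict[str, list[FamilyCandidate]] = {}
    known_hits: dict[str, list] = {}
    xlinked: dict[str, list] = {}
    known_genes = list(known_genes)

    for fam, pid in probands.items():
        proband = next(s for s in families[fam] if s.individual_id == pid)
        trace = FilterTrace()
        fam_variants = [v for v in variants if pid in v.genotypes and v.genotype(pid).carries_alt]
        retained = filter_rare(fam_variants, maf_threshold, trace=trace)
        known_hits[fam] = known_gene_crossref(retained, known_genes)
        rescued = [
            v
            for v in rescue_variants
            if pid in v.genotypes and v.genotype(pid).carries_alt
        ]
        if rescued:
            rescued = filter_rare(rescued, maf_threshold)
            retained = retained + [v for v in rescued if v.key not in {r.key for r in retained}]
        retained_by_family[fam] = retained
        if proband.sex == Sex.MALE and (xlinked_families is None or fam in xlinked_families):
            xcands = xlinked_step(retained, proband)
            xlinked[fam] = xcands
            trace.add("step2_xlinked", retained, xcands)
        candidates_by_family[fam] = recessive_step(retained, proband, trace=trace)
        traces[fam] = trace

    shared = intersect_step(candidates_by_family) if candidates_by_family else set()
    for fam, trace in traces.items():
        kept = [
            v
            for c in candidates_by_family[fam]
            if c.gene in shared
            for v in c.variants
        ]
        pool = [v for c in candidates_by_family[fam] for v in c.variants]
        trace.add("step4_shared", pool, kept)

    fallback: list[dict] = []
    if not shared and len(candidates_by_family) >= 2:
        fallback = singleton_het_fallback(candidates_by_family, retained_by_family, probands)

    verdicts: list = []
    if run_segregation:
        from .segregate import classify_inheritance

        interesting = [
            c
            for fam, cands in candidates_by_family.items()
            for c in cands
            if c.gene in shared or c.gene in {row["gene"] for row in fallback}
        ]
        verdicts = classify_inheritance(interesting, pedigree)

    return PipelineResult(
        traces=traces,
        retained_by_family=retained_by_family,
        candidates_by_family=candidates_by_family,
        known_gene_hits=known_hits,
        xlinked_candidates=xlinked,
        shared_genes=shared,
        fallback=fallback,
        verdicts=verdicts,
        probands=probands,
    )
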