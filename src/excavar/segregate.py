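"""Pedigree segregation tests for autosomal-recessive candidate variants.

Two recessive configurations are tested: a homozygous variant, and a pair
of heterozygous variants that must lie in trans (compound heterozygosity).
The model assumes complete penetrance: an individual is affected if and
only if both gene copies carry a pathogenic allele. Missing genotypes never
make a verdict inconsistent — they only cap how confidently phase can be
asserted (``confirmed_trans`` needs both parents observed; ``inferred_trans``
needs one observed parent carrying exactly one of the two alleles, the
other allele being imputed to the unobserved parent).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core_io import Genotype, PedigreeSample, VariantRecord

__all__ = [
    "InheritanceModel",
    "Phase",
    "SegregationVerdict",
    "check_homozygous",
    "check_compound_het",
    "classify_inheritance",
]


class InheritanceModel(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    COMPOUND_HET = "compound_het"


class Phase(str, enum.Enum):
    CONFIRMED_TRANS = "confirmed_trans"
    INFERRED_TRANS = "inferred_trans"
    UNPHASED = "unphased"


@dataclass(slots=True)
class SegregationVerdict:
    model: InheritanceModel
    consistent: bool
    phase: Phase = Phase.UNPHASED
    evidence: dict = field(default_factory=dict)  # individual_id -> note

    def __post_init__(self) -> None:
        if self.phase == Phase.CONFIRMED_TRANS and not self.consistent:
            raise ValueError("confirmed_trans verdict cannot be inconsistent")


def _find_proband(family: Sequence[PedigreeSample], proband_id: Optional[str]) -> PedigreeSample:
    if proband_id is not None:
        for s in family:
            if s.individual_id == proband_id:
                return s
        raise ValueError(f"proband {proband_id!r} not in family")
    affected = [s for s in family if s.affected]
    if not affected:
        raise ValueError("family has no affected individual")
    return affected[0]


def check_homozygous(
    family: Sequence[PedigreeSample], variant: VariantRecord, proband_id: Optional[str] = None
) -> SegregationVerdict:
    """Test a homozygous candidate against a recessive model in one family.

    Consistent iff every genotyped parent of the proband is a carrier (het
    or, if affected, hom_alt), every genotyped affected member is hom_alt,
    and no genotyped unaffected member is hom_alt.
    """
    proband = _find_proband(family, proband_id)
    gt = variant.genotype(proband.individual_id)
    if gt != Genotype.HOM_ALT:
        raise ValueError(f"proband {proband.individual_id} is {gt.value}, not hom_alt")

    evidence: dict[str, str] = {}
    consistent = True
    parent_ids = {proband.father_id, proband.mother_id}
    for s in family:
        g = variant.genotype(s.individual_id)
        if g == Genotype.MISSING:
            evidence[s.individual_id] = "unobserved"
            continue
        note = g.value
        if s.affected and g != Genotype.HOM_ALT:
            consistent = False
            note += " (affected but not homozygous)"
        elif not s.affected and g == Genotype.HOM_ALT:
            consistent = False
            note += " (unaffected homozygote)"
        elif s.individual_id in parent_ids and not g.carries_alt:
            consistent = False
            note += " (non-carrier parent of homozygous child)"
        evidence[s.individual_id] = note
    return SegregationVerdict(InheritanceModel.HOMOZYGOUS, consistent, Phase.UNPHASED, evidence)


def check_compound_het(
    family: Sequence[PedigreeSample],
    variant_a: VariantRecord,
    variant_b: VariantRecord,
    proband_id: Optional[str] = None,
) -> SegregationVerdict:
    """Test a candidate compound-heterozygous pair in one family.

    Consistency requires: every genotyped affected member carries both
    alleles; no genotyped unaffected member carries both (a double carrier
    must be either affected, or an unaffected cis configuration which the
    child then inherits in cis) and no unaffected member is homozygous for
    either allele; and, among the proband's genotyped parents, each variant
    can be traced to a different parent.
    """
    if variant_a.key == variant_b.key:
        raise ValueError("compound-het test requires two distinct variants")
    proband = _find_proband(family, proband_id)
    pid = proband.individual_id
    if not (variant_a.genotype(pid).carries_alt and variant_b.genotype(pid).carries_alt):
        raise ValueError(f"proband {pid} does not carry both candidate alleles")

    def carriage(iid: str) -> Optional[tuple[bool, bool]]:
        ga, gb = variant_a.genotype(iid), variant_b.genotype(iid)
        if ga == Genotype.MISSING and gb == Genotype.MISSING:
            return None
        return (ga.carries_alt, gb.carries_alt)

    evidence: dict[str, str] = {}
    consistent = True
    for s in family:
        c = carriage(s.individual_id)
        if c is None:
            evidence[s.individual_id] = "unobserved"
            continue
        ga, gb = variant_a.genotype(s.individual_id), variant_b.genotype(s.individual_id)
        note = f"{ga.value}/{gb.value}"
        if s.affected and not (c[0] and c[1]):
            consistent = False
            note += " (affected missing one allele)"
        elif not s.affected:
            if c[0] and c[1]:
                consistent = False
                note += " (unaffected double carrier)"
            elif Genotype.HOM_ALT in (ga, gb):
                consistent = False
                note += " (unaffected homozygote)"
        evidence[s.individual_id] = note

    # phase from the proband's parents
    phase = Phase.UNPHASED
    parent_carriage = {
        parent_id: carriage(parent_id)
        for parent_id in (proband.father_id, proband.mother_id)
    }
    observed = {k: v for k, v in parent_carriage.items() if v is not None}
    if len(observed) == 2:
        (ca, cb) = observed.values()
        one_each = (ca == (True, False) and cb == (False, True)) or (
            ca == (False, True) and cb == (True, False)
        )
        if one_each:
            phase = Phase.CONFIRMED_TRANS
        else:
            # no parental origin assignment puts the two alleles in trans
            consistent = False
    elif len(observed) == 1:
        ((parent_id, c),) = observed.items()
        if sum(c) == 1:
            phase = Phase.INFERRED_TRANS
            evidence[parent_id] = evidence.get(parent_id, "") + " (other allele imputed to unobserved parent)"
        elif sum(c) == 0:
            # both alleles would have to come from the single missing parent: cis
            consistent = False
            evidence[parent_id] = evidence.get(parent_id, "") + " (carries neither allele)"
        # sum(c) == 2 already handled by the double-carrier rule
    if not consistent:
        phase = Phase.UNPHASED if phase == Phase.CONFIRMED_TRANS else phase
    return SegregationVerdict(InheritanceModel.COMPOUND_HET, consistent, phase, evidence)


def classify_inheritance(candidates, pedigree: Iterable[PedigreeSample]) -> list[dict]:
    """Run the segregation test matching each candidate gene's model.

    ``candidates`` is an iterable of :class:`excavar.prioritize.FamilyCandidate`.
    Genes failing segregation in a family are demoted (flagged), never
    deleted. Returns one row per (family, gene, model) with its verdict.
    """
    from .prioritize import GeneModel  # local import to avoid a cycle

    fams: dict[str, list[PedigreeSample]] = {}
    for s in pedigree:
        fams.setdefault(s.family_id, []).append(s)

    rows: list[dict] = []
    for cand in candidates:
        family = fams[cand.family_id]
        verdict: Optional[SegregationVerdict] = None
        if cand.model == GeneModel.HOMOZYGOUS:
            for v in cand.variants:
                try:
                    vd = check_homozygous(family, v, proband_id=cand.proband_id)
                except ValueError:
                    continue
                if verdict is None or (vd.consistent and not verdict.consistent):
                    verdict = vd
        elif cand.model == GeneModel.POTENTIAL_COMPOUND_HET:
            order = {Phase.CONFIRMED_TRANS: 2, Phase.INFERRED_TRANS: 1, Phase.UNPHASED: 0}
            for i, va in enumerate(cand.variants):
                for vb in cand.variants[i + 1 :]:
                    try:
                        vd = check_compound_het(family, va, vb, proband_id=cand.proband_id)
                    except ValueError:
                        continue
                    if verdict is None or (vd.consistent, order[vd.phase]) > (
                        verdict.consistent,
                        order[verdict.phase],
                    ):
                        verdict = vd
        else:  # hemizygous X candidates: no autosomal recessive test
            continue
        if verdict is not None:
            rows.append(
                {
                    "family": cand.family_id,
                    "gene": cand.gene,
                    "model": cand.model.value,
                    "consistent": verdict.consistent,
                    "phase": verdict.phase.value,
                    "verdict": verdict,
                    "demoted": not verdict.consistent,
                }
            )
    return rows
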