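"""The filtering cascade: frequency arithmetic, per-step behaviour, rescue."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excavar.core_io import (
    ConsequenceClass,
    FrequencyRecord,
    FrequencySource,
    Genotype,
    PedigreeSample,
    Sex,
)
from excavar.prioritize import (
    FilterTrace,
    GeneModel,
    allele_frequency,
    coverage_gap_report,
    filter_rare,
    homozygote_screen,
    intersect_step,
    known_gene_crossref,
    partition_zygosity,
    recessive_step,
    run_pipeline,
    xlinked_step,
)
from excavar.synthetic_cohort import mask_coverage

from conftest import make_freq, make_trio, make_variant

G = Genotype
SRC = FrequencySource


def test_allele_frequency_exact():
    assert allele_frequency(make_freq(ac=21, an=11520)) == Fraction(21, 11520)
    assert float(allele_frequency(make_freq(ac=21, an=11520))) == pytest.approx(0.0018229, abs=1e-6)
    assert allele_frequency(make_freq(ac=0, an=1980)) == 0
    assert float(allele_frequency(make_freq(ac=1, an=120688))) == pytest.approx(8.286e-6, rel=1e-3)


def test_allele_frequency_zero_denominator():
    with pytest.raises(ValueError):
        FrequencyRecord(SRC.EXAC, 0, 0, 0)


def test_filter_rare_rules():
    absent = make_variant(pos=1, genotypes={"p": G.HET})  # no records anywhere
    boundary = make_variant(pos=2, genotypes={"p": G.HET},
                            frequencies=[make_freq(ac=50, an=10_000)])  # exactly 0.005
    common_internal = make_variant(pos=3, genotypes={"p": G.HET},
                                   frequencies=[make_freq(SRC.INTERNAL, 20, 1980),
                                                make_freq(SRC.EXAC, 0, 120_000)])
    trace = FilterTrace()
    retained = filter_rare([absent, boundary, common_internal], trace=trace)
    assert retained == [absent, boundary]  # max-over-sources rule; inclusive threshold
    assert trace.counts() == [("step1_rare", 3, 2)]


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    threshold_lo=st.floats(0.0, 0.02),
    threshold_hi=st.floats(0.0, 0.02),
    seed=st.integers(0, 10_000),
)
def test_filter_rare_monotone_in_threshold(threshold_lo, threshold_hi, seed):
    """Raising the MAF threshold never shrinks the retained set."""
    lo, hi = sorted((threshold_lo, threshold_hi))
    rng = random.Random(seed)
    variants = [
        make_variant(pos=i, genotypes={"p": G.HET},
                     frequencies=[make_freq(ac=rng.randint(0, 100), an=5_000)])
        for i in range(30)
    ]
    kept_lo = {v.key for v in filter_rare(variants, lo)}
    kept_hi = {v.key for v in filter_rare(variants, hi)}
    assert kept_lo <= kept_hi


def test_filter_rare_agrees_with_bruteforce_1000_records():
    rng = random.Random(42)
    variants = []
    for i in range(1_000):
        freqs = [
            FrequencyRecord(src, rng.randint(0, 60), an, 0)
            for src, an in ((SRC.INTERNAL, 1980), (SRC.EVS, 12000),
                            (SRC.EXAC, 120000), (SRC.THOUSAND_GENOMES, 5008))
            if rng.random() < 0.8
        ]
        variants.append(make_variant(pos=i, genotypes={"p": G.HET}, frequencies=freqs))
    kept = {v.key for v in filter_rare(variants, 0.005)}
    brute = {
        v.key
        for v in variants
        if all(f.alt_allele_count / f.total_alleles <= 0.005 for f in v.frequencies)
    }
    assert kept == brute


def test_homozygote_screen_flags_not_filters():
    clean = make_variant(pos=1, frequencies=[make_freq(ac=10, an=10_000, hom=0)])
    flagged = make_variant(pos=2, frequencies=[make_freq(ac=10, an=10_000, hom=3)])
    variants = [clean, flagged]
    hits = homozygote_screen(variants)
    assert hits == [flagged]
    assert variants == [clean, flagged]  # annotation only: input untouched


def test_partition_zygosity():
    vs = [
        make_variant(pos=1, genotypes={"p": G.HOM_ALT}),
        make_variant(pos=2, genotypes={"p": G.HET}),
        make_variant(pos=3, genotypes={"p": G.HET}),
        make_variant(chrom="X", pos=4, genotypes={"p": G.HEMI}),
    ]
    parts = partition_zygosity(vs, "p")
    sizes = {g.value: len(v) for g, v in parts.items()}
    assert sizes == {"hom_alt": 1, "het": 2, "hemi": 1}
    assert sum(sizes.values()) == len(vs)
    with pytest.raises(ValueError, match="missing"):
        partition_zygosity(vs, "ghost")


def test_known_gene_crossref():
    planted = make_variant(gene="PAX6", pos=1, genotypes={"p": G.HET})
    other = make_variant(gene="G00001", pos=2, genotypes={"p": G.HET})
    hits = known_gene_crossref([planted, other], ["PAX6", "FOXC1"])
    assert hits == [planted]
    assert set(v.key for v in hits) <= {planted.key, other.key}


def test_xlinked_step():
    male = PedigreeSample("F", "boy", sex=Sex.MALE, affected=True)
    female = PedigreeSample("F", "girl", sex=Sex.FEMALE, affected=True)
    xvar = make_variant(chrom="X", gene="ARMCX4", pos=1, genotypes={"boy": G.HEMI})
    avar = make_variant(chrom="7", pos=2, genotypes={"boy": G.HET})
    hits = xlinked_step([xvar, avar], male)
    assert hits == [xvar] and all(v.is_x for v in hits)
    with pytest.warns(UserWarning):
        assert xlinked_step([xvar], female) == []


def test_recessive_step_matches_bruteforce():
    rng = random.Random(7)
    proband = PedigreeSample("F", "p", sex=Sex.FEMALE, affected=True)
    genes = [f"g{i}" for i in range(8)]
    variants = [
        make_variant(
            gene=rng.choice(genes), chrom=rng.choice(["1", "2", "X"]), pos=i,
            genotypes={"p": rng.choice([G.HOM_ALT, G.HET, G.HET, G.HEMI])},
        )
        for i in range(60)
    ]
    reports = recessive_step(variants, proband)
    got = {(c.gene, c.model) for c in reports}
    # brute-force re-scan over grouped autosomal variants
    expected = set()
    for gene in genes:
        gv = [v for v in variants if v.gene == gene and not v.is_x]
        if any(v.genotype("p") == G.HOM_ALT for v in gv):
            expected.add((gene, GeneModel.HOMOZYGOUS))
        if len({v.key for v in gv if v.genotype("p") == G.HET}) >= 2:
            expected.add((gene, GeneModel.POTENTIAL_COMPOUND_HET))
    assert got == expected


def test_single_het_gene_not_reported():
    proband = PedigreeSample("F", "p", affected=True)
    v = make_variant(gene="solo", genotypes={"p": G.HET})
    assert recessive_step([v], proband) == []


def test_intersect_step():
    def cand(gene, fam):
        return type("C", (), {"gene": gene})()

    per_family = {
        "F1": [cand("CPAMD8", "F1"), cand("AAA", "F1")],
        "F2": [cand("CPAMD8", "F2"), cand("AAA", "F2")],
        "F3": [cand("CPAMD8", "F3"), cand("BBB", "F3")],
    }
    assert intersect_step(per_family) == {"CPAMD8"}  # 2/3-family decoy excluded
    assert intersect_step({"F1": [], "F2": [cand("X", "F2")]}) == set()
    with pytest.warns(UserWarning):
        assert intersect_step({"F1": [cand("Z", "F1")]}) == {"Z"}


def test_trace_retained_subset_enforced():
    trace = FilterTrace()
    a = make_variant(pos=1, genotypes={"p": G.HET})
    b = make_variant(pos=2, genotypes={"p": G.HET})
    with pytest.raises(ValueError):
        trace.add("bogus", [a], [b])


# ---------------------------------------------------------------------------
# pipeline-level behaviour on the small synthetic cohort


def test_pipeline_recovers_planted_gene(small_cohort):
    res = run_pipeline(small_cohort.variants, small_cohort.pedigree,
                       ["PAX6", "FOXC1"], run_segregation=False)
    assert res.shared_genes == {"CPAMD8"}
    for fam, trace in res.traces.items():
        for step in trace.steps:
            assert step["n_retained"] <= step["n_input"]


def test_pipeline_known_gene_crossref_empty(small_cohort):
    res = run_pipeline(small_cohort.variants, small_cohort.pedigree,
                       ["PAX6", "FOXC1", "CYP1B1"], run_segregation=False)
    assert all(len(h) == 0 for h in res.known_gene_hits.values())


def test_pipeline_xlinked_single_candidate(small_cohort):
    res = run_pipeline(small_cohort.variants, small_cohort.pedigree, run_segregation=False)
    (xc,) = res.xlinked_candidates["F2"]
    assert (xc.gene, xc.cdna_change) == ("ARMCX4", "c.979A>G")


def test_coverage_gap_and_rescue_flow():
    from excavar.synthetic_cohort import BackgroundModel, generate_cohort

    cohort = generate_cohort(
        background=BackgroundModel(n_variants_per_proband=400, n_genes=2_000), seed=11
    )
    gaps_scenario = cohort.scenarios[2].coverage_gap_exons
    mask = mask_coverage(cohort, "CPAMD8", gaps_scenario, "F3-II2")
    # the hidden allele is gone from the proband's analysis
    res = run_pipeline(cohort.variants, cohort.pedigree, run_segregation=False)
    assert res.shared_genes == set()
    assert [(r["gene"], r["missing_family"]) for r in res.fallback] == [("CPAMD8", "F3")]
    (single,) = res.fallback[0]["singleton_hets"]
    assert single.cdna_change == "c.4002+1G>A"
    # the gap report equals the generator's mask and includes the hidden exon
    gaps = coverage_gap_report("CPAMD8", cohort.transcript, mask, "F3-II2")
    assert gaps == sorted(gaps_scenario) and 7 in gaps
    # merging the targeted-sequencing rescue restores full recovery
    res2 = run_pipeline(cohort.variants, cohort.pedigree,
                        rescue_variants=cohort.rescue_records, run_segregation=False)
    assert res2.shared_genes == {"CPAMD8"}


def test_coverage_gap_full_coverage_empty(small_cohort):
    mask = mask_coverage(small_cohort, "CPAMD8", (), "F1-II1")
    assert coverage_gap_report("CPAMD8", small_cohort.transcript, mask, "F1-II1") == []


def test_coverage_gap_requires_transcript(small_cohort):
    mask = mask_coverage(small_cohort, "CPAMD8", (), "F1-II1")
    with pytest.raises(ValueError):
        coverage_gap_report("CPAMD8", None, mask, "F1-II1")
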