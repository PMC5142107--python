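"""Shared fixtures: toy transcripts, trio builders and a small cohort."""

from __future__ import annotations

import random

import pytest

from excavar.core_io import (
    ConsequenceClass,
    FrequencyRecord,
    FrequencySource,
    Genotype,
    PedigreeSample,
    Sex,
    VariantRecord,
)
from excavar.cpamd8_fixture import cpamd8_transcript
from excavar.splicing import TranscriptModel
from excavar.synthetic_cohort import BackgroundModel, generate_cohort

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@pytest.fixture(scope="session")
def cpamd8():
    return cpamd8_transcript()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-background cohort for I/O and pipeline unit tests."""
    background = BackgroundModel(n_variants_per_proband=400, n_genes=2_000)
    return generate_cohort(background=background, seed=11)


def random_toy_transcript(rng: random.Random, n_exons=None, n_codons=None) -> TranscriptModel:
    """A random multi-exon toy transcript with stop-free codons and introns."""
    n_exons = n_exons or rng.randint(3, 7)
    n_codons = n_codons or rng.randint(25, 70)
    length = 3 * n_codons
    cuts = sorted(rng.sample(range(2, length - 1), n_exons - 1))
    bounds = [0] + cuts + [length]
    cds = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons - 1)) + "TAA"
    exons = [(k, bounds[k - 1] + 1, bounds[k]) for k in range(1, n_exons + 1)]
    introns = {
        i: "GT" + "".join(rng.choice("ACGT") for _ in range(rng.randint(18, 70))) + "AG"
        for i in range(1, n_exons)
    }
    return TranscriptModel(gene="TOY", exons=exons, coding_sequence=cds, introns=introns)


def make_variant(gene="GENE1", chrom="1", pos=1000, ref="A", alt="G", genotypes=None, **kw):
    return VariantRecord(
        chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt, gene=gene,
        genotypes=dict(genotypes or {}), **kw,
    )


def make_freq(source=FrequencySource.EXAC, ac=0, an=10_000, hom=0):
    return FrequencyRecord(source, ac, an, hom)


def make_trio(family="FAM", child_sex=Sex.FEMALE):
    """Father, mother, affected child."""
    return [
        PedigreeSample(family, "dad", sex=Sex.MALE),
        PedigreeSample(family, "mum", sex=Sex.FEMALE),
        PedigreeSample(family, "kid", "dad", "mum", child_sex, affected=True),
    ]
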