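# excavar

Rare-disease exome variant prioritization, pedigree segregation, and
splice-consequence arithmetic — the analysis path by which recessive
disease genes such as *CPAMD8* (anterior segment dysgenesis) are found
from a handful of family exomes, packaged as a tested, reusable library
with a CLI and a synthetic-cohort generator so the whole path runs with no
sequencing data.

## What it does

**Filtering cascade** (`excavar.prioritize`). From per-proband exonic
variant tables (~25,000 variants each): (1) retain variants with minor
allele frequency MAF ≤ 0.005 — exact rational arithmetic, maximum over all
annotated population databases (1000 Genomes, EVS, ExAC, an internal
panel) — and cross-reference against known disease genes; (2) list rare
hemizygous X variants for male probands; (3) per family, keep genes with a
homozygous rare variant or ≥ 2 distinct rare heterozygotes (potential
compound heterozygotes); (4) intersect candidate genes across families.
When the intersection fails, a singleton-heterozygote fallback re-ranks
genes qualifying in all-but-one family whose remaining family carries one
rare heterozygote — the signature of a second allele hidden in an exome
coverage gap, which `coverage_gap_report` pinpoints for Sanger follow-up
and a rescue merge restores.

**Segregation** (`excavar.segregate`). Homozygous and compound-het
verdicts under complete-penetrance recessive inheritance, with phase
bookkeeping: `confirmed_trans` needs both parents genotyped carrying one
allele each; `inferred_trans` needs one genotyped parent carrying exactly
one (the other allele imputed to the missing parent); missing genotypes
never falsify a verdict, they only cap phase certainty.

**Splice consequences** (`excavar.splicing`). HGVS c. parsing
(`c.700+1G>T` → donor of intron 7), aberrant-event simulation (exon
skipping, intron retention, cryptic GT/AG site usage) on cDNA-space
transcript models, translation, and HGVS p. emission with 3′-normalized
boundaries: in-frame `p.Ile1517_Gln1537del`, frameshift
`p.Arg785Glnfs*23` where the new stop counts the first altered residue
as 1. Codon arithmetic: codon *i* spans c.(3*i*−2)…c.(3*i*), so c.4351
falls in codon ⌈4351/3⌉ = 1451.

**Conservation support** (`excavar.conserve`). Needleman–Wunsch global
protein alignment with full-length percent identity, MSA column
invariance, and a synteny presence/absence check.

**Synthetic cohorts** (`excavar.synthetic_cohort`). Three-family cohorts
with planted causal configurations (homozygous consanguineous; compound
het trio; compound het with an ungenotyped father), decoy genes, database
counts drawn binomially at realistic depths, and optional coverage gaps —
written as plain VCF/PED/TSV/BED.

## Worked example

```sh
$ excavar splice-consequence --variant "c.4549-1G>A" --enumerate
c.4549-1G>A: acceptor of intron 33
  skip exon 34: inframe_deletion p.Ile1517_Gln1537del
  retain intron 33: inframe_insertion p.Ala1516_Ile1517ins26
  skip exons 33-34: inframe_deletion p.Asp1465_Gln1537del
```

Losing the acceptor of intron 33 yields three candidate aberrant
transcripts on the packaged CPAMD8-like fixture: skipping exon 34 (63 nt)
deletes 21 residues in frame; retaining the 78-nt intron inserts 26
residues between Ala1516 and Ile1517; skipping exons 33–34 (219 nt)
deletes 73 residues.

```sh
$ excavar simulate --out demo --seed 3 --n-variants 2000
$ excavar prioritize --vcf demo/cohort.vcf --ped demo/cohort.ped \
      --annotations demo/annotations.tsv --trace demo/trace.json
F1  step1_rare       2005 -> 17
F1  step3_recessive    17 -> 3
F1  step4_shared        3 -> 1
...
shared genes: ['CPAMD8']
$ excavar segregate --vcf demo/cohort.vcf --ped demo/cohort.ped \
      --annotations demo/annotations.tsv --gene CPAMD8
F1  CPAMD8  homozygous             consistent  unphased
F2  CPAMD8  potential_compound_het consistent  confirmed_trans
F3  CPAMD8  potential_compound_het consistent  inferred_trans
```

The cascade reduces each proband's table to a dozen-odd rare variants and
intersects to the single planted gene; segregation then confirms the
homozygous model in the consanguineous family and compound heterozygosity
in the other two — inferred, not confirmed, in family 3, where the father
is ungenotyped.

## Layout

- `src/excavar/core_io.py` — domain types; VCF/PED/TSV/BED readers-writers
- `src/excavar/prioritize.py` — the filtering cascade and coverage-gap rescue
- `src/excavar/segregate.py` — recessive segregation verdicts and phase
- `src/excavar/splicing.py` — transcript models, HGVS, consequence engine
- `src/excavar/conserve.py` — alignment identity, MSA columns, synteny
- `src/excavar/synthetic_cohort.py` — cohort generator and coverage masking
- `src/excavar/cpamd8_fixture.py` — the frozen CPAMD8-like transcript fixture
- `docs/methods.md` — model assumptions, parameters, numerical choices
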