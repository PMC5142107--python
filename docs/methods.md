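# Methods

## The filtering model

The cascade assumes a fully penetrant autosomal-recessive condition shared
by unrelated families, so a causal allele must be individually rare and
the causal gene must carry a qualifying recessive genotype in every
proband. Rarity is judged per database at MAF ≤ 0.005 and aggregated as a
**maximum over sources**: a variant common in any one database is
discarded. The databases report allele counts, not frequencies, so the
comparison uses exact rational arithmetic (`Fraction(ac, an) ≤ 1/200`);
a variant at exactly the threshold is retained, and a database with no
record contributes frequency zero (databases print explicit `0/N` counts
for unseen alleles). Population homozygote counts are a *flag*, not a
filter — a recessive candidate homozygous in controls is suspect but is
annotated rather than removed. In-silico scores (SIFT < 0.05 damaging,
PolyPhen-2 ≥ 0.85, PhyloP > 0.95 conserved) likewise only rank candidate
genes (`plausibility_score`); they never remove a variant, mirroring how
such predictions are used as supporting evidence.

The compound-het model at step 3 is deliberately permissive ("potential"):
two distinct rare heterozygotes in one gene, phase unknown. Phase is the
segregation module's job. The X-linked screen runs for male probands only
and is reported for manual review, not intersected.

**Coverage-gap rescue.** When the cross-family intersection is empty, genes
qualifying in all-but-one family are re-ranked, requiring the remaining
family to carry at least one rare singleton heterozygote in the gene. This
formalizes the manual re-analysis that recovers a second allele missed by
exome capture: `coverage_gap_report` lists coding exons with zero overlap
against a sample's covered intervals, and targeted-sequencing results are
merged back as `rescue_variants` before the recessive step is re-run.

## Segregation and phase

An individual is affected iff both gene copies carry a pathogenic allele
(complete penetrance, no phenocopies). Verdict rules for a candidate pair
(A, B): genotyped affected members must carry both; a genotyped unaffected
member may carry either allele alone (carrier parents, carrier
grandchildren) but not both (an unaffected double carrier implies cis,
which the proband would then inherit in cis) and may not be homozygous for
either. Phase: `confirmed_trans` iff both parents are genotyped and each
carries exactly one, different, allele; `inferred_trans` iff exactly one
parent is genotyped and carries exactly one allele — the other allele is
imputed to the missing parent and no more is claimed; otherwise
`unphased`. A genotyped parent carrying *neither* allele forces both onto
the other parent, i.e. cis, and is inconsistent. For fully genotyped
trios these rules coincide with brute-force enumeration of parental
haplotype phases and transmissions (verified exhaustively in the tests
over all 3² × 3² parental genotype configurations).

## Transcript arithmetic

All splice work happens in cDNA coordinates (c.1 = first base of the start
codon); genomic↔cDNA projection and strand handling are out of scope.
`c.N+k` denotes the k-th base of the intron after the exon ending at c.N
(donor side), `c.N−k` the k-th base before the exon starting at c.N
(acceptor side). Events are sequence rewrites: exon skipping removes the
exon's bases, retention inserts the intron between its flanking exons, a
cryptic donor at +k retains the intron's first k bases, a cryptic acceptor
at −k its last k. When the canonical site carries the mutation (e.g. a
+1 G>T), retention/cryptic products carry the mutated intronic base, so
the engine substitutes it into the intron before simulation
(`apply_intronic_variant`).

The consequence engine translates reference and mutant with the standard
nuclear code (translation stops at the first stop codon; selenocysteine
and non-ATG starts unsupported) and diffs the proteins. An event is
**in-frame** iff its length change is ≡ 0 (mod 3) *and* the mutant stop
falls exactly where a clean codon-count change predicts (no premature
stop). In-frame boundaries are 3′-normalized per HGVS (deletion windows
shifted right across repeats; insertions rotated right across duplicated
residues); insertions of > 5 residues are named by count
(`ins26`). Frameshifts are `p.(ref)(pos)(new)fs*N` with the first altered
residue counted as 1; a mutant that never reaches a stop is emitted as
`fs*?` and flagged. Candidate-event enumeration for a lost site always
proposes the adjacent-exon skip, the adjacent-intron retention and the
two-exon skip, then every GT (donor) or AG (acceptor) dinucleotide within
a 500-nt window when intronic sequence is available — bare dinucleotide
matching, no splice-strength scoring, since observed aberrant products
are identified empirically.

## The packaged transcript fixture

The real CPAMD8 coding sequence is not bundled; `cpamd8_fixture` builds a
synthetic 35-exon, 4,710-nt CDS whose exon boundaries and local codons are
pinned exactly where published variant nomenclature pins them (exon 6 =
c.628–645, exon 7 = c.646–700, exon 29 = c.3928–4002, exon 33 =
c.4393–4548, exon 34 = c.4549–4611; Ser1451 at c.4351; Arg785 at c.2353
with the shifted frame terminating 23 codons in). Intron fixtures encode
the constraints the observed products force: intron 33 is 78 nt and
stop-free in frame (26 inserted residues); intron 7 carries its only
internal GT at +143/144 (cryptic donor retaining 142 nt) and an in-frame
TAA at +87–89 of the mutant reading. Every other codon is a seeded random
sense codon, fixed forever. Consequently the fixture reproduces the
published worked consequences exactly, while its background sequence is
synthetic — identity percentages or alignments computed against it mean
nothing biologically.

## The synthetic cohort generator

The generator emulates the *shape* of a three-family exome study, not real
genomes: no linkage disequilibrium, no sequencing error, no read-level
simulation, and relatives' background genotypes are drawn independently
at Hardy–Weinberg rather than by gamete transmission (planted causal and
decoy genotypes are exact, so everything the pipeline intersects or
segregates is faithful; only background genotypes are simplified).
Parameters and defaults:

- `n_variants_per_proband` = 25,000 — the magnitude of exonic variant
  calls per exome.
- `fraction_rare` = 0.005 with rare allele frequencies ~ Exponential(mean
  0.001), clipped to [1e-5, 0.05]; common frequencies ~ Uniform(0.01,
  0.5). This yields ~110–140 rare survivors per proband after the MAF
  filter, the magnitude seen in practice (a hundred-odd rare
  heterozygotes per exome).
- Database counts are Binomial at fixed depths — 1,980 / 12,000 / 120,000
  / 5,008 total alleles for the internal panel, EVS, ExAC and 1000
  Genomes — so sampling noise around the rarity threshold is realistic.
- Planted causal variants carry published-style counts (e.g. 21/11,520
  and 47/115,670 for the frameshift; zeros elsewhere) with zero
  homozygotes.
- Decoys: common variants inside the causal gene (removed at step 1); a
  rare het pair in a gene shared by exactly two of three families
  (removed at step 4); a benign-scored rare het pair private to family 3
  (the gene a stringent intersection would wrongly nominate); one rare
  hemizygous X missense in the family-2 male proband (the X-screen's
  expected single finding). Background rare variants avoid known disease
  genes and the X chromosome so the known-gene cross-reference and the
  X screen reproduce the study design's observed yields (empty, and one).
- Coverage masking pads exon intervals by 8 bp so donor/acceptor ±1–2
  variants belong to their exon's capture interval; masked variants are
  set to missing in the masked sample only and stashed as rescue records.

All randomness flows from one explicit integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical VCFs.

## Alignment

Global alignment uses linear gap penalties (default match 1, mismatch −1,
gap −2; configurable) with a deterministic tie-break (the aligner's first
enumeration, which prefers the diagonal). Percent identity divides matches
by **all** alignment columns, gap columns included — full-length identity;
tools normalizing by aligned columns or the shorter sequence report higher
values. Published cross-species identity ranges are treated as
qualitative: the sequence versions and alignment parameters behind them
are not reproducible, so tests assert the arithmetic (DP optimum vs
exhaustive enumeration on small pairs), not any particular percentage.

## Problem sizes and tolerances

Worked splice-consequence examples are exact string/integer equalities.
Property suites: consequence engine vs an independent naive
translate-and-diff oracle on 500 random transcript/event pairs; alignment
DP vs exhaustive path enumeration on sequences of length ≤ 6; segregation
vs brute-force Mendelian enumeration over all fully genotyped trio
configurations; planted-gene recovery on 20 seeded full-size cohorts
(25,000 background variants per proband), plus the masked/fallback/rescue
path on 3 seeds. The acceptance script uses a reduced sanity cohort
(5,000 variants per proband) for its end-to-end check; recovery behaviour
is size-independent well above the point where background genes start
pairing rare heterozygotes by chance.

## Known limitations

- PED parsing supports the 6-column dialect only; half-sib/complex
  pedigrees are representable but consanguinity loops are not modelled
  beyond cycle rejection.
- The VCF writer emits a minimal GT-only dialect; phased input is read as
  unphased; structural/symbolic alleles are skipped.
- `fs*N` for a first-altered-residue stop is emitted as `p.XposTer`
  (nonsense form) with `stop_offset` 1.
- De novo dominant models are outside the cascade; penetrance is complete;
  no linkage or identity-by-descent support.
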