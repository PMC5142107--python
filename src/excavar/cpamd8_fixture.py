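"""A synthetic CPAMD8-like transcript fixture reconstructed from HGVS anchors.

The real CPAMD8 coding sequence is not bundled. Instead, this module builds
a synthetic 35-exon, 4,710-nt CDS whose exon boundaries and local codons
are pinned exactly where the published variant nomenclature pins them, so
every worked splice-consequence example is reproducible without any
download:

* exon 6 = c.628-645 and exon 7 = c.646-700 (both exon-7 and exons-6+7
  skipping must read exon 8 in the same shifted frame, giving
  p.Asp216Alafs*5 and p.Leu210Alafs*5);
* exon 29 = c.3928-4002 (skip deletes Gly1310..Glu1334, 25 residues);
* exon 33 = c.4393-4548, exon 34 = c.4549-4611 (skip of 34 deletes
  Ile1517..Gln1537, 21 residues; skip of 33+34 deletes Asp1465..Gln1537,
  73 residues);
* Ser1451 encoded TCC at c.4351-4353 (c.4351T>C -> Pro);
* Arg785 encoded AGA at c.2353-2355 with a downstream frame engineered so
  c.2352_2353insC terminates 23 codons into the new frame (p.Arg785Glnfs*23);
* intron 7 (180 nt) whose only internal GT lies at +143/+144, so the
  cryptic donor retains 142 bases, with an in-frame TAA at +87..89 of the
  mutant reading (p.Gly234Valfs*30);
* intron 33 (78 nt, GT...AG) that is stop-free in frame, so retention
  inserts 26 residues between Ala1516 and Ile1517.

All remaining codons are filled with seeded random sense codons; the
fixture is deterministic and identical on every build.
"""

from __future__ import annotations

import random

from .splicing import TranscriptModel

GENE = "CPAMD8"

#: 1-based cDNA end coordinate of each exon, in exon order.
_EXON8_28_SIZES = [154] * 14 + [153] * 7  # distributes c.701..c.3927
EXON_ENDS = (
    [120, 240, 390, 510, 627, 645, 700]
    + [700 + sum(_EXON8_28_SIZES[: k + 1]) for k in range(21)]
    + [4002, 4130, 4260, 4392, 4548, 4611, 4710]
)

N_CODONS = EXON_ENDS[-1] // 3  # 1570

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: Codon patches (1-based residue index -> codon) realising the anchors above.
CODON_PATCHES = {
    210: "CTG",  # Leu210, first codon of exon 6
    216: "GAT",  # Asp216, first codon of exon 7
    234: "GGC",  # Gly234 spans the exon7/8 junction (c.700|c.701-702)
    # c.703..715 pinned so the shifted exon-8 frame reads Ala,Ala,Ala,Ala,stop
    235: "CGC",
    236: "TGC",
    237: "AGC",
    238: "ATA",
    239: "AAA",
    785: "AGA",  # Arg785 at c.2353-2355
    **{k: "GCT" for k in range(786, 807)},  # keeps the +1 frame stop-free...
    807: "AAA",  # ...until TAA at c.2418-2420 in the shifted frame
    1310: "GGT",  # Gly1310, first codon of exon 29
    1334: "GAA",  # Glu1334, last codon of exon 29
    1335: "CCT",  # breaks 3' repeat so the exon-29 deletion does not shift
    1451: "TCC",  # Ser1451 (c.4351 = T)
    1465: "GAT",  # Asp1465, first codon of exon 33
    1516: "GCC",  # Ala1516, last codon of exon 33
    1517: "ATT",  # Ile1517, first codon of exon 34
    1537: "CAG",  # Gln1537, last codon of exon 34
    1538: "TGG",  # Trp: distinct from Ile/Asp, no 3' shift of the deletions
    N_CODONS: "TAA",
}

#: Intron 7 fixture: canonical GT..AG; cryptic GT at +143/+144; TAA at
#: +87..89 of the frame read after the mutant donor retains 142 bases.
INTRON_7 = "GT" + "C" * 84 + "TAA" + "C" * 53 + "GT" + "C" * 34 + "AG"
#: Intron 29 fixture: unconstrained beyond canonical ends.
INTRON_29 = "GT" + "C" * 86 + "AG"
#: Intron 33 fixture: 78 nt, stop-free in frame (Val + 24xPro + Gln).
INTRON_33 = "GT" + "C" * 74 + "AG"

_SEED = 20170401


def build_coding_sequence() -> str:
    rng = random.Random(_SEED)
    codons = [rng.choice(_SENSE_CODONS) for _ in range(N_CODONS)]
    for idx, codon in CODON_PATCHES.items():
        codons[idx - 1] = codon
    return "".join(codons)


def cpamd8_transcript() -> TranscriptModel:
    """The packaged CPAMD8-like transcript model (synthetic; see module doc)."""
    exons = []
    start = 1
    for k, end in enumerate(EXON_ENDS, start=1):
        exons.append((k, start, end))
        start = end + 1
    return TranscriptModel(
        gene=GENE,
        exons=exons,
        coding_sequence=build_coding_sequence(),
        introns={7: INTRON_7, 29: INTRON_29, 33: INTRON_33},
    )


assert len(INTRON_7) == 180 and len(INTRON_33) == 78 and len(INTRON_29) == 90
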