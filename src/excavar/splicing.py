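"""Transcript-coordinate arithmetic and splice-event consequence prediction.

Everything here works in cDNA (c.) space: c.1 is the A of the start codon,
exons are contiguous 1-based intervals over the coding sequence, and
intronic positions are written relative to exon boundaries (``c.N+k`` lies k
bases into the intron following the exon that ends at c.N; ``c.N-k`` lies k
bases before the exon that starts at c.N). Genomic-to-cDNA projection is
deliberately out of scope, which also sidesteps minus-strand bookkeeping.

The consequence engine simulates an aberrant splicing event (exon skipping,
intron retention, cryptic donor/acceptor usage) or a small exonic edit on
the coding sequence, translates reference and mutant with the standard
nuclear code, and emits the protein-level HGVS consequence: in-frame
deletions/insertions with 3'-normalized boundaries, or a frameshift
``p.Xaa###Yaafs*N`` where the first altered residue counts as 1.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "TranscriptModel",
    "Exon",
    "SpliceEventKind",
    "SpliceEventSpec",
    "ConsequenceCategory",
    "ProteinConsequence",
    "SpliceSite",
    "codon_of",
    "parse_cdna_change",
    "site_of_variant",
    "apply_event",
    "apply_small_variant",
    "apply_intronic_variant",
    "consequence",
    "enumerate_candidate_events",
]

_STOPS = {"TAA", "TAG", "TGA"}


def codon_of(c_position: int) -> int:
    """Residue index of an exonic cDNA position: codon i spans c.(3i-2)..c.(3i)."""
    if c_position < 1:
        raise ValueError(f"cDNA position must be >= 1, got {c_position}")
    return (c_position + 2) // 3


@dataclass(frozen=True, slots=True)
class Exon:
    index: int  # 1-based exon number
    c_start: int  # 1-based inclusive, cDNA coordinates
    c_end: int

    @property
    def length(self) -> int:
        return self.c_end - self.c_start + 1


@dataclass(slots=True)
class TranscriptModel:
    """Ordered coding exons plus (optionally) the CDS and intron sequences.

    ``coding_sequence`` must cover exactly the exon span, be a multiple of 3
    and end in a stop codon; ``introns`` maps intron index i (between exon i
    and exon i+1) to its nucleotide sequence, and is required only for
    retention and cryptic-site simulation.
    """

    gene: str
    exons: list[Exon]
    coding_sequence: Optional[str] = None
    introns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = [e if isinstance(e, Exon) else Exon(*e) for e in self.exons]
        prev_end = 0
        for k, exon in enumerate(self.exons, start=1):
            if exon.index != k:
                raise ValueError(f"exon indices must be 1..n in order, got {exon.index} at {k}")
            if exon.c_start != prev_end + 1 or exon.c_end < exon.c_start:
                raise ValueError(f"exon {k} interval not contiguous/ascending")
            prev_end = exon.c_end
        if self.coding_sequence is not None:
            self.coding_sequence = self.coding_sequence.upper()
            n = len(self.coding_sequence)
            if n != prev_end:
                raise ValueError("coding_sequence length does not match exon span")
            if n % 3 != 0:
                raise ValueError("coding_sequence length must be a multiple of 3")
            if self.coding_sequence[-3:] not in _STOPS:
                raise ValueError("coding_sequence must end in a stop codon")
        self.introns = {int(k): str(v).upper() for k, v in self.introns.items()}

    @property
    def cds_length(self) -> int:
        return self.exons[-1].c_end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> Exon:
        if not 1 <= index <= self.n_exons:
            raise ValueError(f"exon index {index} out of range 1..{self.n_exons}")
        return self.exons[index - 1]

    def exon_ending_at(self, c_end: int) -> Exon:
        for e in self.exons:
            if e.c_end == c_end:
                return e
        raise ValueError(f"no exon ends at c.{c_end}")

    def exon_starting_at(self, c_start: int) -> Exon:
        for e in self.exons:
            if e.c_start == c_start:
                return e
        raise ValueError(f"no exon starts at c.{c_start}")

    def exon_sequence(self, index: int) -> str:
        if self.coding_sequence is None:
            raise ValueError("transcript has no coding sequence")
        e = self.exon(index)
        return self.coding_sequence[e.c_start - 1 : e.c_end]

    def protein(self) -> str:
        """Reference protein up to (excluding) the terminal stop."""
        return translate_to_stop(self.coding_sequence)


def translate_to_stop(cdna: str) -> str:
    """Translate with the standard code, truncating at the first stop codon."""
    prot = str(Seq(cdna[: len(cdna) - len(cdna) % 3]).translate())
    stop = prot.find("*")
    return prot if stop == -1 else prot[:stop]


# ---------------------------------------------------------------------------
# HGVS c. parsing

_RE_SUB = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_RE_INTRONIC = re.compile(r"^c\.(\d+)([+-])(\d+)([ACGT])>([ACGT])$")
_RE_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_RE_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")


@dataclass(frozen=True, slots=True)
class CdnaVariant:
    """Parsed HGVS c. description (substitution, insertion or deletion)."""

    kind: str  # "sub" | "intronic_sub" | "ins" | "del"
    start: int
    end: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    offset: int = 0  # signed intronic offset for intronic substitutions


def parse_cdna_change(cdna_change: str) -> CdnaVariant:
    s = cdna_change.replace("–", "-").replace(" ", "")
    if m := _RE_INTRONIC.match(s):
        pos, sign, off, ref, alt = m.groups()
        return CdnaVariant(
            kind="intronic_sub",
            start=int(pos),
            ref=ref,
            alt=alt,
            offset=int(off) if sign == "+" else -int(off),
        )
    if m := _RE_SUB.match(s):
        pos, ref, alt = m.groups()
        return CdnaVariant(kind="sub", start=int(pos), end=int(pos), ref=ref, alt=alt)
    if m := _RE_INS.match(s):
        a, b, ins = m.groups()
        if int(b) != int(a) + 1:
            raise ValueError(f"insertion positions must be adjacent in {cdna_change!r}")
        return CdnaVariant(kind="ins", start=int(a), end=int(b), alt=ins)
    if m := _RE_DEL.match(s):
        a, b, ref = m.groups()
        return CdnaVariant(kind="del", start=int(a), end=int(b) if b else int(a), ref=ref or None)
    raise ValueError(f"cannot parse HGVS cDNA description {cdna_change!r}")


class SpliceSiteKind(str, enum.Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"


@dataclass(frozen=True, slots=True)
class SpliceSite:
    kind: SpliceSiteKind
    intron_index: int  # intron i lies between exon i and exon i+1


def site_of_variant(cdna_change: str, transcript: TranscriptModel) -> SpliceSite:
    """Resolve which splice site an intronic HGVS c. variant disrupts.

    ``c.N+k`` hits the donor of the intron following the exon ending at c.N;
    ``c.N-k`` hits the acceptor of the intron preceding the exon starting at
    c.N.
    """
    var = parse_cdna_change(cdna_change)
    if var.kind != "intronic_sub":
        raise ValueError(f"{cdna_change!r} is not an intronic (c.N+k / c.N-k) variant")
    if var.offset > 0:
        exon = transcript.exon_ending_at(var.start)
        return SpliceSite(SpliceSiteKind.DONOR, exon.index)
    exon = transcript.exon_starting_at(var.start)
    return SpliceSite(SpliceSiteKind.ACCEPTOR, exon.index - 1)


# ---------------------------------------------------------------------------
# splice events


class SpliceEventKind(str, enum.Enum):
    EXON_SKIP = "exon_skip"
    MULTI_EXON_SKIP = "multi_exon_skip"
    INTRON_RETENTION = "intron_retention"
    CRYPTIC_DONOR = "cryptic_donor"
    CRYPTIC_ACCEPTOR = "cryptic_acceptor"


@dataclass(frozen=True, slots=True)
class SpliceEventSpec:
    """One aberrant splicing event in cDNA space.

    ``offset`` is the signed cryptic-site offset: ``+k`` retains the first k
    bases of the intron (cryptic donor), ``-k`` retains the last k bases
    (cryptic acceptor).
    """

    kind: SpliceEventKind
    exon_indices: tuple = ()
    intron_index: Optional[int] = None
    offset: int = 0

    def __post_init__(self) -> None:
        if self.kind in (SpliceEventKind.EXON_SKIP, SpliceEventKind.MULTI_EXON_SKIP):
            if not self.exon_indices:
                raise ValueError("exon skip requires exon indices")
            idx = sorted(self.exon_indices)
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise ValueError("skipped exons must be contiguous")
            object.__setattr__(self, "exon_indices", tuple(idx))
        else:
            if self.intron_index is None:
                raise ValueError(f"{self.kind.value} requires an intron index")
        if self.kind == SpliceEventKind.CRYPTIC_DONOR and self.offset <= 0:
            raise ValueError("cryptic donor offset must be positive")
        if self.kind == SpliceEventKind.CRYPTIC_ACCEPTOR and self.offset >= 0:
            raise ValueError("cryptic acceptor offset must be negative")

    def describe(self) -> str:
        if self.kind == SpliceEventKind.EXON_SKIP:
            return f"skip exon {self.exon_indices[0]}"
        if self.kind == SpliceEventKind.MULTI_EXON_SKIP:
            return f"skip exons {self.exon_indices[0]}-{self.exon_indices[-1]}"
        if self.kind == SpliceEventKind.INTRON_RETENTION:
            return f"retain intron {self.intron_index}"
        sign = "+" if self.offset > 0 else ""
        return f"cryptic {self.kind.value.split('_')[1]} {sign}{self.offset} in intron {self.intron_index}"


def apply_event(transcript: TranscriptModel, event: SpliceEventSpec) -> str:
    """Return the mutant cDNA produced by one aberrant splicing event."""
    if transcript.coding_sequence is None:
        raise ValueError("transcript has no coding sequence")
    cds = transcript.coding_sequence
    if event.kind in (SpliceEventKind.EXON_SKIP, SpliceEventKind.MULTI_EXON_SKIP):
        first = transcript.exon(event.exon_indices[0])
        last = transcript.exon(event.exon_indices[-1])
        return cds[: first.c_start - 1] + cds[last.c_end :]
    intron = transcript.introns.get(event.intron_index)
    if intron is None:
        raise ValueError(f"no sequence for intron {event.intron_index}")
    if event.intron_index >= transcript.n_exons:
        raise ValueError(f"intron index {event.intron_index} out of range")
    junction = transcript.exon(event.intron_index).c_end  # last base of upstream exon
    if event.kind == SpliceEventKind.INTRON_RETENTION:
        inserted = intron
    elif event.kind == SpliceEventKind.CRYPTIC_DONOR:
        if event.offset > len(intron):
            raise ValueError("cryptic donor offset exceeds intron length")
        inserted = intron[: event.offset]
    else:  # cryptic acceptor: retain the intron's last |offset| bases
        k = -event.offset
        if k > len(intron):
            raise ValueError("cryptic acceptor offset exceeds intron length")
        inserted = intron[len(intron) - k :]
    return cds[:junction] + inserted + cds[junction:]


def apply_small_variant(transcript: TranscriptModel, cdna_change: str) -> str:
    """Apply an exonic HGVS substitution/insertion/deletion to the CDS."""
    if transcript.coding_sequence is None:
        raise ValueError("transcript has no coding sequence")
    cds = transcript.coding_sequence
    var = parse_cdna_change(cdna_change)
    if var.kind == "intronic_sub":
        raise ValueError(f"{cdna_change!r} is intronic; use splice-event simulation")
    if var.kind == "sub":
        if cds[var.start - 1] != var.ref:
            raise ValueError(
                f"reference mismatch at c.{var.start}: CDS has {cds[var.start - 1]}, HGVS says {var.ref}"
            )
        return cds[: var.start - 1] + var.alt + cds[var.start :]
    if var.kind == "ins":
        return cds[: var.start] + var.alt + cds[var.start :]
    # deletion
    if var.ref and cds[var.start - 1 : var.end] != var.ref:
        raise ValueError(f"reference mismatch for {cdna_change!r}")
    return cds[: var.start - 1] + cds[var.end :]


def apply_intronic_variant(transcript: TranscriptModel, cdna_change: str) -> TranscriptModel:
    """Return a copy of the transcript with an intronic base substituted.

    Needed before simulating retention/cryptic events on a splice-site
    mutant, whose aberrant transcripts carry the mutated intronic base.
    """
    var = parse_cdna_change(cdna_change)
    if var.kind != "intronic_sub":
        raise ValueError(f"{cdna_change!r} is not intronic")
    site = site_of_variant(cdna_change, transcript)
    intron = transcript.introns.get(site.intron_index)
    if intron is None:
        raise ValueError(f"no sequence for intron {site.intron_index}")
    idx = var.offset - 1 if var.offset > 0 else len(intron) + var.offset
    if not 0 <= idx < len(intron):
        raise ValueError("intronic offset outside the provided intron sequence")
    if intron[idx] != var.ref:
        raise ValueError(f"reference mismatch in intron {site.intron_index} for {cdna_change!r}")
    introns = dict(transcript.introns)
    introns[site.intron_index] = intron[:idx] + var.alt + intron[idx + 1 :]
    return TranscriptModel(
        gene=transcript.gene,
        exons=list(transcript.exons),
        coding_sequence=transcript.coding_sequence,
        introns=introns,
    )


# ---------------------------------------------------------------------------
# protein consequence


class ConsequenceCategory(str, enum.Enum):
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELINS = "inframe_delins"
    FRAMESHIFT = "frameshift"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NO_CHANGE = "no_change"


@dataclass(frozen=True, slots=True)
class ProteinConsequence:
    category: ConsequenceCategory
    hgvs_p: str
    first_residue: int = 0
    n_residues_changed: int = 0  # deleted+inserted count for in-frame; 0 for frameshift
    stop_offset: int = 0  # the N of fs*N; 0 otherwise
    flagged_no_stop: bool = False


def _aa3(residue: str) -> str:
    return "Ter" if residue == "*" else seq3(residue)


def consequence(ref_transcript, mutant_cdna: str) -> ProteinConsequence:
    """Translate reference and mutant cDNA and emit the HGVS p. consequence.

    An event whose length change is a multiple of 3 and which introduces no
    premature stop is reported as an in-frame deletion/insertion/delins with
    3'-most (HGVS-normalized) boundaries; anything else is a frameshift
    ``p.Xaa(pos)Yaafs*N`` where N counts the new stop with the first altered
    residue as position 1. A mutant that never reaches a stop codon is
    reported as ``fs*?`` and flagged.
    """
    ref_cdna = (
        ref_transcript.coding_sequence
        if isinstance(ref_transcript, TranscriptModel)
        else str(ref_transcript).upper()
    )
    mutant_cdna = mutant_cdna.upper()
    ref_p = translate_to_stop(ref_cdna)
    mut_p = translate_to_stop(mutant_cdna)
    mut_has_stop = "*" in str(Seq(mutant_cdna[: len(mutant_cdna) - len(mutant_cdna) % 3]).translate())

    if mut_p == ref_p and mut_has_stop:
        if mutant_cdna == ref_cdna:
            return ProteinConsequence(ConsequenceCategory.NO_CHANGE, "p.=")
        return ProteinConsequence(ConsequenceCategory.SYNONYMOUS, "p.=")

    length_change = len(mutant_cdna) - len(ref_cdna)
    inframe = (
        length_change % 3 == 0
        and mut_has_stop
        and len(mut_p) == len(ref_p) + length_change // 3
    )
    # common prefix of the two proteins
    prefix = 0
    while prefix < min(len(ref_p), len(mut_p)) and ref_p[prefix] == mut_p[prefix]:
        prefix += 1

    if not inframe:
        first = prefix + 1
        ref_aa = ref_p[prefix] if prefix < len(ref_p) else "*"
        if prefix == len(mut_p):
            # the first altered codon is itself a stop
            if mut_has_stop:
                return ProteinConsequence(
                    ConsequenceCategory.FRAMESHIFT,
                    f"p.{_aa3(ref_aa)}{first}Ter",
                    first_residue=first,
                    stop_offset=1,
                )
            return ProteinConsequence(
                ConsequenceCategory.FRAMESHIFT,
                f"p.{_aa3(ref_aa)}{first}fs*?",
                first_residue=first,
                flagged_no_stop=True,
            )
        new_aa = mut_p[prefix]
        if not mut_has_stop:
            return ProteinConsequence(
                ConsequenceCategory.FRAMESHIFT,
                f"p.{_aa3(ref_aa)}{first}{_aa3(new_aa)}fs*?",
                first_residue=first,
                flagged_no_stop=True,
            )
        stop_offset = len(mut_p) - prefix + 1  # stop position, first altered residue = 1
        return ProteinConsequence(
            ConsequenceCategory.FRAMESHIFT,
            f"p.{_aa3(ref_aa)}{first}{_aa3(new_aa)}fs*{stop_offset}",
            first_residue=first,
            stop_offset=stop_offset,
        )

    # in-frame: trim common suffix, then shift the changed window 3'-most
    suffix = 0
    while (
        suffix < min(len(ref_p), len(mut_p)) - prefix
        and ref_p[len(ref_p) - 1 - suffix] == mut_p[len(mut_p) - 1 - suffix]
    ):
        suffix += 1
    del_start, del_end = prefix, len(ref_p) - suffix  # ref_p[del_start:del_end] removed
    inserted = mut_p[prefix : len(mut_p) - suffix]
    deleted = ref_p[del_start:del_end]

    if len(deleted) == 1 and len(inserted) == 1:
        pos = del_start + 1
        return ProteinConsequence(
            ConsequenceCategory.MISSENSE,
            f"p.{_aa3(deleted)}{pos}{_aa3(inserted)}",
            first_residue=pos,
            n_residues_changed=1,
        )

    if not inserted:  # pure deletion: shift right while the window repeats
        s, e = del_start, del_end
        while e < len(ref_p) and ref_p[s] == ref_p[e]:
            s += 1
            e += 1
        pos1, pos2 = s + 1, e
        if pos1 == pos2:
            hgvs = f"p.{_aa3(ref_p[s])}{pos1}del"
        else:
            hgvs = f"p.{_aa3(ref_p[pos1 - 1])}{pos1}_{_aa3(ref_p[pos2 - 1])}{pos2}del"
        return ProteinConsequence(
            ConsequenceCategory.INFRAME_DELETION,
            hgvs,
            first_residue=pos1,
            n_residues_changed=pos2 - pos1 + 1,
        )

    if not deleted:  # pure insertion: rotate right while it duplicates the next residue
        p, ins = del_start, inserted
        while p < len(ref_p) and ins[0] == ref_p[p]:
            ins = ins[1:] + ins[0]
            p += 1
        left, right = p, p + 1  # inserted between residues left and right
        ins_desc = "".join(_aa3(a) for a in ins) if len(ins) <= 5 else str(len(ins))
        left_name = _aa3(ref_p[left - 1]) if left >= 1 else "?"
        right_name = _aa3(ref_p[right - 1]) if right <= len(ref_p) else "Ter"
        hgvs = f"p.{left_name}{left}_{right_name}{right}ins{ins_desc}"
        return ProteinConsequence(
            ConsequenceCategory.INFRAME_INSERTION,
            hgvs,
            first_residue=left,
            n_residues_changed=len(ins),
        )

    pos1, pos2 = del_start + 1, del_end
    ins_desc = "".join(_aa3(a) for a in inserted) if len(inserted) <= 5 else str(len(inserted))
    if pos1 == pos2:
        hgvs = f"p.{_aa3(ref_p[pos1 - 1])}{pos1}delins{ins_desc}"
    else:
        hgvs = f"p.{_aa3(ref_p[pos1 - 1])}{pos1}_{_aa3(ref_p[pos2 - 1])}{pos2}delins{ins_desc}"
    return ProteinConsequence(
        ConsequenceCategory.INFRAME_DELINS,
        hgvs,
        first_residue=pos1,
        n_residues_changed=len(deleted) + len(inserted),
    )


# ---------------------------------------------------------------------------
# candidate-event enumeration


def enumerate_candidate_events(
    site: SpliceSite, transcript: TranscriptModel, window: int = 500
) -> list[SpliceEventSpec]:
    """Enumerate plausible aberrant events when a canonical site is lost.

    Always proposes (in rank order): skipping of the adjacent exon, retention
    of the adjacent intron, skipping of the adjacent exon together with its
    upstream neighbour; then, when intronic sequence is available, every
    cryptic GT (donor) or AG (acceptor) dinucleotide within ``window`` bases
    of the lost site. Aberrant spliceosome products observed in vitro are
    drawn from exactly this repertoire.
    """
    i = site.intron_index
    if not 1 <= i < transcript.n_exons:
        raise ValueError(f"intron index {i} out of range")
    adjacent = i if site.kind == SpliceSiteKind.DONOR else i + 1
    events: list[SpliceEventSpec] = [
        SpliceEventSpec(SpliceEventKind.EXON_SKIP, exon_indices=(adjacent,)),
        SpliceEventSpec(SpliceEventKind.INTRON_RETENTION, intron_index=i),
    ]
    if adjacent - 1 >= 1:
        events.append(
            SpliceEventSpec(SpliceEventKind.MULTI_EXON_SKIP, exon_indices=(adjacent - 1, adjacent))
        )
    intron = transcript.introns.get(i)
    if intron is not None:
        if site.kind == SpliceSiteKind.DONOR:
            # GT at intronic positions j..j+1 (1-based, j >= 3 so as not to
            # re-propose the mutated canonical site) -> retain j-1 bases
            for j in range(3, min(len(intron), window + 1)):
                if intron[j - 1 : j + 1] == "GT":
                    events.append(
                        SpliceEventSpec(
                            SpliceEventKind.CRYPTIC_DONOR, intron_index=i, offset=j - 1
                        )
                    )
        else:
            # AG ending k+1 bases before the intron end -> retain last k bases
            L = len(intron)
            for k in range(1, min(L - 2, window) + 1):
                if intron[L - k - 2 : L - k] == "AG":
                    events.append(
                        SpliceEventSpec(
                            SpliceEventKind.CRYPTIC_ACCEPTOR, intron_index=i, offset=-k
                        )
                    )
    return events
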