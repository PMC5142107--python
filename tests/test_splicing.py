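"""Splice-event arithmetic: codon maps, event application, HGVS consequences."""

from __future__ import annotations

import random

import pytest

from excavar.splicing import (
    ConsequenceCategory,
    SpliceEventKind,
    SpliceEventSpec,
    SpliceSiteKind,
    TranscriptModel,
    apply_event,
    apply_intronic_variant,
    apply_small_variant,
    codon_of,
    consequence,
    enumerate_candidate_events,
    parse_cdna_change,
    site_of_variant,
    translate_to_stop,
)

from conftest import SENSE_CODONS, random_toy_transcript

K = SpliceEventKind
E = SpliceEventSpec

# ---------------------------------------------------------------------------
# codon arithmetic & HGVS parsing


@pytest.mark.parametrize(
    "c_pos,residue",
    [(4351, 1451), (3, 1), (2353, 785), (1, 1), (4, 2), (700, 234)],
)
def test_codon_of(c_pos, residue):
    assert codon_of(c_pos) == residue


def test_codon_of_rejects_nonpositive():
    with pytest.raises(ValueError):
        codon_of(0)


@pytest.mark.parametrize(
    "change,kind,intron",
    [
        ("c.700+1G>T", SpliceSiteKind.DONOR, 7),
        ("c.4549-1G>A", SpliceSiteKind.ACCEPTOR, 33),
        ("c.4002+1G>A", SpliceSiteKind.DONOR, 29),
    ],
)
def test_site_of_variant(cpamd8, change, kind, intron):
    site = site_of_variant(change, cpamd8)
    assert (site.kind, site.intron_index) == (kind, intron)


def test_site_of_variant_rejects_exonic(cpamd8):
    with pytest.raises(ValueError):
        site_of_variant("c.4351T>C", cpamd8)


def test_parse_rejects_garbage():
    for bad in ("c.12X>Y", "p.Ser1451Pro", "c.10_12insA", "nonsense"):
        with pytest.raises(ValueError):
            parse_cdna_change(bad)


# ---------------------------------------------------------------------------
# event application: length accounting


def test_event_length_changes(cpamd8):
    ref_len = len(cpamd8.coding_sequence)
    skip34 = apply_event(cpamd8, E(K.EXON_SKIP, exon_indices=(34,)))
    assert len(skip34) == ref_len - 63  # 21 codons
    retained = apply_event(cpamd8, E(K.INTRON_RETENTION, intron_index=33))
    assert len(retained) == ref_len + 78
    cryptic = apply_event(cpamd8, E(K.CRYPTIC_DONOR, intron_index=7, offset=142))
    assert len(cryptic) == ref_len + 142


def test_cryptic_offset_beyond_intron_is_error(cpamd8):
    with pytest.raises(ValueError):
        apply_event(cpamd8, E(K.CRYPTIC_DONOR, intron_index=7, offset=10_000))


def test_retention_needs_intron_sequence(cpamd8):
    with pytest.raises(ValueError):
        apply_event(cpamd8, E(K.INTRON_RETENTION, intron_index=5))


# ---------------------------------------------------------------------------
# worked consequences on the packaged transcript


@pytest.mark.parametrize(
    "event,category,hgvs,n_changed",
    [
        (E(K.EXON_SKIP, exon_indices=(34,)), ConsequenceCategory.INFRAME_DELETION,
         "p.Ile1517_Gln1537del", 21),
        (E(K.MULTI_EXON_SKIP, exon_indices=(33, 34)), ConsequenceCategory.INFRAME_DELETION,
         "p.Asp1465_Gln1537del", 73),
        (E(K.EXON_SKIP, exon_indices=(29,)), ConsequenceCategory.INFRAME_DELETION,
         "p.Gly1310_Glu1334del", 25),
    ],
)
def test_inframe_skip_consequences(cpamd8, event, category, hgvs, n_changed):
    cons = consequence(cpamd8, apply_event(cpamd8, event))
    assert cons.category == category
    assert cons.hgvs_p == hgvs
    assert cons.n_residues_changed == n_changed


def test_frameshift_skips(cpamd8):
    cons7 = consequence(cpamd8, apply_event(cpamd8, E(K.EXON_SKIP, exon_indices=(7,))))
    assert (cons7.hgvs_p, cons7.stop_offset) == ("p.Asp216Alafs*5", 5)
    cons67 = consequence(cpamd8, apply_event(cpamd8, E(K.MULTI_EXON_SKIP, exon_indices=(6, 7))))
    assert (cons67.hgvs_p, cons67.stop_offset) == ("p.Leu210Alafs*5", 5)


def test_intron_retention_insertion(cpamd8):
    mutant_model = apply_intronic_variant(cpamd8, "c.4549-1G>A")
    cons = consequence(cpamd8, apply_event(mutant_model, E(K.INTRON_RETENTION, intron_index=33)))
    assert cons.category == ConsequenceCategory.INFRAME_INSERTION
    assert cons.hgvs_p == "p.Ala1516_Ile1517ins26"
    assert cons.n_residues_changed == 26


def test_cryptic_donor_truncation(cpamd8):
    mutant_model = apply_intronic_variant(cpamd8, "c.700+1G>T")
    cons = consequence(cpamd8, apply_event(mutant_model, E(K.CRYPTIC_DONOR, intron_index=7, offset=142)))
    assert cons.hgvs_p == "p.Gly234Valfs*30"


def test_small_variants(cpamd8):
    cons = consequence(cpamd8, apply_small_variant(cpamd8, "c.4351T>C"))
    assert (cons.category, cons.hgvs_p) == (ConsequenceCategory.MISSENSE, "p.Ser1451Pro")
    cons = consequence(cpamd8, apply_small_variant(cpamd8, "c.2352_2353insC"))
    assert cons.hgvs_p == "p.Arg785Glnfs*23"
    assert (cons.first_residue, cons.stop_offset) == (785, 23)


def test_small_variant_ref_mismatch(cpamd8):
    with pytest.raises(ValueError, match="mismatch"):
        apply_small_variant(cpamd8, "c.4351A>C")


def test_delete_then_reinsert_is_identity(cpamd8):
    base = cpamd8.coding_sequence[9]  # c.10
    deleted = apply_small_variant(cpamd8, f"c.10del{base}")
    roundtrip = deleted[:9] + base + deleted[9:]
    assert roundtrip == cpamd8.coding_sequence


# ---------------------------------------------------------------------------
# candidate-event enumeration


def test_enumerate_acceptor_events(cpamd8):
    site = site_of_variant("c.4549-1G>A", cpamd8)
    described = {e.describe() for e in enumerate_candidate_events(site, cpamd8)}
    assert {"skip exon 34", "retain intron 33", "skip exons 33-34"} <= described


def test_enumerate_donor_events_with_cryptic(cpamd8):
    mutant_model = apply_intronic_variant(cpamd8, "c.700+1G>T")
    site = site_of_variant("c.700+1G>T", mutant_model)
    events = enumerate_candidate_events(site, mutant_model)
    described = {e.describe() for e in events}
    assert {"skip exon 7", "retain intron 7", "skip exons 6-7"} <= described
    cryptics = [e for e in events if e.kind == K.CRYPTIC_DONOR]
    assert [e.offset for e in cryptics] == [142]


def test_enumerate_without_intron_sequence(cpamd8):
    bare = TranscriptModel(
        gene=cpamd8.gene, exons=list(cpamd8.exons), coding_sequence=cpamd8.coding_sequence
    )
    site = site_of_variant("c.700+1G>T", bare)
    events = enumerate_candidate_events(site, bare)
    kinds = {e.kind for e in events}
    assert K.CRYPTIC_DONOR not in kinds
    assert {K.EXON_SKIP, K.INTRON_RETENTION, K.MULTI_EXON_SKIP} <= kinds


# ---------------------------------------------------------------------------
# properties & the independent oracle

_CODON_TABLE = {}


def _naive_codon_table():
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        for i, a in enumerate(bases):
            for j, b in enumerate(bases):
                for k, c in enumerate(bases):
                    _CODON_TABLE[a + b + c] = aas[16 * i + 4 * j + k]
    return _CODON_TABLE


def _naive_consequence(ref: str, mut: str):
    """Brute-force translate-then-diff oracle, independent of the engine."""
    table = _naive_codon_table()

    def translate(seq):
        prot, stopped = [], False
        for i in range(0, len(seq) - len(seq) % 3, 3):
            aa = table[seq[i : i + 3]]
            if aa == "*":
                stopped = True
                break
            prot.append(aa)
        return "".join(prot), stopped

    ref_p, _ = translate(ref)
    mut_p, mut_stopped = translate(mut)
    if ref_p == mut_p and mut_stopped:
        return ("synonymous_or_same", None, None)
    delta = len(mut) - len(ref)
    if delta % 3 == 0 and mut_stopped and len(mut_p) == len(ref_p) + delta // 3:
        i = 0
        while i < min(len(ref_p), len(mut_p)) and ref_p[i] == mut_p[i]:
            i += 1
        j = 0
        while j < min(len(ref_p), len(mut_p)) - i and ref_p[-1 - j] == mut_p[-1 - j]:
            j += 1
        deleted = ref_p[i : len(ref_p) - j]
        inserted = mut_p[i : len(mut_p) - j]
        if deleted and not inserted:
            s, e = i, len(ref_p) - j
            while e < len(ref_p) and ref_p[s] == ref_p[e]:
                s, e = s + 1, e + 1
            return ("del", s + 1, e)
        if inserted and not deleted:
            p, ins = i, inserted
            while p < len(ref_p) and ins[0] == ref_p[p]:
                ins = ins[1:] + ins[0]
                p += 1
            return ("ins", p, len(inserted))
        if len(deleted) == 1 == len(inserted):
            return ("missense", i + 1, inserted)
        return ("delins", i + 1, len(deleted) + len(inserted))
    i = 0
    while i < min(len(ref_p), len(mut_p)) and ref_p[i] == mut_p[i]:
        i += 1
    if not mut_stopped:
        return ("fs_no_stop", i + 1, None)
    return ("fs", i + 1, len(mut_p) - i + 1)


def _random_event(rng, transcript):
    kind = rng.choice(
        [K.EXON_SKIP, K.MULTI_EXON_SKIP, K.INTRON_RETENTION, K.CRYPTIC_DONOR, K.CRYPTIC_ACCEPTOR]
    )
    n = transcript.n_exons
    if kind == K.EXON_SKIP:
        return E(kind, exon_indices=(rng.randint(1, n),))
    if kind == K.MULTI_EXON_SKIP:
        a = rng.randint(1, n - 1)
        return E(kind, exon_indices=(a, a + 1))
    i = rng.randint(1, n - 1)
    if kind == K.INTRON_RETENTION:
        return E(kind, intron_index=i)
    intron_len = len(transcript.introns[i])
    if kind == K.CRYPTIC_DONOR:
        return E(kind, intron_index=i, offset=rng.randint(1, intron_len))
    return E(kind, intron_index=i, offset=-rng.randint(1, intron_len))


def test_consequence_matches_naive_oracle_500_trials():
    """Engine vs brute-force translate-and-diff on random transcripts/events."""
    rng = random.Random(1234)
    mismatches = []
    for trial in range(500):
        t = random_toy_transcript(rng)
        event = _random_event(rng, t)
        mut = apply_event(t, event)
        got = consequence(t, mut)
        want = _naive_consequence(t.coding_sequence, mut)
        kind, a, b = want
        if kind == "synonymous_or_same":
            ok = got.category in (ConsequenceCategory.SYNONYMOUS, ConsequenceCategory.NO_CHANGE)
        elif kind == "del":
            ok = (
                got.category == ConsequenceCategory.INFRAME_DELETION
                and got.first_residue == a
                and got.first_residue + got.n_residues_changed - 1 == b
            )
        elif kind == "ins":
            ok = (
                got.category == ConsequenceCategory.INFRAME_INSERTION
                and got.first_residue == a
                and got.n_residues_changed == b
            )
        elif kind == "missense":
            ok = got.category == ConsequenceCategory.MISSENSE and got.first_residue == a
        elif kind == "delins":
            ok = (
                got.category == ConsequenceCategory.INFRAME_DELINS
                and got.first_residue == a
                and got.n_residues_changed == b
            )
        elif kind == "fs_no_stop":
            ok = got.category == ConsequenceCategory.FRAMESHIFT and got.flagged_no_stop
        else:  # fs
            ok = (
                got.category == ConsequenceCategory.FRAMESHIFT
                and got.first_residue == a
                and (got.stop_offset == b or (b == 1 and got.stop_offset == 1))
            )
        if not ok:
            mismatches.append((trial, event, want, got))
    assert not mismatches, mismatches[:3]


def test_event_length_invariant_randomized():
    rng = random.Random(99)
    for _ in range(100):
        t = random_toy_transcript(rng)
        event = _random_event(rng, t)
        mut = apply_event(t, event)
        if event.kind in (K.EXON_SKIP, K.MULTI_EXON_SKIP):
            expected = -sum(t.exon(k).length for k in event.exon_indices)
        elif event.kind == K.INTRON_RETENTION:
            expected = len(t.introns[event.intron_index])
        else:
            expected = abs(event.offset)
        assert len(mut) - len(t.coding_sequence) == expected


def test_inframe_iff_mod3_and_no_stop_exhaustive():
    """On a 10-codon toy CDS, every single-exon skip is in-frame exactly when
    its length is a multiple of 3 and the junction creates no early stop."""
    rng = random.Random(5)
    for _ in range(30):
        t = random_toy_transcript(rng, n_exons=4, n_codons=10)
        for k in range(1, t.n_exons + 1):
            mut = apply_event(t, E(K.EXON_SKIP, exon_indices=(k,)))
            got = consequence(t, mut)
            removed = t.exon(k).length
            # in-frame means: multiple-of-3 loss, a stop still reached, and
            # the stop exactly where a clean codon-count deletion puts it
            mut_p = translate_to_stop(mut)
            has_stop = len(mut_p) < (len(mut) - len(mut) % 3) // 3
            inframe_expected = (
                removed % 3 == 0
                and has_stop
                and len(mut_p) == len(t.protein()) - removed // 3
            )
            inframe_got = got.category in (
                ConsequenceCategory.INFRAME_DELETION,
                ConsequenceCategory.INFRAME_INSERTION,
                ConsequenceCategory.INFRAME_DELINS,
                ConsequenceCategory.SYNONYMOUS,
                ConsequenceCategory.NO_CHANGE,
            )
            assert inframe_got == inframe_expected, (k, t.exons, got)


def test_hgvs_3prime_normalization_is_maximal():
    """Deleting any one codon of a repeat run names the 3'-most copy."""
    # M K A A A A R stop
    cds = "ATG" + "AAA" + "GCT" * 4 + "CGT" + "TAA"
    t = TranscriptModel(gene="TOY", exons=[(1, 1, len(cds))], coding_sequence=cds)
    for start in (7, 10, 13, 16):  # each GCT codon
        mut = cds[: start - 1] + cds[start + 2 :]
        got = consequence(t, mut)
        assert got.hgvs_p == "p.Ala6del"  # always the last repeat copy
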