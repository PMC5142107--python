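"""Lightweight comparative-sequence support.

Pairwise global protein alignment (Needleman-Wunsch with linear gap
penalties, via Biopython's PairwiseAligner) reporting full-length percent
identity, plus alignment-column conservation over a pre-built MSA, and a
declarative synteny presence/absence check for the CPAMD8 locus.

Percent identity is computed over *all* alignment columns, gap columns
included ("full-length" identity). Tools that divide by the shorter
sequence or by aligned columns only will report higher numbers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio import Align

__all__ = [
    "AlignmentResult",
    "global_align",
    "identity_matrix",
    "column_conserved",
    "cpamd8_synteny_table",
    "rodents_lack_gene",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass(frozen=True, slots=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float
    n_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences must have equal length")


def global_align(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Linear gap penalty (open == extend). Ties between co-optimal alignments
    are broken deterministically (the aligner's first enumeration order,
    which prefers the diagonal). Raises on empty input or characters outside
    the 20-letter amino-acid alphabet.
    """
    a, b = a.upper(), b.upper()
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"illegal residue characters in sequence {name}: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    n_columns = len(ga)
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
        identity_percent=100.0 * matches / n_columns,
        n_columns=n_columns,
    )


def identity_matrix(sequences: dict, **scores) -> pd.DataFrame:
    """Pairwise full-length percent-identity matrix over named sequences."""
    names = list(sequences)
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            ident = global_align(sequences[x], sequences[y], **scores).identity_percent
            mat.loc[x, y] = mat.loc[y, x] = ident
    return mat


def column_conserved(msa: list[str], column: int) -> tuple[Counter, bool]:
    """Residue multiset at one 0-based MSA column and an invariance flag.

    Invariant iff a single residue type occupies the column across all
    non-gap rows; an all-gap column is not invariant.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows differ in length")
    if not 0 <= column < width:
        raise ValueError(f"column {column} out of range 0..{width - 1}")
    residues = Counter(row[column] for row in msa if row[column] != GAP)
    return residues, len(residues) == 1


def cpamd8_synteny_table() -> pd.DataFrame:
    """Packaged presence/absence table for the HAUS8-CPAMD8-SIN3B locus."""
    with resources.files("excavar.data").joinpath("synteny_cpamd8.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def rodents_lack_gene(table: pd.DataFrame) -> bool:
    """True iff the gene is flanked by HAUS8/SIN3B everywhere yet absent
    from every rodent row and present in every non-rodent row."""
    flanked = ((table["left_flank"] == "HAUS8") & (table["right_flank"] == "SIN3B")).all()
    rodent = table["lineage"] == "rodent"
    return bool(
        flanked
        and (table.loc[rodent, "gene_present"] == 0).all()
        and (table.loc[~rodent, "gene_present"] == 1).all()
    )
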