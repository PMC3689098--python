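"""Pairwise global alignment and percent identity, whole-sequence and binding-area.

Alignment is optimal Needleman–Wunsch with affine gaps (Biopython's
``PairwiseAligner``), BLOSUM62 with gap open 10 / extend 0.5 by default —
the era defaults of classic multiple-alignment tools.  Percent identity is
computed over mutually aligned (non-gap-pair) columns; the binding-area
variant restricts to alignment columns touched by either protein's interface
positions, so identities of the contact region can be compared with the
whole-chain value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SequenceRecord",
    "AlignParams",
    "PairwiseAlignment",
    "read_fasta",
    "write_fasta",
    "global_align",
    "percent_identity",
    "binding_area_identity",
    "identity_matrix",
]

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (1-letter codes, X allowed for unknowns)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid letters {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0  # cost of the first residue of a gap
    gap_extend: float = 0.5  # cost of each further gap residue


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def _make_aligner(params: AlignParams):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -float(params.gap_open)
    aligner.extend_gap_score = -float(params.gap_extend)
    aligner.mode = "global"
    return aligner


def global_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment; the aligner's first traceback is taken, which
    is deterministic for fixed inputs and parameters."""
    p = params or AlignParams()
    aligner = _make_aligner(p)
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    al = PairwiseAlignment(aligned_a, aligned_b, float(best.score), p)
    if al.degapped() != (a.residues, b.residues):
        raise AssertionError("alignment does not round-trip to its inputs")
    return al


def percent_identity(al: PairwiseAlignment, mode: str = "aligned-columns") -> float:
    """Percent identical residues.

    ``aligned-columns`` (default): identical columns / columns where both
    sequences have a residue.  ``shorter-seq``: identical columns / length of
    the shorter input sequence.
    """
    same = 0
    both = 0
    for x, y in zip(al.aligned_a, al.aligned_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                same += 1
    if mode == "aligned-columns":
        if both == 0:
            raise ValueError("alignment has no mutually aligned columns")
        return 100.0 * same / both
    if mode == "shorter-seq":
        sa, sb = al.degapped()
        return 100.0 * same / min(len(sa), len(sb))
    raise ValueError(f"unknown identity mode {mode!r}")


def binding_area_identity(
    al: PairwiseAlignment,
    contacts_a: Sequence[int] | set[int],
    contacts_b: Sequence[int] | set[int],
) -> float:
    """Percent identity over the interface columns of the alignment.

    ``contacts_a``/``contacts_b`` are 1-based residue positions in the
    respective *ungapped* sequences; a column is selected when its position in
    either sequence is a contact (union through the alignment).  Identity is
    then identical / mutually-aligned over the selected columns.
    """
    ca, cb = set(contacts_a), set(contacts_b)
    if not ca and not cb:
        raise ValueError("both contact sets are empty")
    pos_a = pos_b = 0
    same = both = selected = 0
    for x, y in zip(al.aligned_a, al.aligned_b):
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        hit = (x != "-" and pos_a in ca) or (y != "-" and pos_b in cb)
        if not hit:
            continue
        selected += 1
        if x != "-" and y != "-":
            both += 1
            if x == y:
                same += 1
    if selected == 0:
        raise ValueError("no alignment column matches the contact positions")
    if both == 0:
        raise ValueError("all selected interface columns are gapped")
    return 100.0 * same / both


def identity_matrix(
    records: Sequence[SequenceRecord], params: AlignParams | None = None
) -> pd.DataFrame:
    """Lower-triangle percent-identity matrix over whole sequences."""
    ids = [r.id for r in records]
    mat = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for r in records:
        mat.loc[r.id, r.id] = 100.0
    for a, b in combinations(records, 2):
        pid = percent_identity(global_align(a, b, params))
        mat.loc[a.id, b.id] = pid
        mat.loc[b.id, a.id] = pid
    return mat
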