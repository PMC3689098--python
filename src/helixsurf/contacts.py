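"""Residue-level interface contacts and helix-face key-residue extraction.

A receptor residue and a peptide residue are in contact when the minimum
distance over qualifying atom pairs is at or below the cutoff (default 5 Å,
inclusive).  By default only side-chain atoms qualify on *both* sides —
glycine contributes its CA so it is not structurally invisible.

On an ideal alpha helix (100° per residue) positions i, i+3/i+4 and i+7 fall
on one face; the triple of contacting peptide residues with those offsets is
the face that small-molecule helix mimetics (e.g. terphenyls) reproduce.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure, StructureError

__all__ = [
    "ContactParams",
    "ResidueRef",
    "ContactPair",
    "ContactMap",
    "contact_residues",
    "helix_face_triples",
    "HelixFaceTriple",
    "receptor_hotspot_tally",
]


class ResidueRef(NamedTuple):
    """Residue identity by author numbering, with its name for reporting."""

    chain_id: str
    number: int
    icode: str
    name: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.icode.strip()}"


@dataclass(frozen=True)
class ContactParams:
    cutoff: float = 5.0  # Å, inclusive
    sidechain_only: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("contact cutoff must be positive")


class ContactPair(NamedTuple):
    receptor: ResidueRef
    peptide: ResidueRef
    min_distance: float  # Å


@dataclass
class ContactMap:
    """Interface contacts between one receptor and one bound peptide."""

    pairs: list[ContactPair]
    params: ContactParams = field(default_factory=ContactParams)

    @property
    def receptor_residues(self) -> set[ResidueRef]:
        return {p.receptor for p in self.pairs}

    @property
    def peptide_residues(self) -> set[ResidueRef]:
        return {p.peptide for p in self.pairs}

    @property
    def pair_keys(self) -> set[tuple[tuple, tuple]]:
        return {(p.receptor.key, p.peptide.key) for p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs, key=lambda p: (p.receptor.key, p.peptide.key))
        return pd.DataFrame(
            {
                "receptor_res": [p.receptor.label for p in rows],
                "receptor_chain": [p.receptor.chain_id for p in rows],
                "peptide_res": [p.peptide.label for p in rows],
                "peptide_chain": [p.peptide.chain_id for p in rows],
                "min_dist": [round(p.min_distance, 3) for p in rows],
            }
        )


def _qualifying_indices(s: Structure, sidechain_only: bool) -> list[int]:
    if sidechain_only:
        return [i for i, a in enumerate(s.atoms) if a.is_sidechain]
    return list(range(len(s)))


def contact_residues(
    receptor: Structure, peptide: Structure, params: ContactParams | None = None
) -> ContactMap:
    """All (receptor residue, peptide residue) pairs within the cutoff.

    The k-d tree pair query at the exact cutoff radius is equivalent to the
    brute-force all-pairs scan (asserted by tests); the boundary is inclusive.
    """
    p = params or ContactParams()
    if len(receptor) == 0 or len(peptide) == 0:
        raise StructureError("receptor and peptide must both be non-empty")
    ri = _qualifying_indices(receptor, p.sidechain_only)
    pi = _qualifying_indices(peptide, p.sidechain_only)
    best: dict[tuple, ContactPair] = {}
    if ri and pi:
        rc = receptor.coords()[ri]
        pc = peptide.coords()[pi]
        tree_r = cKDTree(rc)
        tree_p = cKDTree(pc)
        # sparse matrix of all qualifying atom pairs within cutoff
        pairs = tree_r.sparse_distance_matrix(tree_p, p.cutoff, output_type="coo_matrix")
        for k, (a, b) in enumerate(zip(pairs.row, pairs.col)):
            d = pairs.data[k]
            ra = receptor.atoms[ri[a]]
            pa = peptide.atoms[pi[b]]
            key = (ra.residue_key, pa.residue_key)
            if key not in best or d < best[key].min_distance:
                best[key] = ContactPair(
                    ResidueRef(ra.chain_id, ra.residue_number, ra.icode, ra.residue_name),
                    ResidueRef(pa.chain_id, pa.residue_number, pa.icode, pa.residue_name),
                    float(d),
                )
    return ContactMap(sorted(best.values(), key=lambda c: (c.receptor.key, c.peptide.key)), p)


@dataclass(frozen=True)
class HelixFaceTriple:
    """Three contacting peptide residues on one helix face."""

    residues: tuple[ResidueRef, ResidueRef, ResidueRef]
    pattern: str  # "i,i+3,i+7" or "i,i+4,i+7"

    def __post_init__(self) -> None:
        i, j, k = (r.number for r in self.residues)
        if (j - i, k - i) not in {(3, 7), (4, 7)}:
            raise ValueError(f"offsets ({j - i}, {k - i}) are not a helix-face pattern")

    @property
    def labels(self) -> tuple[str, str, str]:
        return tuple(r.label for r in self.residues)  # type: ignore[return-value]


def helix_face_triples(cm: ContactMap) -> list[HelixFaceTriple]:
    """Every (i, i+3, i+7) and (i, i+4, i+7) triple among contacting peptide residues."""
    by_chain: dict[str, dict[int, ResidueRef]] = {}
    for r in cm.peptide_residues:
        by_chain.setdefault(r.chain_id, {})[r.number] = r
    out: list[HelixFaceTriple] = []
    for chain in sorted(by_chain):
        nums = by_chain[chain]
        for i in sorted(nums):
            for mid, pattern in ((3, "i,i+3,i+7"), (4, "i,i+4,i+7")):
                if i + mid in nums and i + 7 in nums:
                    out.append(
                        HelixFaceTriple((nums[i], nums[i + mid], nums[i + 7]), pattern)
                    )
    return out


def receptor_hotspot_tally(maps: Mapping[str, ContactMap] | Iterable[ContactMap]) -> pd.DataFrame:
    """Per receptor residue, the number of complexes in which it contacts the peptide.

    Input maps must share the receptor numbering scheme (same protein bound to
    different peptides).  Returns a table sorted by descending count.
    """
    if isinstance(maps, Mapping):
        maps = list(maps.values())
    else:
        maps = list(maps)
    if not maps:
        raise ValueError("no contact maps given")
    # tally by (number, icode, name): the shared numbering scheme, ignoring
    # per-complex chain ids
    counts: Counter[tuple[int, str, str]] = Counter()
    for cm in maps:
        counts.update({(r.number, r.icode, r.name) for r in cm.receptor_residues})
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "residue": [f"{name}{num}{icode.strip()}" for (num, icode, name), _ in rows],
            "n_complexes": [c for _, c in rows],
        }
    )
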