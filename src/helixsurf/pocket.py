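"""Helix-binding pocket definition and descriptors: volume, hydrophobicity, density.

The pocket is not detected blindly: it is anchored on the bound (then removed)
peptide.  Lining atoms are the receptor atoms within ``lining_cutoff`` of any
peptide atom, and the former peptide atom positions seed the cavity.

Volume is measured on a regular grid: a voxel belongs to the pocket when it is
outside every receptor atom, not part of bulk solvent, within an envelope
around the seed points, and flood-fill-connected to a seed voxel.  Bulk
solvent is the boundary-connected region where a ball of radius
``mouth_probe`` fits, dilated back by that radius — so space reachable only
through openings wider than the mouth probe is treated as outside.

The hydrophobicity score is the mean per-residue hydrophobicity (Monera scale
by default, the convention of pocket-profiling tools) over the lining
residues; local hydrophobic density is the mean number of apolar lining
neighbours per apolar lining atom, a measure of hydrophobic clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .contacts import ResidueRef
from .structure import Structure, StructureError

__all__ = [
    "PocketDefinition",
    "PocketDescriptors",
    "define_pocket",
    "pocket_volume",
    "hydrophobicity_score",
    "local_hydrophobic_density",
    "describe_pocket",
    "MONERA_SCALE",
    "KYTE_DOOLITTLE_SCALE",
    "APOLAR_RESIDUES",
    "HYDROPHOBICITY_SCALES",
]

#: Normalised hydrophobicity of residues in an alpha-helical context at pH 7
#: (Monera et al. scale, as used by pocket-profiling descriptors).
MONERA_SCALE: dict[str, float] = {
    "ALA": 41.0, "ARG": -14.0, "ASN": -28.0, "ASP": -55.0, "CYS": 49.0,
    "GLN": -10.0, "GLU": -31.0, "GLY": 0.0, "HIS": 8.0, "ILE": 99.0,
    "LEU": 97.0, "LYS": -23.0, "MET": 74.0, "PHE": 100.0, "PRO": -46.0,
    "SER": -5.0, "THR": 13.0, "TRP": 97.0, "TYR": 63.0, "VAL": 76.0,
}

#: Kyte–Doolittle hydropathy, provided as an alternate scale.
KYTE_DOOLITTLE_SCALE: dict[str, float] = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

HYDROPHOBICITY_SCALES = {"monera": MONERA_SCALE, "kyte-doolittle": KYTE_DOOLITTLE_SCALE}

#: Residues whose carbon/sulfur atoms count as apolar for the density measure.
APOLAR_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS", "GLY"}
)


@dataclass
class PocketDefinition:
    """Peptide-anchored pocket: lining atoms of the receptor plus seed points."""

    lining_indices: np.ndarray  # indices into the receptor structure
    lining_residues: list[ResidueRef]
    seed_points: np.ndarray  # (m, 3) former peptide atom positions, Å
    lining_cutoff: float  # Å

    @property
    def n_lining_atoms(self) -> int:
        return len(self.lining_indices)

    @property
    def n_lining_residues(self) -> int:
        return len(self.lining_residues)


@dataclass
class PocketDescriptors:
    """Table-3-style descriptor row for one pocket."""

    volume: float  # ų
    hydrophobicity_score: float
    local_hydrophobic_density: float
    n_lining_residues: int


def define_pocket(
    receptor: Structure, peptide: Structure, lining_cutoff: float = 4.5
) -> PocketDefinition:
    """Lining = receptor atoms within *lining_cutoff* of any peptide atom."""
    if len(receptor) == 0 or len(peptide) == 0:
        raise StructureError("receptor and peptide must both be non-empty")
    seeds = peptide.coords()
    tree = cKDTree(seeds)
    d, _ = tree.query(receptor.coords(), k=1)
    idx = np.flatnonzero(d <= lining_cutoff)
    if idx.size == 0:
        raise StructureError(
            f"no receptor atom within {lining_cutoff} Å of the peptide; not a bound complex"
        )
    seen: dict[tuple, ResidueRef] = {}
    for i in idx:
        a = receptor.atoms[int(i)]
        seen.setdefault(a.residue_key, ResidueRef(a.chain_id, a.residue_number, a.icode, a.residue_name))
    residues = [seen[k] for k in sorted(seen)]
    return PocketDefinition(idx, residues, seeds, float(lining_cutoff))


def _occupancy_grid(coords, radii, origin, shape, spacing):
    """Boolean grid marking voxels whose centre lies inside any atom."""
    occ = np.zeros(shape, dtype=bool)
    lo = np.asarray(origin)
    for c, r in zip(coords, radii):
        imin = np.maximum(np.floor((c - r - lo) / spacing).astype(int), 0)
        imax = np.minimum(np.ceil((c + r - lo) / spacing).astype(int) + 1, shape)
        if np.any(imin >= imax):
            continue
        ax = [lo[k] + spacing * np.arange(imin[k], imax[k]) for k in range(3)]
        dx2 = (ax[0] - c[0]) ** 2
        dy2 = (ax[1] - c[1]) ** 2
        dz2 = (ax[2] - c[2]) ** 2
        # closed balls: a centre exactly on an atom surface counts occupied,
        # which removes the one-shell overcount when the grid happens to align
        # with a tangent plane
        local = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occ[imin[0]:imax[0], imin[1]:imax[1], imin[2]:imax[2]] |= local
    return occ


def pocket_volume(
    receptor: Structure,
    pocket: PocketDefinition,
    grid_spacing: float = 0.5,
    mouth_probe: float = 3.0,
    envelope_radius: float = 8.0,
) -> float:
    """Grid volume (ų) of the cavity seeded by the removed peptide.

    Deterministic for fixed inputs.  ``grid_spacing`` must lie in
    [0.25, 1.0] Å; ``mouth_probe`` controls which openings connect the cavity
    to bulk solvent; ``envelope_radius`` bounds the pocket to the neighbourhood
    of the seed points.
    """
    if not (0.25 <= grid_spacing <= 1.0):
        raise ValueError("grid_spacing must be within [0.25, 1.0] Å")
    coords = receptor.coords()
    radii = receptor.radii()
    seeds = np.atleast_2d(pocket.seed_points)

    pad = mouth_probe + 2.0 * grid_spacing
    lo = np.minimum(coords.min(axis=0) - radii.max(), seeds.min(axis=0) - envelope_radius) - pad
    hi = np.maximum(coords.max(axis=0) + radii.max(), seeds.max(axis=0) + envelope_radius) + pad
    # irrational origin offset: keeps voxel centres off any flat atom-tangent
    # plane, so midpoint counting is not biased by a degenerate alignment
    lo = lo - grid_spacing / np.pi
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1

    occ = _occupancy_grid(coords, radii, lo, shape, grid_spacing)
    free = ~occ

    # clearance: distance from each free voxel to the occupied region
    clearance = ndimage.distance_transform_edt(free, sampling=grid_spacing)

    # bulk solvent: wide (clearance >= mouth_probe) free space connected to the
    # grid boundary, dilated back by the mouth-probe radius
    wide = clearance >= mouth_probe
    labels, _ = ndimage.label(wide)
    boundary_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    boundary_labels = boundary_labels[boundary_labels != 0]
    bulk_core = np.isin(labels, boundary_labels)
    if bulk_core.any():
        dist_to_bulk = ndimage.distance_transform_edt(~bulk_core, sampling=grid_spacing)
        bulk = dist_to_bulk <= mouth_probe
    else:
        bulk = np.zeros_like(free)

    # envelope: voxels near any seed point
    seed_tree = cKDTree(seeds)
    candidate = free & ~bulk
    cand_idx = np.argwhere(candidate)
    if cand_idx.size == 0:
        raise StructureError("no free pocket voxel; cavity is fully occluded or open")
    cand_pts = lo + cand_idx * grid_spacing
    near = seed_tree.query(cand_pts, k=1)[0] <= envelope_radius
    region = np.zeros_like(free)
    region[tuple(cand_idx[near].T)] = True

    # flood fill from seed voxels across the region
    seed_vox = np.round((seeds - lo) / grid_spacing).astype(int)
    seed_vox = seed_vox[np.all((seed_vox >= 0) & (seed_vox < shape), axis=1)]
    seed_mask = np.zeros_like(free)
    seed_mask[tuple(seed_vox.T)] = True
    seed_mask &= region
    if not seed_mask.any():
        raise StructureError("no seed voxel is free inside the pocket region")
    labels, _ = ndimage.label(region)
    keep = np.unique(labels[seed_mask])
    keep = keep[keep != 0]
    n_voxels = int(np.isin(labels, keep).sum())
    return float(n_voxels) * grid_spacing**3


def hydrophobicity_score(
    pocket: PocketDefinition,
    scale: dict[str, float] | str = "monera",
    unknown_default: float = 0.0,
) -> float:
    """Mean hydrophobicity-scale value over lining residues (each counted once)."""
    if isinstance(scale, str):
        scale = HYDROPHOBICITY_SCALES[scale]
    if not pocket.lining_residues:
        raise StructureError("pocket has no lining residues")
    values = []
    for r in pocket.lining_residues:
        if r.name in scale:
            values.append(scale[r.name])
        else:
            warnings.warn(
                f"residue {r.label} not in hydrophobicity scale; using {unknown_default}",
                stacklevel=2,
            )
            values.append(unknown_default)
    return float(np.mean(values))


def local_hydrophobic_density(
    receptor: Structure, pocket: PocketDefinition, neighbor_cutoff: float = 4.5
) -> float:
    """Mean number of apolar lining neighbours per apolar lining atom.

    Apolar lining atoms are the carbon/sulfur atoms of the lining that belong
    to apolar residues; each one's neighbours are the *other* apolar lining
    atoms within the cutoff.  Returns 0 when the lining has no apolar atoms.
    """
    if pocket.n_lining_atoms == 0:
        raise StructureError("pocket has no lining atoms")
    apolar = [
        int(i)
        for i in pocket.lining_indices
        if receptor.atoms[int(i)].element.upper() in ("C", "S")
        and receptor.atoms[int(i)].residue_name in APOLAR_RESIDUES
    ]
    if len(apolar) == 0:
        return 0.0
    pts = receptor.coords()[apolar]
    tree = cKDTree(pts)
    neighbor_counts = np.array([len(nb) - 1 for nb in tree.query_ball_point(pts, neighbor_cutoff)])
    return float(neighbor_counts.mean())


def describe_pocket(
    receptor: Structure,
    pocket: PocketDefinition,
    grid_spacing: float = 0.5,
    mouth_probe: float = 3.0,
    envelope_radius: float = 8.0,
    scale: dict[str, float] | str = "monera",
    neighbor_cutoff: float = 4.5,
) -> PocketDescriptors:
    """Volume + hydrophobicity + density for one pocket."""
    return PocketDescriptors(
        volume=pocket_volume(receptor, pocket, grid_spacing, mouth_probe, envelope_radius),
        hydrophobicity_score=hydrophobicity_score(pocket, scale),
        local_hydrophobic_density=local_hydrophobic_density(receptor, pocket, neighbor_cutoff),
        n_lining_residues=pocket.n_lining_residues,
    )
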