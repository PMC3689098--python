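"""Synthetic structures with analytically known properties.

Every generator returns a :class:`~helixsurf.structure.Structure` (or a
receptor/peptide pair) together with a ground-truth record, so each pipeline
stage can be validated without any external data:

* spheres and sphere pairs — closed-form accessible areas;
* flat slabs — the smooth limit, surface fractal dimension near 2;
* rough blobs — an ordinal roughness knob (bump shells) that the fractal
  fit must recover monotonically;
* blocks with carved cavities — voxel-countable volumes;
* a receptor groove + ideal alpha-helix complex — known contacts, known
  pocket lining, known carved volume and a designated (i, i+3, i+7)
  anchor face.

All pseudo-atoms carry standard element radii so the SASA engine runs
unmodified.  Randomness (bump placement, pseudo-residue identities) is
confined to a seeded generator: the same spec and seed reproduce the same
structure bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .structure import Atom, Structure, StructureError

__all__ = [
    "SyntheticSpec",
    "make_sphere",
    "make_sphere_pair",
    "make_slab",
    "make_rough_blob",
    "make_block_cavity",
    "make_groove_complex",
    "generate",
]

_DEFAULT_RADIUS = 1.70  # carbon vdW, Å


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative recipe: kind + geometry parameters + seed."""

    kind: str  # sphere | pair | slab | rough_blob | block_cavity | groove_complex
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


def _atoms_from_points(
    points: np.ndarray,
    chain_id: str = "A",
    atom_name: str = "CB",
    residue_names: list[str] | None = None,
    radius: float = _DEFAULT_RADIUS,
    element: str = "C",
    start_serial: int = 1,
) -> list[Atom]:
    """One single-atom pseudo-residue per point (residue-level = atom-level)."""
    atoms = []
    for i, p in enumerate(np.atleast_2d(points)):
        rname = residue_names[i] if residue_names is not None else "UNK"
        atoms.append(
            Atom(
                serial=start_serial + i,
                name=atom_name,
                element=element,
                residue_name=rname,
                residue_number=i + 1,
                chain_id=chain_id,
                position=np.asarray(p, float),
                radius=radius,
            )
        )
    return atoms


def make_sphere(radius: float = _DEFAULT_RADIUS, center=(0.0, 0.0, 0.0)) -> Structure:
    """Single pseudo-atom; SASA at probe R is exactly 4π(r+R)²."""
    atoms = _atoms_from_points(np.asarray([center]), radius=radius)
    return Structure(atoms, source_id="sphere")

def make_sphere_pair(r1: float, r2: float, distance: float) -> Structure:
    """Two pseudo-atoms on the z axis; compare against the two-sphere cap formula."""
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(distance)]])
    atoms = _atoms_from_points(pts[:1], radius=r1) + _atoms_from_points(
        pts[1:], radius=r2, start_serial=2
    )
    # distinct residue numbers
    atoms[1] = Atom(2, "CB", "C", "UNK", 2, "A", pts[1], radius=r2)
    return Structure(atoms, source_id="pair")


def _cubic_lattice(nx: int, ny: int, nz: int, spacing: float) -> np.ndarray:
    ax = [spacing * (np.arange(n) - (n - 1) / 2.0) for n in (nx, ny, nz)]
    g = np.meshgrid(*ax, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def make_slab(
    nx: int = 20,
    ny: int = 20,
    layers: int = 3,
    spacing: float = 1.8,
    radius: float = _DEFAULT_RADIUS,
) -> tuple[Structure, dict]:
    """Flat slab of overlapping pseudo-atoms: the smooth-surface limit (D ≈ 2).

    A finite slab's *total* area still grows with the probe (edge quarter-
    cylinders and corner caps scale with R), which biases the whole-body
    dimension below 2; the smooth limit proper is read on the interior
    top-face atoms, whose indices the ground truth records.
    """
    if nx < 10 or ny < 10 or layers < 1:
        raise ValueError("slab needs nx, ny >= 10 and at least one layer")
    pts = _cubic_lattice(nx, ny, layers, spacing)
    s = Structure(_atoms_from_points(pts, radius=radius), source_id="slab")
    zmax = pts[:, 2].max()
    margin = 3 * spacing
    interior_face = [
        i
        for i in range(len(pts))
        if abs(pts[i, 2] - zmax) < 1e-9
        and abs(pts[i, 0]) <= pts[:, 0].max() - margin
        and abs(pts[i, 1]) <= pts[:, 1].max() - margin
    ]
    truth = {
        "n_atoms": nx * ny * layers,
        "expected_dimension_range": (1.9, 2.1),
        "face_area": (nx * spacing) * (ny * spacing),
        "interior_face_indices": interior_face,
    }
    return s, truth


def make_rough_blob(
    base_radius: float = 9.0,
    bump_levels: int = 2,
    bump_scale: float = 0.8,
    seed: int = 0,
    spacing: float = 1.8,
    bumps_per_level: int = 15,
    radius: float = _DEFAULT_RADIUS,
) -> tuple[Structure, dict]:
    """Lattice-filled ball decorated with protruding surface bumps.

    Roughness is ordinal in ``bump_levels``: each level adds another seeded
    shell of ``bumps_per_level`` protruding atoms, carving extra crevices at
    the 1–2 Å probe scale, so the fitted fractal dimension must not decrease
    with the level.  ``bump_levels=0`` is the smooth ball.  Bump shells are
    nested across levels (same seed), which makes the roughness ordering a
    property of the construction rather than of sampling noise.
    """
    if not 0 <= bump_levels <= 4:
        raise ValueError("bump_levels must be in [0, 4]")
    pts = _cubic_lattice(
        int(2 * base_radius / spacing) + 3,
        int(2 * base_radius / spacing) + 3,
        int(2 * base_radius / spacing) + 3,
        spacing,
    )
    ball = pts[np.linalg.norm(pts, axis=1) <= base_radius]
    rng = np.random.default_rng(seed)
    # one seeded sequence of minimum-separation bump sites; level L uses the
    # first L*bumps_per_level of them, so levels are nested and each level
    # adds bumps that carve fresh crevices instead of piling onto old ones
    n_total = bump_levels * bumps_per_level
    min_sep = 3.0  # Å chord between bump centres: sparse coverage, so each
    # bump keeps its own crevice ring and roughness rises with every level
    accepted: list[np.ndarray] = []
    attempts = 0
    bump_r = base_radius + bump_scale * radius
    while len(accepted) < n_total:
        attempts += 1
        if attempts > 400 * max(n_total, 1):
            raise StructureError("cannot place non-overlapping bumps; lower bump count")
        v = rng.normal(size=3)
        v = bump_r * v / np.linalg.norm(v)
        if all(np.linalg.norm(v - u) >= min_sep for u in accepted):
            accepted.append(v)
    all_pts = np.vstack([ball] + [np.array(accepted)]) if accepted else ball
    s = Structure(_atoms_from_points(all_pts, radius=radius), source_id=f"blob{bump_levels}")
    truth = {
        "roughness_level": bump_levels,
        "n_core_atoms": len(ball),
        "n_bump_atoms": bumps_per_level * bump_levels,
    }
    return s, truth


def _aligned_axis(tangent: float, spacing: float, shells: int) -> np.ndarray:
    """Symmetric axis grid guaranteed to contain ±tangent, plus outer shells.

    Used so that carved walls have an atom plane exactly tangent to the carve
    box: the void volume then equals the box volume up to small wall scallops.
    """
    vals = np.concatenate(
        [
            np.arange(-tangent, tangent + 1e-9, spacing),
            tangent + spacing * np.arange(0, shells + 1),
            -tangent - spacing * np.arange(1, shells + 1),
        ]
    )
    return np.unique(np.round(vals, 6))


def _box_carve_keep(pts: np.ndarray, lo: np.ndarray, hi: np.ndarray, radius: float) -> np.ndarray:
    """Keep atoms whose sphere does not intersect the open box [lo, hi]."""
    d = np.maximum(lo - pts, 0.0)
    d = np.maximum(d, pts - hi)
    return pts[np.linalg.norm(d, axis=1) >= radius]


def _fibonacci_shell(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_block_cavity(
    shape: str = "box",
    size: float = 5.0,
    cavity_radius: float = 3.0,
    spacing: float = 0.9,
    radius: float = _DEFAULT_RADIUS,
) -> tuple[Structure, dict]:
    """Solid block with a fully enclosed cavity of known analytic volume.

    ``shape="box"`` carves a ``size``³ Å cube out of a dense lattice whose
    atom planes are tangent-aligned to the cavity faces; ``shape="sphere"``
    builds walls from dense concentric Fibonacci shells tangent to a ball of
    ``cavity_radius``.  Either way the cavity has no mouth and its void volume
    equals the analytic value up to small wall scallops.
    """
    if shape == "box":
        half = size / 2.0
        ax = _aligned_axis(half + radius, spacing, shells=2)
        g = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([a.ravel() for a in g])
        pts = _box_carve_keep(pts, np.full(3, -half), np.full(3, half), radius)
        volume = size**3
        surface = 6 * size**2
    elif shape == "sphere":
        shell_gap = 0.8
        shells = []
        for k in range(3):
            r_shell = cavity_radius + radius + k * shell_gap
            n = int(np.ceil(4.0 * np.pi * r_shell**2 / shell_gap**2 * 1.3))
            shells.append(_fibonacci_shell(n, r_shell))
        pts = np.vstack(shells)
        volume = 4.0 / 3.0 * np.pi * cavity_radius**3
        surface = 4.0 * np.pi * cavity_radius**2
    else:
        raise ValueError(shape)
    s = Structure(_atoms_from_points(pts, radius=radius), source_id=f"cavity_{shape}")
    truth = {"volume": float(volume), "cavity_surface": float(surface), "seed_point": (0.0, 0.0, 0.0)}
    return s, truth


def make_groove_complex(
    groove_width: float = 4.5,
    groove_depth: float = 7.5,
    groove_length: float = 19.0,
    n_residues: int = 10,
    peptide_rise: float = 1.5,
    twist_deg: float = 100.0,
    anchor_start: int = 2,
    apolar_fraction: float = 0.6,
    seed: int = 0,
    spacing: float = 1.5,
    radius: float = _DEFAULT_RADIUS,
) -> tuple[Structure, Structure, dict]:
    """Toy receptor groove with an ideal alpha-helical peptide along it.

    The receptor is a slab with a rectangular groove carved into its top face
    (wall-atom surfaces tangent to the groove planes, so the carved volume is
    ``width × depth × length`` analytically).  The peptide is an ideal helix
    (rise 1.5 Å, 100°/residue) riding over the groove mouth: every residue has
    a short CB pseudo-side-chain, and the three *anchor* residues at offsets
    (0, 3, 7) also carry a long CG side chain.  Anchor CG directions get a
    chi-angle-like inward tilt (their lateral component is compressed) so all
    three tips reach below the groove mouth — the way bulky hydrophobic side
    chains anchor into a binding groove while the helix body stays outside.
    By construction only the anchors come within the 5 Å side-chain contact
    cutoff of the receptor; the generator verifies these margins and raises
    on geometric infeasibility.

    Ground truth records: contact pairs at 5 Å (side-chain atoms both sides),
    the anchor triple and its (i, i+3, i+7) pattern, the 4.5 Å lining atom
    set, and the carved groove volume.
    """
    rng = np.random.default_rng(seed)
    half_w, half_l = groove_width / 2.0, groove_length / 2.0
    # groove box open at the top: z from -groove_depth upward
    carve_lo = np.array([-half_l, -half_w, -groove_depth])
    carve_hi = np.array([half_l, half_w, 1000.0])
    # axis grids aligned so wall/floor atom planes are exactly tangent to the
    # groove box; top atom plane at z = -radius (slab surface tangent to z=0)
    xg = _aligned_axis(half_l + radius, spacing, shells=2)
    yg = _aligned_axis(half_w + radius, spacing, shells=2)
    zg = np.unique(
        np.round(
            np.concatenate(
                [
                    -radius - spacing * np.arange(0, int(np.ceil(groove_depth / spacing)) + 1),
                    -(groove_depth + radius) - spacing * np.arange(0, 3),
                ]
            ),
            6,
        )
    )
    g = np.meshgrid(xg, yg, zg, indexing="ij")
    pts = np.column_stack([a.ravel() for a in g])
    pts = _box_carve_keep(pts, carve_lo, carve_hi, radius)
    apolar_pool = ["LEU", "VAL", "PHE", "MET", "ILE"]
    polar_pool = ["SER", "THR", "ASN", "GLN"]
    wall_names = [
        str(rng.choice(apolar_pool if rng.random() < apolar_fraction else polar_pool))
        for _ in range(len(pts))
    ]
    receptor = Structure(
        _atoms_from_points(pts, chain_id="A", atom_name="CB", residue_names=wall_names,
                           radius=radius),
        source_id="groove_receptor",
    )

    # ideal helix along x, axis above the groove centreline
    axis_z = 3.3
    ca_r, cb_r, cg_len = 1.5, 1.0, 5.5
    lateral_squeeze = 0.35  # chi-like inward tilt of anchor side chains
    anchors = {anchor_start, anchor_start + 3, anchor_start + 7}
    if max(anchors) >= n_residues:
        raise StructureError("peptide too short for the anchor triple")
    # phase the anchor face downwards: mean anchor direction = straight down
    rel = np.deg2rad(np.array([0.0, 3 * twist_deg, 7 * twist_deg]))
    mean_dir = np.arctan2(np.sin(rel).mean(), np.cos(rel).mean())
    theta0 = np.deg2rad(270.0) - mean_dir
    pep_atoms: list[Atom] = []
    serial = 1
    for k in range(n_residues):
        theta = theta0 + np.deg2rad(twist_deg) * (k - anchor_start)
        direction = np.array([0.0, np.cos(theta), np.sin(theta)])
        x = peptide_rise * (k - (n_residues - 1) / 2.0)
        base = np.array([x, 0.0, axis_z])
        rname = "LEU" if k in anchors else ("ALA" if rng.random() < apolar_fraction else "SER")
        positions = [("CA", base + ca_r * direction), ("CB", base + cb_r * direction)]
        if k in anchors:
            tilted = np.array([0.0, lateral_squeeze * direction[1], direction[2]])
            tilted /= np.linalg.norm(tilted)
            positions.append(("CG", base + cg_len * tilted))
        for name, pos in positions:
            pep_atoms.append(Atom(serial, name, "C", rname, k + 1, "P", pos, radius=radius))
            serial += 1
    peptide = Structure(pep_atoms, source_id="groove_peptide")

    truth = _groove_truth(receptor, peptide, anchors, groove_width, groove_depth, groove_length)
    return receptor, peptide, truth


def _groove_truth(receptor, peptide, anchors, width, depth, length) -> dict:
    """Brute-force O(n·m) distance audit of the constructed complex."""
    rc, pc = receptor.coords(), peptide.coords()
    d = np.linalg.norm(rc[:, None, :] - pc[None, :, :], axis=2)

    side_r = np.array([a.is_sidechain for a in receptor.atoms])
    side_p = np.array([a.is_sidechain for a in peptide.atoms])
    sc = d[np.ix_(side_r, side_p)]
    ridx = np.flatnonzero(side_r)
    pidx = np.flatnonzero(side_p)
    contact_pairs = set()
    contact_pep_residues = set()
    for i, j in zip(*np.where(sc <= 5.0)):
        ra, pa = receptor.atoms[ridx[i]], peptide.atoms[pidx[j]]
        contact_pairs.add((ra.residue_key, pa.residue_key))
        contact_pep_residues.add(pa.residue_number)

    anchor_numbers = tuple(sorted(k + 1 for k in anchors))
    if set(anchor_numbers) != contact_pep_residues:
        raise StructureError(
            f"groove construction infeasible: contacting peptide residues "
            f"{sorted(contact_pep_residues)} != anchors {anchor_numbers}"
        )
    # margins: every non-anchor side-chain atom clearly beyond the cutoff
    non_anchor = [j for j in range(len(pidx))
                  if peptide.atoms[pidx[j]].residue_number not in anchor_numbers]
    if non_anchor and sc[:, non_anchor].min() < 5.2:
        raise StructureError("groove construction infeasible: non-anchor margin < 0.2 Å")

    lining = np.flatnonzero(d.min(axis=1) <= 4.5)
    if lining.size == 0:
        raise StructureError("groove construction infeasible: empty lining")
    return {
        "contact_pairs": contact_pairs,
        "contact_peptide_residues": contact_pep_residues,
        "anchor_triple": anchor_numbers,
        "anchor_pattern": "i,i+3,i+7",
        "lining_indices": set(int(i) for i in lining),
        "lining_keys": {receptor.atoms[int(i)].residue_key for i in lining},
        "carved_volume": float(width * depth * length),
        "groove_mouth_halfwidth": width / 2.0,
    }


def make_rough_walled_groove(
    n_bumps: int = 24,
    seed: int = 3,
    groove_width: float = 4.5,
    groove_depth: float = 7.5,
    groove_length: float = 19.0,
    radius: float = _DEFAULT_RADIUS,
) -> tuple[Structure, np.ndarray, dict]:
    """Groove receptor whose cavity walls carry bumps while the faces stay smooth.

    Emulates the situation where a binding cavity is rougher than the rest of
    the protein surface: bump atoms protrude ~1.4 Å from the groove walls into
    the channel, carving probe-scale crevices confined to the cavity.  Returns
    the structure, the cavity-lining atom indices (tangent wall/floor atoms
    plus the bumps) and a ground-truth record stating the expected ordering
    (local dimension above global).
    """
    receptor, _, _ = make_groove_complex(
        seed=seed, groove_width=groove_width, groove_depth=groove_depth,
        groove_length=groove_length, radius=radius,
    )
    half_w, half_l = groove_width / 2.0, groove_length / 2.0
    rng = np.random.default_rng(seed)
    bumps = []
    for _ in range(n_bumps):
        side = rng.choice([-1.0, 1.0])
        x = rng.uniform(-half_l + 1.0, half_l - 1.0)
        z = rng.uniform(-groove_depth + 1.0, -1.0)
        bumps.append([x, side * (half_w + radius - 1.4), z])
    atoms = receptor.atoms + _atoms_from_points(
        np.asarray(bumps), chain_id="A", residue_names=["LEU"] * n_bumps,
        radius=radius, start_serial=len(receptor.atoms) + 1,
    )
    rough = Structure(atoms, source_id="rough_groove")

    c = rough.coords()
    lo = np.array([-half_l, -half_w, -groove_depth])
    hi = np.array([half_l, half_w, 1000.0])
    d = np.maximum(np.maximum(lo - c, 0.0), c - hi)
    lining = np.flatnonzero(np.linalg.norm(d, axis=1) <= radius + 1e-6)
    truth = {"n_bumps": n_bumps, "expected": "local dimension exceeds global"}
    return rough, lining, truth


def generate(spec: SyntheticSpec):
    """Dispatch a :class:`SyntheticSpec` to its generator."""
    p = dict(spec.params)
    if spec.kind == "sphere":
        return make_sphere(**p)
    if spec.kind == "pair":
        return make_sphere_pair(**p)
    if spec.kind == "slab":
        return make_slab(**p)
    if spec.kind == "rough_blob":
        return make_rough_blob(seed=spec.seed, **p)
    if spec.kind == "block_cavity":
        return make_block_cavity(**p)
    if spec.kind == "groove_complex":
        return make_groove_complex(seed=spec.seed, **p)
    raise ValueError(f"unknown synthetic kind {spec.kind!r}")
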