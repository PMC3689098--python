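# Methods

This note documents the models and numerical procedures implemented in
`helixsurf`, the parameters that matter, the synthetic structures the tests
run on, and the limits of what those tests demonstrate.

## Solvent-accessible surface area

SASA is defined as the area swept by the centre of a spherical probe of
radius R rolled over the van der Waals surface; equivalently, the exposed
area of each atom's sphere expanded to r_i + R. The engine is a
Shrake–Rupley quadrature: each expanded sphere is sampled with a Fibonacci
(golden-spiral) lattice of `n_points` directions, a point is buried when it
falls strictly inside any neighbour's expanded sphere, and

    area_i = (exposed points / n_points) · 4π (r_i + R)².

Two implementation details matter:

* **No randomness.** The lattice is closed-form, so repeated runs are
  bitwise identical and the area-vs-probe series feeding the fractal fit is
  exactly reproducible. Translation invariance is exact.
* **Per-atom lattice orientation.** Each atom's lattice is spun by a fixed
  rotation derived from its index. On structures with many geometrically
  identical atoms (the crystalline test fixtures), an unrotated lattice makes
  every atom alias identically, and summed areas of small subsets inherit a
  correlated quadrature bias — the fitted dimension of a flat lattice face
  then oscillates with `n_points` instead of converging. With the
  index-derived orientations the quadrature error decorrelates across atoms;
  the face dimension is stable (±0.01) from 240 to 1920 points. Results
  remain deterministic and translation-invariant; rotation invariance of
  totals is approximate (the lattice frame is fixed in space), held to ~1 %
  at 960 points and tested at that tolerance.

Neighbour candidates come from a k-d tree at the exact occlusion cutoff
r_i + r_j + 2R, so the result equals a brute-force all-pairs scan; occluders
are processed nearest-first in chunks with early exit once every sample
point is buried, which is what keeps dense lattice fixtures (~300 neighbours
per atom) fast.

Accuracy: against the closed-form one/two-sphere oracle
(`analytic_sasa_spheres`, spherical-cap geometry, itself cross-checked by
Monte-Carlo sampling), the worst error over a 40-geometry battery —
disjoint, tangent, overlapping, deeply overlapping and contained spheres —
is 0.46 % at the default 960 points.

Defaults: `n_points = 960` (classic density; meets the 0.5 % target),
element radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å (overridable per
atom or via a YAML radius set). Hydrogens, waters and heteroatoms are
excluded at parse time: the analysis is heavy-atom, polypeptide-only. For
multi-model (NMR) entries model 1 is used; alternate locations resolve to
the highest-occupancy conformer.

## Surface fractal dimension

Probing the surface with increasing R low-passes texture finer than R, so a
self-similar surface obeys SA(R) ∝ R^(2−D). D is estimated by unweighted
ordinary least squares of ln SA on ln R over the probe ladder
{1.0, 1.2, 1.4, 1.6, 1.8, 2.0} Å (configurable): `D = 2 − slope`, with the
OLS standard error of the slope reported as the error on D, and r² computed
from residuals (an exactly flat series — D = 2 — scores r² = 1 rather than
0/0). On noiseless power-law input the fit recovers D to better than 1e−9.

The **global** dimension D_S uses the whole receptor's total area. The
**local** dimension D_L sums per-atom SASA over the pocket-lining subset,
computed *in the context of the complete peptide-stripped structure*, not an
excised fragment — occlusion by the rest of the protein is part of the
pocket's texture. Non-positive areas are an error (log undefined).

Two caveats the synthetic fixtures make explicit:

* **Finite-size bias.** Any small convex body has dSA/dR > 0 (edge and
  corner areas grow with R), which depresses the fitted D below 2 — the
  20×20×3 test slab fits D ≈ 1.77 as a whole, while its interior face fits
  D ≈ 2.03. The smooth-limit check therefore reads the interior-face subset;
  whole-body dimensions of small objects should be compared only against
  each other.
* **Concavity alone is not roughness.** Per-atom SASA grows like (r+R)²
  even at fixed solid angle, so a smooth-walled groove's lining does not fit
  D_L > D_S. The ordering flips only when the cavity carries probe-scale
  texture, which is exactly what `make_rough_walled_groove` constructs
  (D_S ≈ 1.95 vs D_L ≈ 2.90) — and what elevated D_L on real binding
  pockets is reporting.

## Interface contacts and helix faces

A receptor residue and a peptide residue are in contact when the minimum
Euclidean distance over qualifying atom pairs is ≤ the cutoff (default
5.0 Å, boundary inclusive). By default only side-chain atoms qualify on
*both* sides; glycine contributes its CA so it can register contacts at all.
Residues are keyed by (chain, author number, insertion code). The k-d-tree
pair query is validated against an all-pairs scan.

Helix-face extraction lists every triple of contacting peptide residues with
number offsets (0, 3, 7) or (0, 4, 7) — the two arrangements that place
three side chains on one face of an ideal helix (100°/residue). All valid
triples are reported; when a single candidate face is wanted, the pipeline
consumer can rank triples by summed hydrophobicity. The hot-spot tally
counts, for each receptor residue (by number, across complexes of the same
protein), how many complexes it contacts.

## Pocket definition and descriptors

The pocket is anchored on the known ligand rather than found by blind
detection: lining atoms are receptor atoms within `lining_cutoff`
(default 4.5 Å) of any peptide atom, and the former peptide atom positions
seed the cavity.

**Volume** is measured on a regular grid (`grid_spacing` ∈ [0.25, 1.0] Å,
default 0.5): a voxel belongs to the pocket when its centre is (i) outside
every receptor atom (closed balls), (ii) not bulk solvent, (iii) within
`envelope_radius` (default 8 Å) of a seed point, and (iv) flood-fill
connected (face connectivity) to a seed voxel. Bulk solvent is the
boundary-connected region where a ball of radius `mouth_probe` (default
3.0 Å) fits, dilated back by that radius — space reachable only through
openings wider than the mouth probe is outside, which is what separates an
open groove from open sky. The grid origin is offset by `spacing/π` so that
voxel centres never align with a flat atom-tangent plane; without the offset
a degenerate alignment overcounts exactly one voxel shell. Validation: an
enclosed 5×5×5 Å carved cube reads 125.0 ų at 0.5 Å spacing; an enclosed
spherical cavity of radius 3 Å converges 120 → 116.6 → 114.9 ų as spacing
drops 1.0 → 0.25 (analytic 113.1, the residual is wall scallop); the open
synthetic groove reads within 8 % of its carved volume.

**Hydrophobicity score** is the arithmetic mean over lining residues (each
once) of a per-residue scale — default the Monera alpha-helical
hydrophobicity scale (PHE 100 … ASP −55), the convention of pocket-profiling
tools; Kyte–Doolittle ships as an alternate. Unknown residues contribute a
configurable default (0) with a warning.

**Local hydrophobic density** is the mean number of *other* apolar lining
atoms within `neighbor_cutoff` (default 4.5 Å) per apolar lining atom, where
apolar lining atoms are C/S atoms in {ALA, VAL, LEU, ILE, MET, PHE, TRP,
PRO, CYS, GLY}; 0 when the lining has no apolar atoms. This is a
fixed-radius neighbour count, not an alpha-sphere decomposition: absolute
values are on their own scale and only comparisons between pockets computed
the same way are meaningful.

## Sequence identity

Alignment is optimal global Needleman–Wunsch with affine gaps via
Biopython's `PairwiseAligner`: BLOSUM62, gap open 10, extend 0.5 (the era
defaults of classic alignment tools; the first gapped position costs the
open penalty). Optimality is tested against exhaustive enumeration of all
alignments for short sequences. Percent identity = identical columns /
mutually aligned (non-gap-pair) columns, the most common convention; a
shorter-sequence denominator is available. Binding-area identity restricts
to alignment columns whose position in either sequence is an interface
position (union through the alignment), with the same denominator rule.
Low-identity pairs (< ~10 %) are alignment-parameter-sensitive and should
not be over-interpreted.

## Synthetic structures: what they emulate and what they don't

All generators are deterministic given their parameters and seed, and carry
ground truth sufficient to check every downstream stage:

* **Spheres / pairs** — closed-form SASA at any probe.
* **Slab** (20×20×3 pseudo-atoms, 1.8 Å spacing, r = 1.7 Å) — the smooth
  limit; ground truth records the interior-face subset on which D ≈ 2 holds.
* **Rough blob** — a lattice ball (radius 9 Å) plus `15 × level` protruding
  bump atoms at seeded minimum-separation (3.0 Å) sites, nested across
  levels. Sparse placement keeps every level in the regime where added bumps
  add crevices; the fitted D ordering level 0 < 1 < 2 < 3 is then strict
  (verified for several seeds, gaps ≈ 0.02). Dense placement would saturate:
  a fully bump-covered ball smooths out again.
* **Block cavities** — enclosed cube (tangent-aligned lattice walls) and
  sphere (tangent Fibonacci-shell walls) with analytic volumes.
* **Groove complex** — a slab with a rectangular groove (4.5 × 7.5 × 19 Å,
  walls exactly tangent to the carve box, so the carved volume is the
  analytic product) and an ideal helix (rise 1.5 Å, 100°/residue) riding
  over the mouth. The three anchor residues at offsets (0, 3, 7) carry long
  side chains whose lateral component is compressed (a chi-angle-like inward
  tilt) so all three tips reach below the mouth — bulky side chains
  anchoring into a groove while the helix body stays outside. The generator
  brute-force-audits its own geometry (anchors contact at ≤ 5 Å, every
  non-anchor side-chain atom ≥ 5.2 Å, lining non-empty) and raises on
  infeasibility, so ground truth is a property of the construction.
* **Rough-walled groove** — the same receptor with bump atoms protruding
  ~1.4 Å from the cavity walls only: the fixture for "pocket rougher than
  surface".

What passing these tests shows: the geometry, counting and fitting machinery
are correct against analytic ground truth, and the fractal estimator
recovers ordinal roughness. What they do not show: agreement with any
particular third-party surface engine on real proteins. Crystal structures
have irregular packing, heteroatoms, missing residues and real side-chain
chemistry; the reference-data tests (which require fetching the published
PDB entries) are the bridge to that regime, with tolerances (±0.05 on D_S,
±0.15 on D_L) acknowledging that different SASA engines and radius sets
shift absolute dimensions.

## Numerical choices and degenerate inputs

* Probe ladder {1.0 … 2.0 Å}: the water-size texture window; ≥ 3 points are
  required for any fit.
* Occupancy grids use closed balls (boundary centre counts occupied);
  clearance and dilation use Euclidean distance transforms at the grid
  resolution.
* Contact and lining thresholds compare with ≤ (boundary inclusive).
* Alignment traceback ties resolve to the aligner's first reported
  alignment, deterministic for fixed inputs.
* Empty structures, empty subsets, empty contact/lining sets, non-positive
  areas, all-gap selections and unresolvable radii raise typed errors; the
  pipeline wraps stage failures with the stage name (`parse`, `split`,
  `contacts`, `pocket`, `fractal`), and descriptor-stage failures downgrade
  to report warnings with None fields so a batch row survives.
* Batch processing isolates per-row failures and reports them in the
  summary; re-running any analysis with the same config and inputs is
  byte-identical (no RNG on the analysis path).

## Problem sizes

Defaults were chosen so the full synthetic validation runs in a few minutes
on one CPU: 960 sphere points, ~1200–1400-atom lattice fixtures, four blob
levels at ~515–560 atoms, 0.5 Å pocket grids. All are configuration
parameters, and the convergence behaviour under refinement (more points,
finer grids) is part of the test suite.

## Known limitations

* No molecular (Connolly) surface; SASA only.
* Pocket volume is a grid flood-fill, not an alpha-shape construction;
  absolute volumes depend on the mouth-probe and envelope conventions.
* Hydrophobic density is a fixed-radius count (see above).
* D_L is defined on the SASA of lining atoms; other tools may measure pocket
  molecular surfaces, shifting absolute D_L.
* Pairwise alignment only; no multiple-sequence alignment or guide trees.
* mmCIF, symmetry mates and assemblies are out of scope; author numbering is
  used as-is.
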