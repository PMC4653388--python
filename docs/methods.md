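# Methods

This note records the models, conventions and numerical choices behind
cleftdock, and what its synthetic test systems do and do not demonstrate.

## Gap-sphere cleft detection

For each candidate atom pair the sphere center is fixed at the pair
midpoint and only the radius shrinks when a third atom clips it:
r = min(r_max, min_k(|c − x_k| − vdW_k)), kept when r ≥ r_min. An
alternative lineage of this algorithm relocates clipped centers away from
the intruding atom; the fixed-midpoint convention was chosen because it is
simpler, deterministic and makes every emitted sphere's non-penetration
property (|c − x_k| ≥ r + vdW_k for all k, tolerance 1e-6 Å) directly
checkable. The practical consequence: a sphere only "fills the gap" of its
generating pair when the pair is at most 2·(r_max + vdW) apart, which is
exactly the pair-enumeration cutoff. Large buried voids therefore need an
r_max on the order of their interior radius — the radius window is a user
parameter precisely for this reason (the hollow-shell test system with a
6.2 Å interior radius is detected with r_max = 7 Å; typical protein work
uses the defaults r_min = 1.5 Å, r_max = 4.0 Å, bracketing water-sized
probes up to wide grooves).

Overlap is strict (|c₁ − c₂| < r₁ + r₂), so tangent spheres never merge —
a deterministic tie rule. Component finding runs as a frontier BFS with
chunked distance blocks rather than an explicit pair list: cavity sphere
sets are near-cliques and a pair list is quadratic in memory. Clefts are
ranked by Σ 4⁄3·π·r³ with overlaps double-counted; this is deliberately a
*rough* sort (cheap, deterministic) — the grid volume is the accurate
measurement. Ties break by sphere count, then by the lowest generating
atom serial.

Van der Waals radii come from a packaged element table
(`cleftdock/data/radii.json`: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80, halogens per common literature values, 1.70 fallback). The table
is one editable data file on purpose; no radii are hard-coded elsewhere.
Nucleic-acid targets use the same table.

## Volume measurement and refinement

Volumes are voxel counts: a voxel's center must lie inside ≥ 1 cleft
sphere and outside every atom's vdW sphere; V = N·h³. Voxel-center
membership (no partial occupancy) is the simplest convention with provable
convergence — for a lone sphere of radius r the relative error falls below
2% by h = r/14, and in practice the default h = 0.5 Å measures the
hollow-shell cavity to within 1% of its h = 0.25 Å value. The lattice is
snapped to integer multiples of h so results do not drift with the
bounding box. Spheres wholly contained in a larger sphere are pruned first
(the union, hence the volume, is unchanged).

Refinement only removes spheres — raising the radius threshold or cropping
around a point — so grid volume at fixed spacing is monotone
non-increasing under any refinement. Re-thresholding can disconnect a
cleft; the largest surviving component is returned because a binding-site
definition must be a single region (the rest is recoverable via
`split_components`). Lowering the threshold below the detection r_min is
refused: those spheres were never generated.

Lining residues are those owning an atom within
vdW + sphere radius + margin of some cleft sphere center; the default
margin of 1.0 Å is typical contact slop and is configurable. This list is
what a user picks flexible side chains from.

## Ligand model and pose reconstruction

Bonds come verbatim from an SDF V2000 bond block (via RDKit) or, for PDB
input, from distances (bonded iff d < 1.3 × covalent-radius sum).
Rotatable bonds are single-order bridge (non-ring) bonds with a heavy
substituent on both sides; ring bonds are identified as non-bridge edges.
The automatic anchor is the heavy atom closest to the heavy-atom centroid
— deterministic, and it minimizes the lever arm of the orientation genes —
with ties to the lowest atom index; callers may override it.

Poses rebuild from DOF values in a fixed order: each flexible dihedral is
set to its absolute target value by rotating the subtree distal to the
bond (reference atoms: the lowest-index neighbor on each side), then the
whole molecule is rotated by intrinsic Z-Y-X Euler angles about the
anchor, then the anchor is translated. Because each bond's subtree
rotation leaves every other flexible bond's dihedral invariant, the order
of dihedral application does not matter, and bond lengths and angles are
preserved to 1e-6 Å by construction. Angles normalize to [0, 360)
(values within one ulp of 360 snap to 0 — `fmod` of a tiny negative
rounds to exactly 360.0).

RMSD is the plain root-mean-square deviation of matched heavy atoms in the
shared target frame — no superposition, no symmetry (automorphism)
correction. For symmetric ligands this overestimates pose error; a known
limitation.

## Scoring

The pair potential is a documented surrogate, not a fitted energy
function. For a ligand/target pair at distance d, d₀ = vdW_i + vdW_j,
width s (`contact_scale`, default 1.0 Å):

* clash: (1 − permeability)·((d₀ − d)/s)² for d < d₀, zero beyond;
* attraction: −exp(−((d − d₀)/s)²) at every distance.

The Gaussian attraction is symmetric about d₀ and equals −1 at touch, so
the pair term is continuous and smooth through d₀ (a piecewise "attraction
only beyond contact" variant would jump by 1 at d₀ and was rejected for
that reason). Permeability ∈ [0, 1] scales only the clash term: 0 = rigid
spheres, 1 = fully permeable. Pairs beyond 8 Å contribute nothing. Lower
is better; all quantities dimensionless.

HET groups in the target are scored by default, waters are not; both are
toggles applied by filtering the target before scoring (scoring a
pre-stripped structure is exactly equivalent). Implicit solvent is the
exclusion-force option: + solvent_weight per ligand heavy atom with no
target atom within 6 Å, a burial reward. A typed pairwise solvent term
("solvent as an extra atom type") is a registered strategy name that
raises NotImplementedError — it needs a per-type parameter table this
package does not define, and silently approximating it would be worse
than refusing.

Distance constraints are harmonic, weight·(d − d_target)², summed; a
tight constraint at a covalent bond length with a large weight emulates
covalent docking. Hydrogen bonds are purely geometric — ligand N/O/S to
target N/O with heavy-atom distance in [2.4, 3.5] Å — because hydrogens
are not required anywhere in the pipeline; without hydrogens no angular
criterion is defensible.

## Genetic algorithm

Integer chromosome: [lattice index | 3 × orientation | one per flexible
dihedral | one per flexible side chain]. The translation lattice is the
set of spacing-multiples inside the union of the selected clefts' spheres
(deterministic x→y→z order), so every pose's anchor provably stays in the
search region. Defaults: lattice 0.5 Å, rotation and dihedral steps 10°.

Operators are fixed for reproducibility: tournament selection of size 2,
single-point crossover (default probability 0.9), per-gene uniform reset
mutation (default 0.025), elitism of 1 (the elite is exempt from
mutation, making the best fitness monotone). All randomness flows from one
seeded PCG64 generator whose state is serialized with the population, the
generation counter and the archive of evaluated genomes, so
run(G) + continue(G) is bit-identical to run(2G). A continuation is
refused unless the SHA-256 digest of every non-GA input (target and ligand
content, lattice, scoring parameters, constraints, flexibility choices,
steps, reference) matches; only the GA parameters may change, and a
changed population size resamples from the saved population with a
warning. "Pause" keeps everything for resumption, "stop" finalizes
results and keeps the population, "abort" discards results.

Results are the top-N (default 10) unique genomes ever evaluated, ranked
by fitness with ties by first-found generation; each is reported with its
pose, score, RMSD to the reference (when given) and hydrogen bonds.
Side-chain flexibility uses an on-the-fly rotamer set — each chi axis
found by walking the side chain outward from CA–CB, rotated by −60°, +60°
or 180° relative to the input conformation, full cross-product capped at
81, with the input conformation always rotamer 0. This is an honest,
dependency-free stand-in for a fitted rotamer library, not a substitute
for one.

## Synthetic study systems

All tests run on generated structures; nothing is downloaded.

* **Atom pair** (two vdW-1.5 atoms 10 Å apart): the midpoint sphere has
  the closed-form radius 3.5 Å; at 4 Å separation no sphere survives.
* **Hollow shell** (Fibonacci lattice on an 8 Å sphere, spacing 1.8 Å,
  vdW 1.8 Å, 248 atoms): encloses one buried cavity of interior radius
  ≈ 6.2 Å. Generation refuses spacing ≥ 2·vdW (a leaky shell).
* **Toy ligand** (7 heavy atoms, one 3-ring, two exocyclic arms): exactly
  two rotatable bonds by the stated rules.
* **Toy pocket**: a rigid five-atom cross-shaped chiral ligand (C anchor,
  short O arm, long C–N arm, out-of-plane S knob) planted inside a
  46-atom complementary wall built at a 0.2 Å standoff from its vdW
  surface, open only through a narrow mouth; a wall N and O provide polar
  contacts at 2.9 and 3.1 Å, and two far-face atoms must never appear as
  lining residues. The planted pose is **certified at generation time**:
  exhaustive enumeration over the search lattice × orientation grid shows
  it scores strictly better than any pose whose anchor lies ≥ 2 Å away,
  and on the fixture's own search grid (0.75 Å lattice, 15° rotation
  step) the planted genome is the exact global optimum. The fixture
  carries its certified search settings (`ToyPocket.docking`): lattice
  0.75 Å, 15° steps, crossover 0.8, mutation 0.18 — the mutation rate
  sits near the 1/L-per-gene heuristic for its 7-gene genome. With 200
  chromosomes × 50 generations these settings re-find the planted pose
  within 1.5 Å RMSD in ≈ 98% of seeds (measured over several hundred
  held-out seeds).

What passing these tests shows: the geometry, scoring, encoding and
search machinery are internally correct and deterministic, and the GA can
solve a pocket whose global optimum is known by enumeration. What they do
not show: performance on real proteins. The fixtures have no hydrogens,
no chemistry beyond vdW radii, walls denser and more regular than protein
surfaces, and a surrogate score with no fitted parameters — so recovery
rates and volumes here say nothing quantitative about docking accuracy on
experimental structures.

## Numerical conventions and degenerate inputs

* Sphere/atom clearance tolerance 1e-6 Å; overlap and tangency strict.
* Voxel membership: center-in-sphere with ≤ (closed ball).
* Only MODEL 1 and altloc ''/'A' of a PDB are read; waters are
  HOH/WAT/DOD by residue name; every water is also HET.
* Sphere files store the radius in the occupancy column (2 decimals);
  centers round-trip at PDB precision (3 decimals).
* Empty refinements return an empty cleft (volume 0) rather than failing;
  an empty search lattice is a configuration error.
* Session files serialize floats via `float.hex` for lossless
  round-trips; the RNG state is stored verbatim.
* Fitness evaluation is vectorized over the population on the rigid path
  (no flexible bonds or side chains) and per-chromosome otherwise; both
  paths agree to 1e-12 relative and the choice never affects results.

## Known limitations

* No symmetry-corrected RMSD; no hydrogen placement or protonation; no
  angular hydrogen-bond criterion.
* The surrogate score has no fitted parameters and no typed solvent term;
  it is a placeholder with the documented knobs, pluggable for a real
  parameterization.
* Fixed-midpoint spheres under-fill cavities much larger than r_max
  unless the radius window is widened (see above).
* mmCIF, assemblies, SMILES-to-3D embedding and GUI visualization are out
  of scope; SDF input requires RDKit.
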