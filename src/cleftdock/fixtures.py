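"""Deterministic synthetic structures for testing and demonstration.

Every generator is a pure function of its parameters (and seed), producing
toy systems with known ground truth:

* :func:`make_pair` — two isolated atoms whose midpoint gap sphere has a
  closed-form radius.
* :func:`make_shell` — a gap-tight Fibonacci-lattice shell of atoms
  enclosing a buried cavity of known approximate interior radius.
* :func:`make_toy_ligand` — a 7-heavy-atom molecule with one ring and
  exactly two rotatable exocyclic bonds.
* :func:`make_toy_pocket` — a concave 14-atom wall with labeled wall and
  far-face residues, a rigid 3-atom ligand planted in a pose engineered to
  be the optimum of the surrogate score (certifiable by exhaustive
  enumeration via :func:`certify_planted_optimum`), and two polar contacts
  at 2.9 and 3.1 Å for hydrogen-bond tests.
* :func:`make_flex_residue` — a serine-like residue for side-chain rotamer
  tests.

These fixtures exercise the geometry and search machinery; they do not
emulate real protein shapes, chemistry or energetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FixtureError
from .ligand_model import LigandTopology, PoseDOF, build_topology, identity_dof
from .structure_io import Atom, Structure, vdw_radius

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _atom(serial, name, element, res_name, res_seq, coords, chain="A", vdw=None,
          is_het=False, is_water=False) -> Atom:
    return Atom(
        serial=serial, name=name, element=element, res_name=res_name,
        res_seq=res_seq, chain_id=chain, coords=np.asarray(coords, float),
        vdw_radius=vdw if vdw is not None else vdw_radius(element),
        is_het=is_het, is_water=is_water,
    )


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n points quasi-uniformly covering a sphere of the given radius."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = GOLDEN_ANGLE * i
    r_xy = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])


def shell_atom_count(radius: float, spacing: float) -> int:
    """Closed-form atom budget: surface area / spacing², rounded."""
    return int(round(4.0 * np.pi * radius**2 / spacing**2))


def make_pair(separation: float = 10.0, vdw: float = 1.5) -> Structure:
    """Two atoms on the x-axis; the midpoint gap sphere has radius
    min(r_max, separation/2 − vdw) in an otherwise empty structure."""
    atoms = [
        _atom(1, "C1", "C", "PRA", 1, (0.0, 0.0, 0.0), vdw=vdw),
        _atom(2, "C2", "C", "PRB", 2, (separation, 0.0, 0.0), vdw=vdw),
    ]
    return Structure(atoms, id="pair")


def make_shell(radius: float = 8.0, spacing: float = 1.8, vdw: float = 1.8,
               center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Structure:
    """Gap-tight atom shell enclosing a buried cavity.

    Atoms sit exactly on the sphere of the given radius around ``center`` on
    a Fibonacci lattice; the enclosed cavity has approximate interior radius
    (radius − vdw). Raises :class:`FixtureError` when the spacing cannot
    produce a tight shell (spacing must stay below 2·vdw).
    """
    if spacing >= 2.0 * vdw:
        raise FixtureError(
            f"shell would leak: spacing {spacing} ≥ 2·vdw = {2 * vdw}"
        )
    n = shell_atom_count(radius, spacing)
    pts = fibonacci_sphere(n, radius) + np.asarray(center, float)
    atoms = [
        _atom(i + 1, "C", "C", "SHL", i + 1, p, vdw=vdw) for i, p in enumerate(pts)
    ]
    return Structure(atoms, id="shell")


_TOY_LIGAND_COORDS = {
    # cyclopropane ring (bond 1.50) with two exocyclic chains
    "C1": (0.750, 0.000, 0.000),
    "C2": (-0.750, 0.000, 0.000),
    "C3": (0.000, 1.299, 0.000),
    "C4": (1.750, -1.100, 0.200),   # bonded to C1
    "O5": (3.050, -0.800, 0.500),   # bonded to C4 (heavy substituent)
    "C6": (-1.750, -1.100, -0.200),  # bonded to C2
    "N7": (-2.950, -0.450, -0.500),  # bonded to C6 (heavy substituent)
}


def make_toy_ligand() -> LigandTopology:
    """Seven heavy atoms, one three-membered ring, two rotatable bonds
    (C1–C4 and C2–C6; the distal C4–O5 / C6–N7 bonds are terminal)."""
    atoms = [
        _atom(i + 1, name, name[0], "LIG", 1, xyz, chain="L", is_het=True)
        for i, (name, xyz) in enumerate(_TOY_LIGAND_COORDS.items())
    ]
    return build_topology(Structure(atoms, id="toy_ligand"))


@dataclass
class ToyPocket:
    """A pocket fixture with its ground truth.

    ``docking`` holds the search settings the fixture was certified with
    (lattice spacing, rotation step, GA crossover/mutation rates, rigid
    ligand); re-docking at these settings makes the planted pose an exact
    on-grid genome and the enumerated optimum of the surrogate score.
    """

    target: Structure
    ligand: LigandTopology
    planted: PoseDOF
    wall_residues: set[tuple[str, int]]
    far_residues: set[tuple[str, int]]
    polar_contacts: list[tuple[int, int, float]]  # (ligand idx, target serial, Å)
    docking: dict = None


def _complementary_wall(
    lig_xyz: np.ndarray, lig_vdw: np.ndarray, seed: int,
    n_dir: int = 26, z_open: float = 0.45, wall_vdw: float = 1.7,
    gap: float = 0.2,
) -> np.ndarray:
    """Wall carbons at near vdW contact with the planted ligand.

    Directions come from a Fibonacci sphere with a cap removed around +z
    (the pocket opening); along each direction the wall atom is pushed out
    until it just touches the ligand's contact surface
    (min over ligand atoms of |x − x_k| − (vdW_k + wall vdW) = 0) and then
    backed off by a small uniform ``gap``, making the planted pose a dense
    set of near-touch contacts — the enumerable optimum of the surrogate
    score — while leaving the cavity enough clearance to host the gap
    spheres that define the binding site.
    """
    rng = np.random.default_rng(seed)
    dirs = fibonacci_sphere(n_dir, 1.0)
    dirs = dirs[dirs[:, 2] < z_open]
    # small angular jitter breaks accidental symmetry between seeds
    dirs = dirs + rng.normal(scale=0.03, size=dirs.shape)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wall = []
    for u in dirs:
        lo, hi = 1.0, 9.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            clearance = np.min(
                np.linalg.norm(mid * u - lig_xyz, axis=1) - (lig_vdw + wall_vdw)
            )
            if clearance < 0:
                lo = mid
            else:
                hi = mid
        wall.append((hi + gap) * u)
    return np.array(wall)


def make_toy_pocket(seed: int = 0) -> ToyPocket:
    """Near-enclosed pocket + rigid 5-atom ligand planted in its optimal pose.

    The cross-shaped ligand (C anchor; a short O arm; a long C–N arm; an
    out-of-plane S knob) sits in a shape-complementary cavity whose carbons
    line its vdW surface at a 0.2 Å standoff, open only through a narrow
    mouth toward +z; a wall nitrogen and oxygen form polar contacts of
    2.9 Å (ligand O → wall N) and 3.1 Å (ligand N → wall O). Two far-face
    residues 15 Å away must never appear among the cleft's lining residues.
    """
    # deliberately asymmetric, cross-shaped and chiral: arms of very
    # different lengths plus an out-of-plane S knob mean a misoriented
    # ligand drives an arm into the complementary wall — the planted basin
    # is the only deep one
    lig_c = np.array([0.0, 0.0, 0.0])
    lig_o = np.array([1.20, 0.0, 0.0])
    lig_c2 = np.array([-0.95, 1.65, 0.0])
    lig_n = np.array([-1.70, 2.95, 0.0])
    lig_s = np.array([-0.60, -0.80, 1.25])
    lig_xyz = np.array([lig_c, lig_o, lig_c2, lig_n, lig_s])
    lig_vdw = np.array([1.7, 1.52, 1.7, 1.55, 1.8])

    polar_n = lig_o + np.array([2.9, 0.0, 0.0])  # 2.9 Å contact
    u = lig_n / np.linalg.norm(lig_n)
    polar_o = lig_n + 3.1 * u  # 3.1 Å contact, radially outward
    wall_c = _complementary_wall(lig_xyz, lig_vdw, seed, n_dir=56, z_open=0.8)
    # polar atoms replace any generic wall carbon crowding their site
    wall_c = np.array([
        w for w in wall_c
        if np.linalg.norm(w - polar_n) >= 2.4 and np.linalg.norm(w - polar_o) >= 2.4
    ])

    atoms = []
    serial = 1
    for p in wall_c:
        atoms.append(_atom(serial, "C", "C", "WAL", serial, p))
        serial += 1
    n_serial = serial
    atoms.append(_atom(serial, "N", "N", "WAL", serial, polar_n))
    serial += 1
    o_serial = serial
    atoms.append(_atom(serial, "O", "O", "WAL", serial, polar_o))
    serial += 1
    wall_residues = {("A", a.res_seq) for a in atoms}
    far_residues = set()
    for p in ((15.0, 0.0, 5.0), (15.0, 2.0, 5.0)):
        atoms.append(_atom(serial, "C", "C", "FAR", serial, p))
        far_residues.add(("A", serial))
        serial += 1
    target = Structure(atoms, id="toy_pocket")

    lig_atoms = [
        _atom(1, "C1", "C", "LIG", 1, lig_c, chain="L", is_het=True),
        _atom(2, "O2", "O", "LIG", 1, lig_o, chain="L", is_het=True),
        _atom(3, "C3", "C", "LIG", 1, lig_c2, chain="L", is_het=True),
        _atom(4, "N4", "N", "LIG", 1, lig_n, chain="L", is_het=True),
        _atom(5, "S5", "S", "LIG", 1, lig_s, chain="L", is_het=True),
    ]
    ligand = build_topology(Structure(lig_atoms, id="toy_pocket_ligand"))
    # the pocket fixture docks rigidly: the C1–C3 arm stays planted
    planted = identity_dof(ligand, flexible=[])
    return ToyPocket(
        target=target,
        ligand=ligand,
        planted=planted,
        wall_residues=wall_residues,
        far_residues=far_residues,
        polar_contacts=[(1, n_serial, 2.9), (3, o_serial, 3.1)],
        docking={
            # certified search settings: coarse sampling matched to the toy's
            # size, GA rates at the ~1/L per-gene heuristic for 7 genes
            "lattice_spacing": 0.75,
            "rot_step": 15.0,
            "dih_step": 15.0,
            "flexible_bonds": [],
            "crossover_prob": 0.8,
            "mutation_prob": 0.18,
        },
    )


def pocket_docking_setup(pocket: ToyPocket):
    """Detect the pocket cleft and assemble the certified docking context.

    Returns (cleft, search space, DockingContext) using the search settings
    stored on the fixture; the reference pose for RMSD reporting is the
    planted ligand.
    """
    from .cleft_detection import DetectionParams, detect_clefts
    from .docking_engine import DockingContext, build_search_space

    clefts = detect_clefts(pocket.target, DetectionParams(1.5, 4.0))
    cleft = clefts[0]
    space = build_search_space([cleft], pocket.docking["lattice_spacing"])
    ctx = DockingContext(
        pocket.target,
        pocket.ligand,
        space,
        flexible_bonds=pocket.docking["flexible_bonds"],
        rot_step=pocket.docking["rot_step"],
        dih_step=pocket.docking["dih_step"],
        reference=pocket.ligand.coords,
    )
    return cleft, space, ctx


def pocket_ga_params(pocket: ToyPocket, seed: int, n_chromosomes: int = 200,
                     n_generations: int = 50):
    """GA parameters matching the fixture's certified settings."""
    from .docking_engine import GAParams

    return GAParams(
        n_chromosomes=n_chromosomes,
        n_generations=n_generations,
        crossover_prob=pocket.docking["crossover_prob"],
        mutation_prob=pocket.docking["mutation_prob"],
        seed=seed,
    )


def certify_planted_optimum(
    pocket: ToyPocket,
    lattice_points: np.ndarray,
    scoring_params=None,
    rot_step: float = 30.0,
    exclusion: float = 2.0,
) -> tuple[float, float]:
    """Certify the planted pose by exhaustive rigid enumeration.

    Scores the planted pose and every (lattice point × Euler grid at
    ``rot_step``) pose whose anchor lies at least ``exclusion`` Å from the
    planted anchor; returns (planted score, best competing score) and raises
    :class:`FixtureError` unless the planted pose scores strictly better.
    """
    from scipy.spatial.transform import Rotation

    from .scoring import ScoringParams, filter_target, score_arrays

    p = scoring_params or ScoringParams()
    target = filter_target(pocket.target, p)
    lig = pocket.ligand
    base = lig.coords - lig.coords[lig.anchor]
    lig_vdw = np.array([a.vdw_radius for a in lig.atoms])
    lig_heavy = np.array([a.element.upper() != "H" for a in lig.atoms])

    planted_coords = base + pocket.planted.translation
    planted_score = float(score_arrays(planted_coords, lig_vdw, target.coords,
                                       target.vdw, p, lig_heavy))

    anchor0 = pocket.planted.translation
    far = lattice_points[np.linalg.norm(lattice_points - anchor0, axis=1) >= exclusion]
    n_ang = int(round(360.0 / rot_step))
    grid = np.array(np.meshgrid(*[np.arange(n_ang)] * 3, indexing="ij")).reshape(3, -1).T
    mats = Rotation.from_euler("ZYX", grid * rot_step, degrees=True).as_matrix()
    rotated = np.einsum("nij,aj->nai", mats, base)  # (n_orient, n_atoms, 3)

    best = np.inf
    for trans in far:
        batch = rotated + trans
        scores = score_arrays(batch, lig_vdw, target.coords, target.vdw, p, lig_heavy)
        best = min(best, float(np.min(scores)))
    if planted_score >= best:
        raise FixtureError(
            f"planted pose is not the enumerated optimum "
            f"(planted {planted_score:.4f} vs distant best {best:.4f})"
        )
    return planted_score, best


def make_flex_residue(res_seq: int = 1, chain: str = "B",
                      offset: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Structure:
    """A serine-like residue (N, CA, C, O, CB, OG) for rotamer tests.

    The CA–CB bond is the single chi axis; only OG moves when it rotates.
    """
    off = np.asarray(offset, float)
    coords = {
        "N": (-1.458, 0.0, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (0.55, 1.42, 0.0),
        "O": (1.76, 1.6, 0.0),
        "CB": (0.54, -0.77, 1.2),
        "OG": (0.05, -2.1, 1.3),
    }
    atoms = [
        _atom(i + 1, name, name[0], "SER", res_seq, np.array(xyz) + off, chain=chain)
        for i, (name, xyz) in enumerate(coords.items())
    ]
    return Structure(atoms, id="flex_residue")
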