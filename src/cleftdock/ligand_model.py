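"""Ligand topology and internal-coordinate pose reconstruction.

A ligand is represented by its atoms, a bond graph, the subset of rotatable
bonds, and an anchor atom: the center of rotation and translation of the
pose encoding. Poses are rebuilt from degrees of freedom rather than stored
as coordinates — each flexible dihedral rotates the subtree distal to its
bond, the whole molecule is then oriented by intrinsic Z-Y-X Euler angles
about the anchor and the anchor translated to its target position, so bond
lengths and angles are rigidly preserved.

Bonds are taken verbatim from an SDF V2000 bond block (via RDKit when
available) or inferred from distances for PDB input: two atoms are bonded
when closer than 1.3× the sum of their covalent radii. Rotatable bonds are
single-order bridge (non-ring) bonds with at least one heavy-atom
substituent on both sides. The automatic anchor is the heavy atom closest to
the heavy-atom centroid, which minimizes the lever arm of the orientation
genes; callers may override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .structure_io import Atom, Structure, covalent_radius, vdw_radius

BOND_TOLERANCE = 1.3  # multiplier on covalent-radius sums for bond inference


@dataclass
class PoseDOF:
    """Degrees of freedom of one pose.

    translation: target position of the anchor atom (Å).
    orientation: intrinsic Z-Y-X Euler angles about the anchor (degrees).
    dihedrals: absolute dihedral angle per selected flexible bond (degrees).
    All angles are normalized to [0, 360).
    """

    translation: np.ndarray
    orientation: np.ndarray
    dihedrals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        def wrap(a):
            a = np.mod(np.asarray(a, dtype=float), 360.0)
            return np.where(a >= 360.0, 0.0, a)  # mod of −ε rounds to 360.0

        self.translation = np.asarray(self.translation, dtype=float)
        self.orientation = wrap(self.orientation)
        self.dihedrals = wrap(self.dihedrals)


class LigandTopology:
    """Atoms, bond graph, rotatable bonds and the anchor-rooted tree."""

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Sequence[tuple[int, int, int]],
        anchor: Optional[int] = None,
    ) -> None:
        self.atoms = list(atoms)
        self.bonds = [(min(i, j), max(i, j), order) for i, j, order in bonds]
        self.graph = nx.Graph()
        self.graph.add_nodes_from(range(len(self.atoms)))
        self.graph.add_edges_from((i, j) for i, j, _ in self.bonds)
        if len(self.atoms) == 0:
            raise InputError("ligand has no atoms")
        if len(self.atoms) > 1 and not nx.is_connected(self.graph):
            raise InputError("ligand bond graph is disconnected")
        self.coords = np.array([a.coords for a in self.atoms], dtype=float)
        self.rotatable: list[int] = self._find_rotatable()
        self.anchor: int = auto_anchor(self) if anchor is None else int(anchor)
        self._parent, self._order = self._build_tree(self.anchor)

    # -- construction helpers -------------------------------------------------

    def _heavy(self, i: int) -> bool:
        return self.atoms[i].element.upper() != "H"

    def _find_rotatable(self) -> list[int]:
        bridges = set(frozenset(e) for e in nx.bridges(self.graph)) if self.graph.number_of_edges() else set()
        rot = []
        for b_idx, (i, j, order) in enumerate(self.bonds):
            if order != 1:
                continue
            if frozenset((i, j)) not in bridges:  # ring bond
                continue
            heavy_i = any(self._heavy(n) for n in self.graph[i] if n != j)
            heavy_j = any(self._heavy(n) for n in self.graph[j] if n != i)
            if heavy_i and heavy_j:
                rot.append(b_idx)
        return rot

    def _build_tree(self, root: int) -> tuple[np.ndarray, list[int]]:
        parent = np.full(len(self.atoms), -1, dtype=int)
        order: list[int] = []
        for u, v in nx.bfs_edges(self.graph, root):
            parent[v] = u
            order.append(v)
        return parent, order

    @property
    def dihedral_tree(self) -> np.ndarray:
        """Parent index per atom (−1 at the anchor root), spanning all atoms."""
        return self._parent

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i in range(len(self.atoms)) if self._heavy(i)], dtype=int)

    def __len__(self) -> int:
        return len(self.atoms)

    # -- geometry -------------------------------------------------------------

    def distal_atoms(self, bond_index: int) -> tuple[int, int, np.ndarray]:
        """(proximal, distal) endpoints of a bond and the indices on the
        distal side, with proximal = the side containing the anchor."""
        i, j, _ = self.bonds[bond_index]
        g = self.graph.copy()
        g.remove_edge(i, j)
        comp_j = nx.node_connected_component(g, j)
        if self.anchor in comp_j:
            prox, dist = j, i
            side = np.array(sorted(nx.node_connected_component(g, i)), dtype=int)
        else:
            prox, dist = i, j
            side = np.array(sorted(comp_j), dtype=int)
        return prox, dist, side

    def dihedral_reference(self, bond_index: int) -> Optional[tuple[int, int, int, int]]:
        """Reference quadruple (p, a, b, q) defining the bond's dihedral:
        a–b is the bond (a proximal), p the lowest-index other neighbor of a,
        q the lowest-index other neighbor of b; None when either end has no
        other neighbor (terminal bond — no dihedral defined)."""
        a, b, _side = self.distal_atoms(bond_index)
        p_cand = sorted(n for n in self.graph[a] if n != b)
        q_cand = sorted(n for n in self.graph[b] if n != a)
        if not p_cand or not q_cand:
            return None
        return p_cand[0], a, b, q_cand[0]


def measured_dihedral(coords: np.ndarray, p: int, a: int, b: int, q: int) -> float:
    """Signed dihedral angle p–a–b–q in degrees, in [0, 360)."""
    b0 = coords[p] - coords[a]
    b1 = coords[b] - coords[a]
    b2 = coords[q] - coords[b]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    ang = np.degrees(np.arctan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))
    ang = float(np.mod(ang, 360.0))
    return 0.0 if ang >= 360.0 else ang  # mod of −ε rounds to exactly 360.0


def auto_anchor(t: LigandTopology) -> int:
    """Heavy atom closest to the heavy-atom centroid; ties to lowest index."""
    heavy = t.heavy_indices
    if len(heavy) == 0:
        heavy = np.arange(len(t.atoms))
    centroid = t.coords[heavy].mean(axis=0)
    d = np.linalg.norm(t.coords[heavy] - centroid, axis=1)
    # argmin returns the first (lowest-index) minimizer; heavy is sorted
    return int(heavy[int(np.argmin(np.round(d, 9)))])


def _infer_bonds(atoms: Sequence[Atom]) -> list[tuple[int, int, int]]:
    coords = np.array([a.coords for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            cut = BOND_TOLERANCE * (radii[i] + radii[j])
            if np.linalg.norm(coords[i] - coords[j]) < cut:
                bonds.append((i, j, 1))
    return bonds


def _topology_from_sdf(path: Path, anchor: Optional[int]) -> LigandTopology:
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an optional extra
        raise InputError("SDF input requires the optional rdkit dependency") from exc
    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise InputError(f"cannot parse SDF/MOL file {path}")
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    if conf is None:
        raise InputError(f"{path}: no 3-D coordinates in SDF record")
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        elem = a.GetSymbol()
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"{elem}{i + 1}",
                element=elem,
                res_name="LIG",
                res_seq=1,
                chain_id="L",
                coords=np.array([pos.x, pos.y, pos.z]),
                vdw_radius=vdw_radius(elem),
                is_het=True,
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()) or 1)
        for b in mol.GetBonds()
    ]
    return LigandTopology(atoms, bonds, anchor=anchor)


def build_topology(
    mol: Union[Structure, str, Path], anchor: Optional[int] = None
) -> LigandTopology:
    """Build a ligand topology from a Structure, a PDB path or an SDF path.

    SDF bond blocks are taken verbatim; PDB/Structure input gets
    distance-inferred single bonds.
    """
    if isinstance(mol, (str, Path)):
        path = Path(mol)
        if path.suffix.lower() in (".sdf", ".mol"):
            return _topology_from_sdf(path, anchor)
        from .structure_io import read_pdb

        mol = read_pdb(path, keep_het=True, keep_water=False)
    return LigandTopology(mol.atoms, _infer_bonds(mol.atoms), anchor=anchor)


def apply_dof(
    t: LigandTopology, d: PoseDOF, flexible: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Rebuild Cartesian coordinates from pose degrees of freedom.

    ``flexible`` selects which rotatable bonds the dihedral genes drive
    (defaults to all of ``t.rotatable``); ``d.dihedrals`` must match its
    length. The identity DOF — translation at the original anchor position,
    zero orientation, the original measured dihedrals — reproduces the input
    coordinates.
    """
    flexible = list(t.rotatable) if flexible is None else list(flexible)
    if len(d.dihedrals) != len(flexible):
        raise ValueError(
            f"got {len(d.dihedrals)} dihedral values for {len(flexible)} flexible bonds"
        )
    coords = t.coords.copy()
    for value, b_idx in zip(d.dihedrals, flexible):
        ref = t.dihedral_reference(b_idx)
        if ref is None:
            continue
        p, a, b, q = ref
        current = measured_dihedral(coords, p, a, b, q)
        delta = np.radians(value - current)
        axis = coords[b] - coords[a]
        axis = axis / np.linalg.norm(axis)
        _, _, side = t.distal_atoms(b_idx)
        rot = Rotation.from_rotvec(delta * axis)
        coords[side] = rot.apply(coords[side] - coords[b]) + coords[b]
    anchor_pos = coords[t.anchor].copy()
    rot = Rotation.from_euler("ZYX", d.orientation, degrees=True)
    coords = rot.apply(coords - anchor_pos) + d.translation
    return coords


def identity_dof(t: LigandTopology, flexible: Optional[Sequence[int]] = None) -> PoseDOF:
    """The DOF vector that reproduces the topology's input coordinates."""
    flexible = list(t.rotatable) if flexible is None else list(flexible)
    dihedrals = []
    for b_idx in flexible:
        ref = t.dihedral_reference(b_idx)
        dihedrals.append(0.0 if ref is None else measured_dihedral(t.coords, *ref))
    return PoseDOF(
        translation=t.coords[t.anchor].copy(),
        orientation=np.zeros(3),
        dihedrals=np.array(dihedrals),
    )


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation of matched atoms, without superposition."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.shape != coords_b.shape:
        raise ValueError(f"coordinate shapes differ: {coords_a.shape} vs {coords_b.shape}")
    return float(np.sqrt(np.mean(np.sum((coords_a - coords_b) ** 2, axis=1))))
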