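"""Molecular structure I/O and neighbor queries.

Reads PDB files into a lightweight :class:`Structure` container whose atoms
carry element-based van der Waals radii, HET and water flags; provides exact
radius-limited neighbor queries (backed by a k-d tree) used by all downstream
geometry; and reads/writes the sphere-PDB dialect in which detected cleft
spheres are stored (one ``HETATM`` pseudo-atom per sphere, residue name
``SPH``, sphere radius in the occupancy column).

Only the first MODEL of a file is honored, and only blank/'A' alternate
locations. Waters are recognized by residue name (HOH/WAT/DOD); every water
is also flagged HET regardless of its record type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, InputError

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


def _load_radii() -> dict[str, dict[str, float]]:
    with resources.files("cleftdock.data").joinpath("radii.json").open() as fh:
        return json.load(fh)


_RADII = _load_radii()
VDW_RADII: dict[str, float] = dict(_RADII["vdw"])
COVALENT_RADII: dict[str, float] = dict(_RADII["covalent"])


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) for an element symbol; 1.7 Å fallback."""
    return VDW_RADII.get(element.upper(), VDW_RADII["DEFAULT"])


def covalent_radius(element: str) -> float:
    """Covalent radius (Å) for an element symbol, used for bond inference."""
    return COVALENT_RADII.get(element.upper(), COVALENT_RADII["DEFAULT"])


@dataclass
class Atom:
    """A single atom with coordinates in Å and an element-based vdW radius."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray
    vdw_radius: float
    is_het: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InputError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise InputError(f"atom {self.serial}: vdw_radius must be positive")
        if self.is_water:
            self.is_het = True


class Structure:
    """An ordered collection of atoms with cached arrays and a k-d tree."""

    def __init__(self, atoms: Sequence[Atom], id: str = "") -> None:
        self.atoms: list[Atom] = list(atoms)
        self.id = id
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise InputError("duplicate atom serials in structure")
        self._coords: np.ndarray | None = None
        self._vdw: np.ndarray | None = None
        self._tree: cKDTree | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array, Å."""
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)
        return self._coords

    @property
    def vdw(self) -> np.ndarray:
        """(n,) vdW radius array, Å."""
        if self._vdw is None:
            self._vdw = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        return self._vdw

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    def filtered(self, keep_het: bool = True, keep_water: bool = False) -> "Structure":
        """Copy with HET groups and/or waters removed."""
        atoms = []
        for a in self.atoms:
            if a.is_water:
                if not keep_water:
                    continue
            elif a.is_het and not keep_het:
                continue
            atoms.append(a)
        return Structure(atoms, id=self.id)


def _atom_from_gemmi(serial: int, atom: gemmi.Atom, res: gemmi.Residue, chain_id: str) -> Atom:
    elem = atom.element.name if atom.element else ""
    is_water = res.name.strip() in _WATER_NAMES
    is_het = res.het_flag == "H" or is_water
    return Atom(
        serial=serial,
        name=atom.name,
        element=elem,
        res_name=res.name.strip(),
        res_seq=res.seqid.num,
        chain_id=chain_id,
        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        vdw_radius=vdw_radius(elem),
        is_het=is_het,
        is_water=is_water,
    )


def read_pdb(path: str | Path, keep_het: bool = True, keep_water: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only MODEL 1 and altloc ''/'A' atoms are kept. Waters (HOH/WAT/DOD) are
    dropped when ``keep_water`` is false; non-water HETATM groups are dropped
    when ``keep_het`` is false. Raises :class:`InputError` on unreadable files
    and :class:`EmptyStructureError` when no atoms survive filtering.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            is_water = res.name.strip() in _WATER_NAMES
            is_het = res.het_flag == "H" or is_water
            if is_water and not keep_water:
                continue
            if is_het and not is_water and not keep_het:
                continue
            for atom in res:
                if atom.altloc not in ("\0", "", "A", "\x00"):
                    continue
                atoms.append(_atom_from_gemmi(atom.serial, atom, res, chain.name))
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms after filtering")
    return Structure(atoms, id=path.stem)


def _pdb_atom_name(atom: Atom) -> str:
    # PDB column convention: 1-char elements start in column 14.
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a structure as standard ATOM/HETATM records."""
    lines = []
    for a in s.atoms:
        rec = "HETATM" if a.is_het else "ATOM  "
        x, y, z = a.coords
        lines.append(
            f"{rec}{a.serial:5d} {_pdb_atom_name(a)} {a.res_name:<3s} "
            f"{a.chain_id[:1] or 'A'}{a.res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def neighbors_within(s: Structure, point: Sequence[float], r: float) -> list[Atom]:
    """Atoms with ``|coords − point| ≤ r``, nearest first, ties by serial."""
    if r < 0:
        raise ValueError("query radius must be non-negative")
    point = np.asarray(point, dtype=float)
    if len(s) == 0:
        return []
    idx = s.kdtree.query_ball_point(point, r)
    dists = np.linalg.norm(s.coords[idx] - point, axis=1) if idx else np.empty(0)
    order = sorted(range(len(idx)), key=lambda k: (dists[k], s.atoms[idx[k]].serial))
    return [s.atoms[idx[k]] for k in order]


def write_sphere_pdb(spheres: Iterable, path: str | Path) -> None:
    """Write gap spheres as SPH pseudo-atoms, radius in the occupancy column.

    Round-trips through :func:`read_sphere_pdb` with centers exact to the PDB
    coordinate precision (3 decimals) and radii to 2 decimals.
    """
    spheres = list(spheres)
    if not spheres:
        raise ValueError("cannot write an empty sphere list")
    lines = []
    for i, sp in enumerate(spheres, start=1):
        x, y, z = sp.center
        lines.append(
            f"HETATM{i:5d}  SPH SPH Z{i % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{sp.radius:6.2f}{0.0:6.2f}          "
            f" S"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sphere_pdb(path: str | Path):
    """Read SPH pseudo-atom records back into a list of gap spheres."""
    from .cleft_detection import GapSphere  # deferred: avoids import cycle

    spheres = []
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputError(f"cannot read sphere file {path}: {exc}") from exc
    for line in text.splitlines():
        if not line.startswith(("HETATM", "ATOM")):
            continue
        if line[17:20].strip() != "SPH":
            continue
        center = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        radius = float(line[54:60])
        spheres.append(GapSphere(center=center, radius=radius, pair=(0, 0)))
    if not spheres:
        raise InputError(f"{path}: no SPH records found")
    return spheres
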