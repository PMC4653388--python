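"""Pose scoring: a smooth surrogate pairwise potential with the docking
knobs exposed — van der Waals permeability, implicit-solvent exclusion force,
HET/water handling — plus harmonic distance constraints (covalent-docking
emulation) and geometric hydrogen-bond detection.

The pairwise form is deliberately simple and documented rather than a fitted
energy function (the interface is pluggable so a fitted parameterization can
be dropped in without touching the search engine). For a ligand/target atom
pair at distance d with contact distance d0 = vdW_i + vdW_j and width s
(``contact_scale``):

    clash(d)   = (1 − permeability) · ((d0 − d)/s)²   for d < d0, else 0
    attract(d) = −exp(−((d − d0)/s)²)                 at every distance

The Gaussian attraction is symmetric about d0 and equals −1 at touch, so the
pair term is continuous and smooth everywhere; the permeability knob in
[0, 1] scales only the clash penalty (1 = fully permeable). Pairs beyond an
8 Å cutoff contribute nothing. Lower scores are better.

By default other HET ligands present in the target are considered while
water molecules are ignored; both are toggles. The implicit-solvent
"exclusion force" adds ``solvent_weight`` per ligand heavy atom with no
target atom within 6 Å, rewarding burial when the weight is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .ligand_model import LigandTopology
from .structure_io import Structure

PAIR_CUTOFF = 8.0  # Å, pair interactions beyond this are dropped
SOLVENT_EXPOSURE_CUTOFF = 6.0  # Å, a ligand atom with no target atom nearer is "exposed"
HBOND_MIN, HBOND_MAX = 2.4, 3.5  # Å, heavy-atom donor–acceptor window
_LIGAND_POLAR = frozenset({"N", "O", "S"})
_TARGET_POLAR = frozenset({"N", "O"})


@dataclass
class ScoringParams:
    """Knobs of the pairwise score; see the module docstring for the form."""

    permeability: float = 0.0
    include_het: bool = True
    include_water: bool = False
    solvent_term: str = "none"  # "none" | "exclusion_force" | "solvent_type"
    solvent_weight: float = 1.0
    contact_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.permeability <= 1.0:
            raise ValueError("permeability must lie in [0, 1]")
        if self.solvent_term not in ("none", "exclusion_force", "solvent_type"):
            raise ValueError(f"unknown solvent_term {self.solvent_term!r}")
        if self.contact_scale <= 0:
            raise ValueError("contact_scale must be positive")


@dataclass
class Constraint:
    """Harmonic distance constraint between a ligand atom and a target atom.

    The penalty is weight · (actual − distance)²; a tight, heavily weighted
    constraint at a covalent bond length emulates covalent docking.
    """

    ligand_atom: int
    target_atom: int  # serial in the target structure
    distance: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("constraint distance must be positive")
        if self.weight < 0:
            raise ValueError("constraint weight must be non-negative")


def filter_target(s: Structure, p: ScoringParams) -> Structure:
    """Apply the HET/water inclusion rules to the target structure."""
    return s.filtered(keep_het=p.include_het, keep_water=p.include_water)


def pair_energy(d: np.ndarray, d0: np.ndarray, p: ScoringParams) -> np.ndarray:
    """Vectorized pair term clash(d) + attract(d)."""
    s = p.contact_scale
    clash = np.where(d < d0, (1.0 - p.permeability) * ((d0 - d) / s) ** 2, 0.0)
    attract = -np.exp(-(((d - d0) / s) ** 2))
    return clash + attract


def score_arrays(
    lig_coords: np.ndarray,
    lig_vdw: np.ndarray,
    tgt_coords: np.ndarray,
    tgt_vdw: np.ndarray,
    p: ScoringParams,
    lig_heavy: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Array-level scoring kernel, batched over poses.

    ``lig_coords`` may be (n_atoms, 3) for one pose or (n_poses, n_atoms, 3)
    for a batch; returns a scalar array of per-pose scores (shape () or
    (n_poses,)). The target is assumed already filtered.
    """
    if p.solvent_term == "solvent_type":
        raise NotImplementedError(
            "the typed pairwise solvent term requires a fitted per-type parameter "
            "table; use solvent_term='exclusion_force' or 'none'"
        )
    lig_coords = np.asarray(lig_coords, dtype=float)
    single = lig_coords.ndim == 2
    batch = lig_coords[None] if single else lig_coords
    if len(tgt_coords) == 0:
        heavy = np.ones(batch.shape[1], bool) if lig_heavy is None else np.asarray(lig_heavy, bool)
        base = p.solvent_weight * float(heavy.sum()) if p.solvent_term == "exclusion_force" else 0.0
        out = np.full(batch.shape[0], base)
        return out[0] if single else out

    # (n_poses, n_lig, n_tgt)
    d = np.linalg.norm(batch[:, :, None, :] - tgt_coords[None, None, :, :], axis=-1)
    d0 = np.asarray(lig_vdw)[None, :, None] + np.asarray(tgt_vdw)[None, None, :]
    energy = np.where(d <= PAIR_CUTOFF, pair_energy(d, d0, p), 0.0)
    total = energy.sum(axis=(1, 2))

    if p.solvent_term == "exclusion_force":
        heavy = np.ones(batch.shape[1], bool) if lig_heavy is None else np.asarray(lig_heavy, bool)
        exposed = ((d.min(axis=2) > SOLVENT_EXPOSURE_CUTOFF) & heavy[None, :]).sum(axis=1)
        total = total + p.solvent_weight * exposed
    return total[0] if single else total


def score_pose(
    coords: np.ndarray,
    s: Structure,
    p: ScoringParams = ScoringParams(),
    ligand_vdw: Optional[np.ndarray] = None,
    ligand_heavy: Optional[np.ndarray] = None,
    prefiltered: bool = False,
) -> float:
    """Score ligand coordinates against a target structure (lower = better).

    ``ligand_vdw`` defaults to carbon radii when not given; ``ligand_heavy``
    marks which ligand atoms count for the solvent exposure term (all, by
    default). Pass ``prefiltered=True`` when the structure has already been
    through :func:`filter_target`.
    """
    target = s if prefiltered else filter_target(s, p)
    coords = np.asarray(coords, dtype=float)
    if ligand_vdw is None:
        ligand_vdw = np.full(len(coords), 1.7)
    return float(
        score_arrays(coords, ligand_vdw, target.coords if len(target) else np.empty((0, 3)),
                     target.vdw if len(target) else np.empty(0), p, ligand_heavy)
    )


def constraint_penalty(
    coords: np.ndarray, s: Structure, cs: Sequence[Constraint]
) -> float:
    """Σ weight · (actual − target distance)²; zero iff all met exactly."""
    coords = np.asarray(coords, dtype=float)
    by_serial = {a.serial: a for a in s.atoms}
    total = 0.0
    for c in cs:
        if not 0 <= c.ligand_atom < len(coords):
            raise ValueError(f"constraint references unknown ligand atom {c.ligand_atom}")
        if c.target_atom not in by_serial:
            raise ValueError(f"constraint references unknown target serial {c.target_atom}")
        actual = float(np.linalg.norm(coords[c.ligand_atom] - by_serial[c.target_atom].coords))
        total += c.weight * (actual - c.distance) ** 2
    return total


def hydrogen_bonds(
    coords: np.ndarray, lig: LigandTopology, s: Structure
) -> list[tuple[int, int, float]]:
    """Potential hydrogen bonds between a posed ligand and the target.

    Geometric criterion only: a ligand N/O/S heavy atom and a target N/O
    atom whose distance lies in [2.4, 3.5] Å. Returns (ligand atom index,
    target serial, distance) sorted by distance. No angular term is applied
    so the rule works on structures without hydrogens.
    """
    coords = np.asarray(coords, dtype=float)
    lig_polar = [i for i, a in enumerate(lig.atoms) if a.element.upper() in _LIGAND_POLAR]
    tgt_polar = [a for a in s.atoms if a.element.upper() in _TARGET_POLAR]
    out = []
    for i in lig_polar:
        for a in tgt_polar:
            dist = float(np.linalg.norm(coords[i] - a.coords))
            if HBOND_MIN <= dist <= HBOND_MAX:
                out.append((i, a.serial, dist))
    out.sort(key=lambda t: t[2])
    return out
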