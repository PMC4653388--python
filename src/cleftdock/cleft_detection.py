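"""Gap-sphere detection of surface clefts and buried cavities.

For every pair of atoms closer than a provable cutoff, the largest sphere is
placed at the pair midpoint that does not penetrate the van der Waals surface
of any atom of the macromolecule, subject to a user radius window
[r_min, r_max]. Overlapping spheres are then merged into connected
components: each component is one cleft (surface-exposed) or cavity (fully
buried), and components are ranked by the summed isolated-sphere volume — a
deliberately rough sort; accurate grid volumes are a separate measurement
(see :mod:`cleftdock.cleft_analysis`).

Conventions fixed here for determinism: the sphere center stays at the pair
midpoint (only the radius shrinks when clipped by a third atom); overlap is
the strict inequality |c1 − c2| < r1 + r2, so tangent spheres belong to
separate clefts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import InputError
from .structure_io import Atom, Structure


@dataclass
class GapSphere:
    """A maximal sphere placed at an atom-pair midpoint.

    ``pair`` records the serials of the two generating atoms ((0, 0) for
    spheres re-read from file, where provenance is lost).
    """

    center: np.ndarray
    radius: float
    pair: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    @property
    def volume(self) -> float:
        """Isolated-sphere volume 4/3·π·r³ (ų); overlaps not corrected."""
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class Cleft:
    """A connected union of overlapping gap spheres."""

    id: int
    spheres: list[GapSphere]
    sphere_volume_sum: float
    grid_volume: Optional[float] = None
    r_min: Optional[float] = None  # detection r_min, needed to validate refinement

    def __len__(self) -> int:
        return len(self.spheres)

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.spheres], dtype=float)


@dataclass
class DetectionParams:
    """Radius window and optional chain filter for a detection run."""

    r_min: float = 1.5
    r_max: float = 4.0
    chain_filter: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= self.r_max):
            raise ValueError(f"need 0 < r_min ≤ r_max, got [{self.r_min}, {self.r_max}]")

    def pair_cutoff(self, max_vdw: float) -> float:
        """Candidate pairs are limited to separation ≤ 2·(r_max + max vdW).

        This is the spanning condition: a midpoint sphere capped at r_max can
        reach both of its generating atoms' vdW surfaces only when the pair is
        at most 2·(r_max + vdW) apart — beyond that the sphere would float
        detached from the gap it is meant to fill. It also keeps pair
        enumeration local (spatial index instead of O(n²)). Large cavities
        therefore need an r_max on the order of their interior radius to be
        filled, which is why the radius window is user-set.
        """
        return 2.0 * (self.r_max + max_vdw)


def prune_contained(spheres: Sequence[GapSphere]) -> list[GapSphere]:
    """Drop spheres wholly contained in another sphere of the set.

    The union of the spheres — hence any volume or lattice built from it —
    is unchanged; dense cavity sets shrink dramatically because a few large
    central spheres engulf most midpoint spheres. Containment test:
    |c_i − c_j| + r_i ≤ r_j (ties keep the earlier sphere).
    """
    spheres = list(spheres)
    if len(spheres) < 2:
        return spheres
    order = sorted(range(len(spheres)), key=lambda i: -spheres[i].radius)
    kept: list[int] = []
    kept_centers = np.empty((0, 3))
    kept_radii = np.empty(0)
    for i in order:
        sp = spheres[i]
        if len(kept):
            d = np.linalg.norm(kept_centers - sp.center, axis=1)
            if np.any(d + sp.radius <= kept_radii):
                continue
        kept.append(i)
        kept_centers = np.vstack([kept_centers, sp.center])
        kept_radii = np.append(kept_radii, sp.radius)
    return [spheres[i] for i in sorted(kept)]


def spheres_overlap(s1: GapSphere, s2: GapSphere) -> bool:
    """Strict overlap test: tangency does not merge."""
    return float(np.linalg.norm(s1.center - s2.center)) < s1.radius + s2.radius


def max_gap_sphere(
    a: Atom, b: Atom, s: Structure, p: DetectionParams
) -> Optional[GapSphere]:
    """Largest admissible sphere at the midpoint of atoms ``a`` and ``b``.

    radius = min(r_max, min_k(|center − x_k| − vdW_k)) over all atoms k;
    returns None when that radius falls below r_min.
    """
    if a is b or a.serial == b.serial:
        raise ValueError("gap sphere requires two distinct atoms")
    center = 0.5 * (a.coords + b.coords)
    max_vdw = float(s.vdw.max())
    idx = s.kdtree.query_ball_point(center, p.r_max + max_vdw)
    if idx:
        d = np.linalg.norm(s.coords[idx] - center, axis=1) - s.vdw[idx]
        radius = min(p.r_max, float(d.min()))
    else:
        radius = p.r_max
    if radius < p.r_min:
        return None
    return GapSphere(center=center, radius=radius, pair=(min(a.serial, b.serial), max(a.serial, b.serial)))


def _cluster_spheres(spheres: list[GapSphere]) -> list[list[GapSphere]]:
    """Connected components of the strict-overlap graph.

    Frontier BFS with chunked distance blocks: cavity sphere sets are often
    near-cliques, where materializing the full pair list is quadratic in
    memory; the BFS touches each sphere once and compares frontier blocks
    only against still-unlabeled spheres.
    """
    n = len(spheres)
    if n == 0:
        return []
    centers = np.array([sp.center for sp in spheres])
    radii = np.array([sp.radius for sp in spheres])
    labels = np.full(n, -1, dtype=int)
    comp = 0
    chunk = 256
    for seed in range(n):
        if labels[seed] >= 0:
            continue
        labels[seed] = comp
        frontier = np.array([seed])
        unvis = np.flatnonzero(labels < 0)
        while len(frontier) and len(unvis):
            hit = np.zeros(len(unvis), dtype=bool)
            for k in range(0, len(frontier), chunk):
                blk = frontier[k : k + chunk]
                d = cdist(centers[blk], centers[unvis])
                hit |= (d < radii[blk][:, None] + radii[unvis][None, :]).any(axis=0)
            frontier = unvis[hit]
            labels[frontier] = comp
            unvis = unvis[~hit]
        comp += 1
    comps: list[list[GapSphere]] = [[] for _ in range(comp)]
    for i, lab in enumerate(labels):
        comps[lab].append(spheres[i])
    return comps


def cluster_into_clefts(spheres: list[GapSphere], r_min: Optional[float] = None) -> list[Cleft]:
    """Merge spheres into clefts and rank them.

    Sort key: descending Σ 4/3·π·r³, then descending sphere count, then
    lowest generating serial; ids are assigned 1..N after sorting.
    """
    comps = _cluster_spheres(spheres)
    keyed = []
    for comp in comps:
        vol = float(sum(sp.volume for sp in comp))
        min_serial = min(min(sp.pair) for sp in comp)
        keyed.append((vol, comp, min_serial))
    keyed.sort(key=lambda t: (-t[0], -len(t[1]), t[2]))
    return [
        Cleft(id=i, spheres=comp, sphere_volume_sum=vol, r_min=r_min)
        for i, (vol, comp, _) in enumerate(keyed, start=1)
    ]


def detect_clefts(s: Structure, p: DetectionParams = DetectionParams()) -> list[Cleft]:
    """Detect all clefts and cavities of a structure.

    Candidate pairs are restricted to |a − b| ≤ 2·(r_max + max vdW), which
    loses nothing: beyond it the pair's own atoms already clip the midpoint
    sphere below r_min.
    """
    if p.chain_filter is not None:
        chains = set(p.chain_filter)
        s = Structure([a for a in s.atoms if a.chain_id in chains], id=s.id)
    if len(s) < 2:
        raise InputError("cleft detection needs at least 2 atoms")
    max_vdw = float(s.vdw.max())
    cutoff = p.pair_cutoff(max_vdw)
    pairs = s.kdtree.query_pairs(cutoff, output_type="ndarray")
    spheres: list[GapSphere] = []
    coords, vdw = s.coords, s.vdw
    serials = np.array([a.serial for a in s.atoms])
    chunk = 4096
    for k in range(0, len(pairs), chunk):
        blk = pairs[k : k + chunk]
        centers = 0.5 * (coords[blk[:, 0]] + coords[blk[:, 1]])
        clearance = (cdist(centers, coords) - vdw[None, :]).min(axis=1)
        radii = np.minimum(p.r_max, clearance)
        for (i, j), center, radius in zip(blk, centers, radii):
            if radius >= p.r_min:
                si, sj = serials[i], serials[j]
                spheres.append(
                    GapSphere(center=center, radius=float(radius),
                              pair=(int(min(si, sj)), int(max(si, sj))))
                )
    return cluster_into_clefts(spheres, r_min=p.r_min)
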