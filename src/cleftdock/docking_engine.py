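"""Genetic-algorithm docking over cleft-defined search spaces.

Pose and conformation are encoded as an integer chromosome: one gene indexes
a translational lattice built inside the selected cleft(s), three genes pick
orientation Euler angles on a fixed angular step, one gene per flexible
ligand bond picks its dihedral on the dihedral step, and one gene per
flexible side chain selects a rotamer. The GA is a simple deterministic
generational scheme — tournament selection of size 2, single-point
crossover, per-gene uniform reset mutation, elitism of 1 — driven by a
seeded PCG64 generator, so identical configuration and seed reproduce runs
bit-for-bit.

Sessions can be paused, stopped or aborted, and a saved session's final
population can seed a continuation; a continuation is only accepted when
every parameter other than the GA parameters is unchanged, which is enforced
by a content digest over the full non-GA configuration.

Flexible side chains are sampled from a coarse on-the-fly rotamer set: every
chi angle takes values in {−60°, 60°, 180°}, full cross-product capped at 81
rotamers per residue.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cleft_detection import Cleft
from .errors import ConfigurationError, ContinuationRefusedError, StateError
from .ligand_model import LigandTopology, PoseDOF, apply_dof, rmsd
from .scoring import Constraint, ScoringParams, filter_target, hydrogen_bonds, score_arrays
from .structure_io import Atom, Structure

DEFAULT_LATTICE_SPACING = 0.5  # Å, translational step
DEFAULT_ROT_STEP = 10.0  # degrees
DEFAULT_DIH_STEP = 10.0  # degrees
CHI_VALUES = (-60.0, 60.0, 180.0)
MAX_ROTAMERS = 81


# ---------------------------------------------------------------------------
# search space

@dataclass
class SearchSpace:
    """Translational lattice restricted to the union of cleft spheres."""

    lattice_points: np.ndarray  # (n, 3) Å
    spacing: float
    source_cleft_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lattice_points)


def build_search_space(clefts: Sequence[Cleft], spacing: float) -> SearchSpace:
    """Lattice over the union bounding box, kept inside any cleft sphere.

    Lattice points are integer multiples of the spacing (deterministic,
    independent of bounding-box jitter), ordered by x, then y, then z.
    """
    if not clefts:
        raise ConfigurationError("need at least one cleft to build a search space")
    if spacing <= 0:
        raise ConfigurationError("lattice spacing must be positive")
    all_spheres = [sp for c in clefts for sp in c.spheres]
    if not all_spheres:
        raise ConfigurationError("selected clefts contain no spheres")
    from .cleft_detection import prune_contained

    spheres = prune_contained(all_spheres)
    centers = np.array([sp.center for sp in spheres])
    radii = np.array([sp.radius for sp in spheres])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    axes = [
        np.arange(np.ceil(lo[k] / spacing), np.floor(hi[k] / spacing) + 1) * spacing
        for k in range(3)
    ]
    if any(len(ax) == 0 for ax in axes):
        raise ConfigurationError("lattice spacing too large for the selected clefts")
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(pts)
    inside = np.zeros(len(pts), dtype=bool)
    for ctr, rad in zip(centers, radii):
        inside[tree.query_ball_point(ctr, rad)] = True
    pts = pts[inside]
    if len(pts) == 0:
        raise ConfigurationError("lattice spacing too large: no lattice point falls inside the clefts")
    return SearchSpace(lattice_points=pts, spacing=spacing,
                       source_cleft_ids=[c.id for c in clefts])


# ---------------------------------------------------------------------------
# flexible side chains

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


class FlexibleResidue:
    """A target residue whose side chain samples coarse rotamers.

    Chi bonds are found generically: starting from the CA–CB bond, the side
    chain is walked outward and every bond with a further heavy atom beyond
    it becomes a chi axis. Each chi takes values in ``CHI_VALUES``; the full
    cross-product (capped at ``MAX_ROTAMERS``) forms the rotamer set, and
    rotamer 0 is always the input conformation.
    """

    def __init__(self, s: Structure, chain_id: str, res_seq: int) -> None:
        self.chain_id = chain_id
        self.res_seq = res_seq
        self.atom_serials = [
            a.serial for a in s.atoms if a.chain_id == chain_id and a.res_seq == res_seq
        ]
        if not self.atom_serials:
            raise ConfigurationError(f"no atoms for flexible residue {chain_id}:{res_seq}")
        atoms = [a for a in s.atoms if a.serial in set(self.atom_serials)]
        self._names = [a.name for a in atoms]
        self._coords = np.array([a.coords for a in atoms])
        self._heavy = [a.element.upper() != "H" for a in atoms]
        self._chi_axes = self._find_chi_axes(atoms)
        self._rotamer_coords = self._enumerate_rotamers()

    def _bonded(self, atoms: list[Atom]) -> dict[int, list[int]]:
        from .ligand_model import _infer_bonds

        adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
        for i, j, _ in _infer_bonds(atoms):
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def _find_chi_axes(self, atoms: list[Atom]) -> list[tuple[int, int, list[int]]]:
        """Chi axes as (proximal, distal, moved-atom-indices) triples."""
        name_to_idx = {a.name: i for i, a in enumerate(atoms)}
        if "CA" not in name_to_idx or "CB" not in name_to_idx:
            return []
        adj = self._bonded(atoms)
        backbone = {i for i, a in enumerate(atoms) if a.name in _BACKBONE and a.name != "CB"}
        axes: list[tuple[int, int, list[int]]] = []
        prev, cur = name_to_idx["CA"], name_to_idx["CB"]
        visited = {prev}
        while True:
            # atoms distal to the prev-cur bond (side-chain side)
            stack, moved = [cur], set()
            seen = {prev, cur}
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in seen and v not in backbone:
                        seen.add(v)
                        moved.add(v)
                        stack.append(v)
            heavy_beyond = [m for m in moved if self._heavy[m]]
            if heavy_beyond:
                axes.append((prev, cur, sorted(moved)))
            nxt = [v for v in adj[cur] if v not in visited and v not in backbone and self._heavy[v]]
            if not nxt:
                break
            visited.add(cur)
            prev, cur = cur, sorted(nxt)[0]
        return axes

    def _enumerate_rotamers(self) -> list[np.ndarray]:
        n_chi = len(self._chi_axes)
        rotamers = [self._coords.copy()]
        if n_chi == 0:
            return rotamers
        combos: list[tuple[float, ...]] = [()]
        for _ in range(n_chi):
            combos = [c + (v,) for c in combos for v in CHI_VALUES]
        for combo in combos:
            coords = self._coords.copy()
            for (prox, dist, moved), chi in zip(self._chi_axes, combo):
                axis = coords[dist] - coords[prox]
                axis = axis / np.linalg.norm(axis)
                rot = Rotation.from_rotvec(np.radians(chi) * axis)
                coords[moved] = rot.apply(coords[moved] - coords[dist]) + coords[dist]
            rotamers.append(coords)
            if len(rotamers) >= MAX_ROTAMERS:
                break
        return rotamers

    @property
    def n_rotamers(self) -> int:
        return len(self._rotamer_coords)

    def rotamer(self, k: int) -> tuple[list[int], np.ndarray]:
        """(atom serials, coordinates) of rotamer ``k``."""
        return self.atom_serials, self._rotamer_coords[k]


# ---------------------------------------------------------------------------
# docking context and chromosome codec

@dataclass
class GAParams:
    """Genetic algorithm parameters — the only ones a continuation may change."""

    n_chromosomes: int = 200
    n_generations: int = 50
    crossover_prob: float = 0.9
    mutation_prob: float = 0.025
    seed: int = 0
    top_n: int = 10
    refresh_every: int = 10

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class DockingContext:
    """Everything a docking run needs besides the GA parameters.

    The context digest covers every one of these inputs (structures by
    content); it is what makes continuations refuse silently changed
    parameters.
    """

    def __init__(
        self,
        target: Structure,
        ligand: LigandTopology,
        space: SearchSpace,
        scoring: ScoringParams = ScoringParams(),
        constraints: Sequence[Constraint] = (),
        flexible_bonds: Optional[Sequence[int]] = None,
        flexible_residues: Sequence[FlexibleResidue] = (),
        rot_step: float = DEFAULT_ROT_STEP,
        dih_step: float = DEFAULT_DIH_STEP,
        reference: Optional[np.ndarray] = None,
    ) -> None:
        self.target = target
        self.ligand = ligand
        self.space = space
        self.scoring = scoring
        self.constraints = list(constraints)
        self.flexible_bonds = list(ligand.rotatable) if flexible_bonds is None else list(flexible_bonds)
        self.flexible_residues = list(flexible_residues)
        self.rot_step = float(rot_step)
        self.dih_step = float(dih_step)
        self.reference = None if reference is None else np.asarray(reference, dtype=float)

        self.filtered = filter_target(target, scoring)
        self._serial_to_idx = {a.serial: i for i, a in enumerate(self.filtered.atoms)}
        self._tgt_coords = self.filtered.coords.copy()
        self._tgt_vdw = self.filtered.vdw.copy()
        self._lig_vdw = np.array([a.vdw_radius for a in ligand.atoms])
        self._lig_heavy = np.array([a.element.upper() != "H" for a in ligand.atoms])
        self._constraint_idx = []
        for c in self.constraints:
            if c.target_atom not in self._serial_to_idx:
                raise ConfigurationError(
                    f"constraint target serial {c.target_atom} absent from filtered target"
                )
            if not 0 <= c.ligand_atom < len(ligand.atoms):
                raise ConfigurationError(f"constraint ligand atom {c.ligand_atom} out of range")
            self._constraint_idx.append((c.ligand_atom, self._serial_to_idx[c.target_atom]))

        n_rot = int(round(360.0 / self.rot_step))
        n_dih = int(round(360.0 / self.dih_step))
        self.cardinalities = np.array(
            [len(space)] + [n_rot] * 3 + [n_dih] * len(self.flexible_bonds)
            + [fr.n_rotamers for fr in self.flexible_residues],
            dtype=np.int64,
        )
        self.n_genes = len(self.cardinalities)
        # rigid fast path: rotation+translation only, static target
        self._rigid = not self.flexible_bonds and not self.flexible_residues
        self._base_lig = ligand.coords - ligand.coords[ligand.anchor]

    # -- codec ---------------------------------------------------------------

    def decode(self, genes: np.ndarray) -> tuple[PoseDOF, list[int]]:
        """Genes → pose DOF + per-residue rotamer selection (bijective)."""
        genes = np.asarray(genes, dtype=np.int64)
        if np.any(genes < 0) or np.any(genes >= self.cardinalities):
            raise RuntimeError("chromosome gene out of range: population corrupted")
        nb = len(self.flexible_bonds)
        dof = PoseDOF(
            translation=self.space.lattice_points[genes[0]],
            orientation=genes[1:4] * self.rot_step,
            dihedrals=genes[4 : 4 + nb] * self.dih_step,
        )
        return dof, [int(g) for g in genes[4 + nb :]]

    def encode(self, dof: PoseDOF, rotamers: Sequence[int]) -> np.ndarray:
        """Inverse of :meth:`decode` for on-lattice, on-step DOF values."""
        d = np.linalg.norm(self.space.lattice_points - dof.translation, axis=1)
        g0 = int(np.argmin(d))
        ori = np.mod(np.round(dof.orientation / self.rot_step).astype(int), self.cardinalities[1:4])
        dih = np.mod(np.round(dof.dihedrals / self.dih_step).astype(int),
                     int(round(360.0 / self.dih_step)))
        return np.concatenate([[g0], ori, dih, np.asarray(rotamers, dtype=int)]).astype(np.int64)

    # -- evaluation ----------------------------------------------------------

    def ligand_coords(self, genes: np.ndarray) -> np.ndarray:
        dof, _ = self.decode(genes)
        return apply_dof(self.ligand, dof, flexible=self.flexible_bonds)

    def target_coords(self, genes: np.ndarray) -> np.ndarray:
        """Filtered target coordinates with flexible side chains posed."""
        coords = self._tgt_coords.copy()
        if self.flexible_residues:
            _, rot_sel = self.decode(genes)
            for fr, k in zip(self.flexible_residues, rot_sel):
                serials, rc = fr.rotamer(k)
                for serial, xyz in zip(serials, rc):
                    idx = self._serial_to_idx.get(serial)
                    if idx is not None:
                        coords[idx] = xyz
        return coords

    def evaluate(self, genes: np.ndarray) -> float:
        """Fitness of one chromosome: pose score + constraint penalties."""
        lig = self.ligand_coords(genes)
        tgt = self.target_coords(genes)
        total = float(score_arrays(lig, self._lig_vdw, tgt, self._tgt_vdw,
                                   self.scoring, self._lig_heavy))
        for c, (li, ti) in zip(self.constraints, self._constraint_idx):
            actual = float(np.linalg.norm(lig[li] - tgt[ti]))
            total += c.weight * (actual - c.distance) ** 2
        return total

    def evaluate_population(self, pop: np.ndarray) -> np.ndarray:
        """Vectorized fitness for a whole population (fast rigid path)."""
        if not self._rigid:
            return np.array([self.evaluate(g) for g in pop])
        trans = self.space.lattice_points[pop[:, 0]]
        angles = pop[:, 1:4] * self.rot_step
        rots = Rotation.from_euler("ZYX", angles, degrees=True)
        mats = rots.as_matrix()  # (n, 3, 3)
        lig = np.einsum("nij,aj->nai", mats, self._base_lig) + trans[:, None, :]
        scores = score_arrays(lig, self._lig_vdw, self._tgt_coords, self._tgt_vdw,
                              self.scoring, self._lig_heavy)
        scores = np.atleast_1d(np.asarray(scores, dtype=float))
        if self._constraint_idx:
            for c, (li, ti) in zip(self.constraints, self._constraint_idx):
                actual = np.linalg.norm(lig[:, li, :] - self._tgt_coords[ti], axis=1)
                scores = scores + c.weight * (actual - c.distance) ** 2
        return scores

    # -- digest --------------------------------------------------------------

    def config_digest(self) -> str:
        """Content hash over every non-GA parameter and input."""

        def arr(a: np.ndarray) -> list:
            return np.round(np.asarray(a, dtype=float), 6).tolist()

        payload = {
            "target": [
                (a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                 arr(a.coords), round(a.vdw_radius, 6), a.is_het, a.is_water)
                for a in self.target.atoms
            ],
            "ligand": {
                "coords": arr(self.ligand.coords),
                "elements": [a.element for a in self.ligand.atoms],
                "bonds": self.ligand.bonds,
                "anchor": self.ligand.anchor,
            },
            "space": {"spacing": round(self.space.spacing, 6),
                      "points": arr(self.space.lattice_points)},
            "scoring": {
                "permeability": round(self.scoring.permeability, 6),
                "include_het": self.scoring.include_het,
                "include_water": self.scoring.include_water,
                "solvent_term": self.scoring.solvent_term,
                "solvent_weight": round(self.scoring.solvent_weight, 6),
                "contact_scale": round(self.scoring.contact_scale, 6),
            },
            "constraints": [
                (c.ligand_atom, c.target_atom, round(c.distance, 6), round(c.weight, 6))
                for c in self.constraints
            ],
            "flexible_bonds": self.flexible_bonds,
            "flexible_residues": [(fr.chain_id, fr.res_seq) for fr in self.flexible_residues],
            "steps": {"rot": round(self.rot_step, 6), "dih": round(self.dih_step, 6)},
            "reference": None if self.reference is None else arr(self.reference),
        }
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# session state and results

@dataclass
class SessionState:
    """Resumable GA state: population, archive, RNG, generation counter."""

    config_digest: str
    rng_state: dict
    population: np.ndarray  # (n, n_genes) int64
    fitness: np.ndarray  # (n,) float
    generation: int
    status: str  # running | paused | stopped | aborted | done
    archive: dict[tuple, tuple[float, int]] = field(default_factory=dict)


@dataclass
class DockingResult:
    """One reported pose; ranks are 1..top_n with non-decreasing scores."""

    rank: int
    genes: np.ndarray
    coords: np.ndarray
    score: float
    rmsd_to_reference: Optional[float]
    hydrogen_bonds: list[tuple[int, int, float]]


def save_state(st: SessionState, path: str | Path) -> None:
    """Serialize a session state losslessly to JSON."""
    payload = {
        "config_digest": st.config_digest,
        "rng_state": st.rng_state,
        "population": st.population.tolist(),
        "fitness": [f.hex() for f in st.fitness.astype(float)],
        "generation": st.generation,
        "status": st.status,
        "archive": [
            {"genes": list(k), "fitness": v[0].hex(), "first_gen": v[1]}
            for k, v in st.archive.items()
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_state(path: str | Path) -> SessionState:
    """Load a session state; raises :class:`StateError` on corrupt files."""
    try:
        payload = json.loads(Path(path).read_text())
        return SessionState(
            config_digest=payload["config_digest"],
            rng_state=payload["rng_state"],
            population=np.array(payload["population"], dtype=np.int64),
            fitness=np.array([float.fromhex(f) for f in payload["fitness"]]),
            generation=int(payload["generation"]),
            status=payload["status"],
            archive={
                tuple(e["genes"]): (float.fromhex(e["fitness"]), int(e["first_gen"]))
                for e in payload["archive"]
            },
        )
    except (OSError, KeyError, ValueError, TypeError) as exc:
        raise StateError(f"cannot load session state from {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# the genetic algorithm

def _update_archive(archive: dict, pop: np.ndarray, fit: np.ndarray, gen: int) -> None:
    for genes, f in zip(pop, fit):
        key = tuple(int(g) for g in genes)
        if key not in archive:
            archive[key] = (float(f), gen)


def _top_results(ctx: DockingContext, archive: dict, top_n: int) -> list[DockingResult]:
    ranked = sorted(archive.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))[:top_n]
    results = []
    heavy = ctx._lig_heavy
    for rank, (genes_t, (fit, _gen)) in enumerate(ranked, start=1):
        genes = np.array(genes_t, dtype=np.int64)
        coords = ctx.ligand_coords(genes)
        rms = None
        if ctx.reference is not None:
            rms = rmsd(coords[heavy], ctx.reference[heavy])
        tgt_coords = ctx.target_coords(genes)
        posed_target = Structure(
            [Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                  xyz, a.vdw_radius, a.is_het, a.is_water)
             for a, xyz in zip(ctx.filtered.atoms, tgt_coords)],
            id=ctx.filtered.id,
        )
        hb = hydrogen_bonds(coords, ctx.ligand, posed_target)
        results.append(DockingResult(rank=rank, genes=genes, coords=coords, score=fit,
                                     rmsd_to_reference=rms, hydrogen_bonds=hb))
    return results


def _tournament(rng: np.random.Generator, fitness: np.ndarray) -> int:
    i, j = rng.integers(0, len(fitness), size=2)
    return int(i if fitness[i] <= fitness[j] else j)


def run(
    ga: GAParams,
    context: DockingContext,
    state: Optional[SessionState] = None,
    progress: Optional[Callable[[int, list[DockingResult]], None]] = None,
    control: Optional[Callable[[int], str]] = None,
) -> tuple[SessionState, list[DockingResult]]:
    """Run (or continue) a docking simulation for ``ga.n_generations``.

    ``progress`` is invoked every ``refresh_every`` generations with the
    current top results. ``control``, polled once per generation, may return
    "pause", "stop" or "abort" to interrupt: pause keeps everything for
    resumption, stop finalizes results and keeps the population, abort
    discards results. Continuing from a saved state requires an identical
    non-GA configuration (content digest check); only the population size
    may differ, in which case the population is resampled with a warning.
    """
    digest = context.config_digest()
    if state is not None:
        if state.config_digest != digest:
            raise ContinuationRefusedError(
                "continuation refused: a non-GA parameter changed since the state was saved"
            )
        rng = np.random.Generator(np.random.PCG64())
        rng.bit_generator.state = state.rng_state
        pop = state.population.copy()
        fitness = state.fitness.copy()
        archive = dict(state.archive)
        start_gen = state.generation
        if len(pop) != ga.n_chromosomes:
            warnings.warn(
                f"population size changed ({len(pop)} → {ga.n_chromosomes}); "
                "resampling from the saved population", stacklevel=2
            )
            idx = rng.integers(0, len(pop), size=ga.n_chromosomes)
            pop = pop[idx]
            fitness = context.evaluate_population(pop)
    else:
        rng = np.random.Generator(np.random.PCG64(ga.seed))
        pop = np.column_stack(
            [rng.integers(0, card, size=ga.n_chromosomes) for card in context.cardinalities]
        ).astype(np.int64)
        fitness = context.evaluate_population(pop)
        archive = {}
        start_gen = 0
        _update_archive(archive, pop, fitness, 0)

    n_genes = context.n_genes
    status = "running"
    end_gen = start_gen + ga.n_generations
    gen = start_gen
    for gen in range(start_gen + 1, end_gen + 1):
        if control is not None:
            verdict = control(gen)
            if verdict == "pause":
                status = "paused"
                gen -= 1
                break
            if verdict == "stop":
                status = "stopped"
                gen -= 1
                break
            if verdict == "abort":
                st = SessionState(digest, rng.bit_generator.state, pop, fitness,
                                  gen - 1, "aborted", archive)
                return st, []

        elite = pop[int(np.argmin(fitness))].copy()
        children = [elite]
        while len(children) < ga.n_chromosomes:
            p1 = pop[_tournament(rng, fitness)].copy()
            p2 = pop[_tournament(rng, fitness)].copy()
            if n_genes > 1 and rng.random() < ga.crossover_prob:
                cut = int(rng.integers(1, n_genes))
                p1[cut:], p2[cut:] = p2[cut:].copy(), p1[cut:].copy()
            children.append(p1)
            if len(children) < ga.n_chromosomes:
                children.append(p2)
        pop = np.array(children, dtype=np.int64)
        # per-gene uniform reset mutation (elite at row 0 is exempt)
        mask = rng.random(pop.shape) < ga.mutation_prob
        resets = np.column_stack(
            [rng.integers(0, card, size=len(pop)) for card in context.cardinalities]
        )
        mask[0, :] = False
        pop = np.where(mask, resets, pop)
        fitness = context.evaluate_population(pop)
        _update_archive(archive, pop, fitness, gen)
        if progress is not None and ga.refresh_every > 0 and gen % ga.refresh_every == 0:
            progress(gen, _top_results(context, archive, ga.top_n))
    else:
        status = "done"

    final = SessionState(digest, rng.bit_generator.state, pop, fitness, gen, status, archive)
    if status == "paused":
        return final, []
    return final, _top_results(context, archive, ga.top_n)
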