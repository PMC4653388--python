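"""Search-space lattice, chromosome codec, GA determinism and sessions."""

import warnings

import numpy as np
import pytest

from cleftdock import (
    Cleft,
    ConfigurationError,
    Constraint,
    ContinuationRefusedError,
    DockingContext,
    GAParams,
    GapSphere,
    ScoringParams,
    StateError,
    build_search_space,
    load_state,
    run,
    save_state,
)
from cleftdock.docking_engine import FlexibleResidue
from cleftdock.fixtures import (
    make_flex_residue,
    pocket_docking_setup,
    pocket_ga_params,
)
from cleftdock.scoring import score_pose


def lone_cleft(radius=3.5, center=(0, 0, 0)):
    sp = GapSphere(center=center, radius=radius)
    return Cleft(id=1, spheres=[sp], sphere_volume_sum=sp.volume)


@pytest.fixture(scope="module")
def pocket_setup(toy_pocket):
    return pocket_docking_setup(toy_pocket)


class TestSearchSpace:
    def test_lattice_count_matches_brute_force(self):
        space = build_search_space([lone_cleft()], spacing=1.0)
        grid = np.array(np.meshgrid(*[np.arange(-4, 5)] * 3, indexing="ij")).reshape(3, -1).T
        want = int(np.sum(np.linalg.norm(grid, axis=1) <= 3.5))
        assert len(space) == want == 179

    def test_disjoint_clefts_are_additive(self):
        c1 = lone_cleft(center=(0, 0, 0))
        c2 = lone_cleft(center=(100, 0, 0))
        n1 = len(build_search_space([c1], 1.0))
        n2 = len(build_search_space([c2], 1.0))
        both = build_search_space([c1, c2], 1.0)
        assert len(both) == n1 + n2
        assert both.source_cleft_ids == [1, 1]

    def test_points_unique_and_ordered(self):
        space = build_search_space([lone_cleft()], 1.0)
        pts = space.lattice_points
        assert len(np.unique(pts, axis=0)) == len(pts)
        order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
        np.testing.assert_array_equal(order, np.arange(len(pts)))

    def test_oversized_spacing_rejected(self):
        # a sphere that straddles no multiple of the spacing yields no points
        off_origin = lone_cleft(center=(10.0, 10.0, 10.0))
        with pytest.raises(ConfigurationError):
            build_search_space([off_origin], spacing=100.0)

    def test_every_point_inside_some_sphere(self, pocket_setup):
        cleft, space, _ = pocket_setup
        d = np.linalg.norm(
            space.lattice_points[:, None, :] - cleft.centers[None, :, :], axis=-1
        )
        assert np.all((d <= cleft.radii[None, :]).any(axis=1))


class TestCodec:
    def test_all_zero_genes(self, pocket_setup):
        _, space, ctx = pocket_setup
        dof, rot = ctx.decode(np.zeros(ctx.n_genes, dtype=int))
        np.testing.assert_array_equal(dof.translation, space.lattice_points[0])
        np.testing.assert_array_equal(dof.orientation, np.zeros(3))
        assert rot == []

    def test_rotation_gene_times_step(self, pocket_setup):
        _, _, ctx = pocket_setup
        genes = np.zeros(ctx.n_genes, dtype=int)
        genes[1] = 6
        dof, _ = ctx.decode(genes)
        assert dof.orientation[0] == pytest.approx(6 * ctx.rot_step)

    @pytest.mark.parametrize("seed", range(5))
    def test_decode_encode_round_trip(self, pocket_setup, seed):
        _, _, ctx = pocket_setup
        rng = np.random.default_rng(seed)
        genes = np.array([rng.integers(0, c) for c in ctx.cardinalities])
        dof, rot = ctx.decode(genes)
        np.testing.assert_array_equal(ctx.encode(dof, rot), genes)

    def test_out_of_range_gene_is_internal_error(self, pocket_setup):
        _, _, ctx = pocket_setup
        genes = np.zeros(ctx.n_genes, dtype=int)
        genes[0] = ctx.cardinalities[0]
        with pytest.raises(RuntimeError):
            ctx.decode(genes)


class TestEvaluate:
    def test_reference_chromosome_equals_direct_score(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        genes = ctx.encode(toy_pocket.planted, [])
        lig_vdw = np.array([a.vdw_radius for a in toy_pocket.ligand.atoms])
        direct = score_pose(
            ctx.ligand_coords(genes), toy_pocket.target, ctx.scoring,
            ligand_vdw=lig_vdw,
            ligand_heavy=np.ones(len(lig_vdw), bool),
        )
        assert ctx.evaluate(genes) == pytest.approx(direct, rel=1e-12)

    def test_constraint_violation_is_additive(self, toy_pocket, pocket_setup):
        cleft, space, ctx = pocket_setup
        genes = ctx.encode(toy_pocket.planted, [])
        coords = ctx.ligand_coords(genes)
        tgt_atom = toy_pocket.target.atoms[0]
        actual = float(np.linalg.norm(coords[0] - tgt_atom.coords))
        con = Constraint(0, tgt_atom.serial, distance=actual + 1.0, weight=10.0)
        ctx_con = DockingContext(
            toy_pocket.target, toy_pocket.ligand, space, constraints=[con],
            flexible_bonds=[], rot_step=ctx.rot_step, dih_step=ctx.dih_step,
        )
        assert ctx_con.evaluate(genes) == pytest.approx(ctx.evaluate(genes) + 10.0)

    def test_batch_matches_scalar_path(self, pocket_setup):
        _, _, ctx = pocket_setup
        rng = np.random.default_rng(0)
        pop = np.column_stack(
            [rng.integers(0, c, size=16) for c in ctx.cardinalities]
        )
        batch = ctx.evaluate_population(pop)
        scalar = np.array([ctx.evaluate(g) for g in pop])
        np.testing.assert_allclose(batch, scalar, rtol=1e-12)


class TestRun:
    def test_deterministic_and_ranked(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=3, n_chromosomes=60, n_generations=12)
        st1, res1 = run(ga, ctx)
        st2, res2 = run(ga, ctx)
        np.testing.assert_array_equal(st1.population, st2.population)
        assert [r.score for r in res1] == [r.score for r in res2]
        scores = [r.score for r in res1]
        assert scores == sorted(scores)
        assert [r.rank for r in res1] == list(range(1, len(res1) + 1))

    def test_unique_genomes_in_results(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=3, n_chromosomes=60, n_generations=12)
        _, res = run(ga, ctx)
        genomes = {tuple(r.genes) for r in res}
        assert len(genomes) == len(res)

    def test_elitism_best_never_worsens(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        bests = []

        def progress(gen, top):
            bests.append(top[0].score)

        ga = GAParams(n_chromosomes=60, n_generations=15, seed=5, refresh_every=1,
                      crossover_prob=0.8, mutation_prob=0.15)
        run(ga, ctx, progress=progress)
        assert all(a >= b for a, b in zip(bests, bests[1:]))

    def test_anchor_stays_inside_search_space(self, toy_pocket, pocket_setup):
        cleft, space, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=2, n_chromosomes=60, n_generations=12)
        _, res = run(ga, ctx)
        anchor_idx = toy_pocket.ligand.anchor
        for r in res:
            anchor = r.coords[anchor_idx]
            d = np.linalg.norm(cleft.centers - anchor, axis=1)
            assert np.any(d <= cleft.radii + 1e-9)

    def test_continuation_equals_single_long_run(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        ga_g = pocket_ga_params(toy_pocket, seed=11, n_chromosomes=50, n_generations=8)
        ga_2g = pocket_ga_params(toy_pocket, seed=11, n_chromosomes=50, n_generations=16)
        st_a, _ = run(ga_g, ctx)
        st_b, res_b = run(ga_g, ctx, state=st_a)
        st_c, res_c = run(ga_2g, ctx)
        assert st_b.generation == st_c.generation == 16
        np.testing.assert_array_equal(st_b.population, st_c.population)
        np.testing.assert_array_equal(st_b.fitness, st_c.fitness)
        assert [tuple(r.genes) for r in res_b] == [tuple(r.genes) for r in res_c]
        assert [r.score for r in res_b] == [r.score for r in res_c]

    def test_continuation_refused_when_scoring_changes(self, toy_pocket, pocket_setup):
        _, space, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=1, n_chromosomes=40, n_generations=5)
        st, _ = run(ga, ctx)
        changed = DockingContext(
            toy_pocket.target, toy_pocket.ligand, space,
            scoring=ScoringParams(permeability=0.25),
            flexible_bonds=[], rot_step=ctx.rot_step, dih_step=ctx.dih_step,
        )
        with pytest.raises(ContinuationRefusedError):
            run(ga, changed, state=st)

    def test_population_resize_resamples_with_warning(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=1, n_chromosomes=40, n_generations=5)
        st, _ = run(ga, ctx)
        bigger = pocket_ga_params(toy_pocket, seed=1, n_chromosomes=80, n_generations=3)
        with pytest.warns(UserWarning, match="population size changed"):
            st2, _ = run(bigger, ctx, state=st)
        assert len(st2.population) == 80

    def test_abort_discards_results(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=1, n_chromosomes=40, n_generations=10)
        st, res = run(ga, ctx, control=lambda gen: "abort" if gen > 3 else "run")
        assert st.status == "aborted" and res == []

    def test_pause_preserves_resumability(self, toy_pocket, pocket_setup):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=9, n_chromosomes=40, n_generations=10)
        st_pause, res = run(ga, ctx, control=lambda gen: "pause" if gen > 5 else "run")
        assert st_pause.status == "paused" and res == []
        remaining = pocket_ga_params(toy_pocket, seed=9, n_chromosomes=40,
                                     n_generations=10 - st_pause.generation)
        st_done, _ = run(remaining, ctx, state=st_pause)
        st_ref, _ = run(ga, ctx)
        np.testing.assert_array_equal(st_done.population, st_ref.population)


class TestSessionState:
    def test_save_load_round_trip(self, toy_pocket, pocket_setup, tmp_path):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=4, n_chromosomes=30, n_generations=4)
        st, _ = run(ga, ctx)
        path = tmp_path / "session.json"
        save_state(st, path)
        back = load_state(path)
        assert back.config_digest == st.config_digest
        assert back.generation == st.generation and back.status == st.status
        np.testing.assert_array_equal(back.population, st.population)
        np.testing.assert_array_equal(back.fitness, st.fitness)
        assert back.rng_state == st.rng_state
        assert back.archive == st.archive

    def test_tampered_digest_refused_downstream(self, toy_pocket, pocket_setup, tmp_path):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=4, n_chromosomes=30, n_generations=4)
        st, _ = run(ga, ctx)
        st.config_digest = "0" * 64
        with pytest.raises(ContinuationRefusedError):
            run(ga, ctx, state=st)

    def test_corrupt_file_is_state_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(StateError):
            load_state(path)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_populations_round_trip_bit_identically(
        self, toy_pocket, pocket_setup, tmp_path, seed
    ):
        _, _, ctx = pocket_setup
        ga = pocket_ga_params(toy_pocket, seed=seed, n_chromosomes=25, n_generations=3)
        st, _ = run(ga, ctx)
        path = tmp_path / f"s{seed}.json"
        save_state(st, path)
        save_state(load_state(path), tmp_path / f"s{seed}b.json")
        assert (tmp_path / f"s{seed}.json").read_bytes() == (
            tmp_path / f"s{seed}b.json"
        ).read_bytes()


class TestFlexibleResidue:
    def test_serine_has_one_chi_and_four_rotamers(self):
        s = make_flex_residue()
        fr = FlexibleResidue(s, "B", 1)
        assert len(fr._chi_axes) == 1
        assert fr.n_rotamers == 4  # input conformation + three chi values

    def test_rotamer_zero_is_input_conformation(self):
        s = make_flex_residue()
        fr = FlexibleResidue(s, "B", 1)
        serials, coords = fr.rotamer(0)
        np.testing.assert_allclose(coords, [a.coords for a in s.atoms])

    def test_only_og_moves(self):
        s = make_flex_residue()
        fr = FlexibleResidue(s, "B", 1)
        names = [a.name for a in s.atoms]
        og = names.index("OG")
        base = np.array([a.coords for a in s.atoms])
        for k in range(1, fr.n_rotamers):
            _, coords = fr.rotamer(k)
            still = [i for i in range(len(names)) if i != og]
            np.testing.assert_allclose(coords[still], base[still], atol=1e-9)
        moved = [np.linalg.norm(fr.rotamer(k)[1][og] - base[og]) for k in (1, 2, 3)]
        assert sum(m > 0.2 for m in moved) >= 2  # one chi value may equal the input

    def test_rotamer_preserves_bond_length(self):
        s = make_flex_residue()
        fr = FlexibleResidue(s, "B", 1)
        names = [a.name for a in s.atoms]
        cb, og = names.index("CB"), names.index("OG")
        want = np.linalg.norm(s.atoms[cb].coords - s.atoms[og].coords)
        for k in range(fr.n_rotamers):
            _, coords = fr.rotamer(k)
            assert np.linalg.norm(coords[cb] - coords[og]) == pytest.approx(want, abs=1e-9)

    def test_rotamer_gene_moves_target_side_chain(self, toy_pocket):
        # a flexible residue far from the pocket: fitness must change with
        # the rotamer gene only through the moved side-chain coordinates
        from cleftdock.structure_io import Structure

        extra = make_flex_residue(res_seq=99, chain="B", offset=(6.0, 0.0, 0.0))
        merged = Structure(
            toy_pocket.target.atoms
            + [type(a)(a.serial + 100, a.name, a.element, a.res_name, a.res_seq,
                       a.chain_id, a.coords, a.vdw_radius) for a in extra.atoms],
            id="merged",
        )
        fr = FlexibleResidue(merged, "B", 99)
        from cleftdock.fixtures import pocket_docking_setup

        cleft, space, _ = pocket_docking_setup(toy_pocket)
        ctx = DockingContext(
            merged, toy_pocket.ligand, space, flexible_bonds=[],
            flexible_residues=[fr], rot_step=15.0,
        )
        genes = np.zeros(ctx.n_genes, dtype=int)
        f0 = ctx.evaluate(genes)
        genes[-1] = 1
        f1 = ctx.evaluate(genes)
        assert f0 != f1
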