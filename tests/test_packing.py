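import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberpack import (
    DensityTrace,
    GammaDiameterModel,
    PackingConfig,
    PackingState,
    build_population,
    compute_gap_matrix,
    compute_velocities,
    convergence_variation,
    initialize_grid,
    run_packing,
    step,
)
from fiberpack._kernel import migrate

CONFIG = PackingConfig(iter_max=100, trace_every=10, seed=0)


def python_oracle_velocities(state: PackingState, config: PackingConfig) -> np.ndarray:
    """Brute-force O(N^2) per-disk loop, independent of the library paths."""
    pos = state.positions
    r = state.packing_diameters / 2.0
    cx, cy = state.domain_center
    vel = np.zeros_like(pos)
    for k in range(len(r)):
        overlappers = []
        for j in range(len(r)):
            if j == k:
                continue
            dx, dy = pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1]
            if np.sqrt(dx * dx + dy * dy) - (r[k] + r[j] + state.delta) < 0:
                overlappers.append(j)
        if not overlappers:
            dx, dy = cx - pos[k, 0], cy - pos[k, 1]
            nrm = np.sqrt(dx * dx + dy * dy)
            if nrm > 1e-12:
                vel[k] = (config.v_att * dx / nrm, config.v_att * dy / nrm)
        else:
            sx = sy = 0.0
            for j in overlappers:
                dx, dy = pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if d > 1e-12:
                    sx += dx / d
                    sy += dy / d
            nrm = np.sqrt(sx * sx + sy * sy)
            if nrm > 1e-12:
                vel[k] = (config.v_rep * sx / nrm, config.v_rep * sy / nrm)
    return vel


def random_state(n: int, seed: int, delta: float = 0.0) -> PackingState:
    rng = np.random.default_rng(seed)
    d = rng.gamma(9.0, 1 / 3.0, size=n).clip(0.2, 10.0)
    # box small enough that a good fraction of pairs overlap
    pos = rng.uniform(-8, 8, size=(n, 2))
    return PackingState(positions=pos, packing_diameters=d, delta=delta)


class TestConfig:
    def test_repulsion_must_dominate_attraction(self):
        with pytest.raises(ValueError):
            PackingConfig(iter_max=10, v_att=0.1, v_rep=0.05)

    def test_positive_iterations_required(self):
        with pytest.raises(ValueError):
            PackingConfig(iter_max=0)


class TestInitialization:
    def test_monodisperse_domain_area(self):
        # area = N * (2*max radius + delta)^2; 250 disks of diameter 4, zero gap
        pop = build_population(np.full(250, 4.0), pack_on="inner")
        state = initialize_grid(pop, CONFIG)
        assert state.domain_side**2 == pytest.approx(250 * 4.0**2)

    def test_single_disk(self):
        pop = build_population([3.0])
        state = initialize_grid(pop, CONFIG)
        assert state.n == 1
        assert np.isfinite(state.positions).all()

    @pytest.mark.parametrize("n,seed,delta", [(250, 0, 0.0), (100, 3, 0.5), (37, 8, 0.0)])
    def test_no_initial_overlap(self, n, seed, delta):
        model = GammaDiameterModel(3.0, 1.0)
        pop = build_population(model.sample(n, seed=seed), delta=delta)
        state = initialize_grid(pop, PackingConfig(iter_max=10, seed=seed))
        assert compute_gap_matrix(state).min() >= 0

    def test_monodisperse_contact_lattice_does_not_overlap(self):
        pop = build_population(np.full(64, 4.0), pack_on="inner")
        state = initialize_grid(pop, CONFIG)
        assert compute_gap_matrix(state).min() >= 0

    def test_seed_controls_layout(self):
        pop = build_population(GammaDiameterModel(3.0, 1.0).sample(50, seed=0))
        s1 = initialize_grid(pop, PackingConfig(iter_max=10, seed=1))
        s2 = initialize_grid(pop, PackingConfig(iter_max=10, seed=2))
        assert not np.array_equal(s1.positions, s2.positions)


class TestGapMatrix:
    def test_separated_pair(self):
        state = PackingState(
            positions=[[0.0, 0.0], [3.0, 0.0]], packing_diameters=[2.0, 2.0], delta=0.0
        )
        p = compute_gap_matrix(state)
        assert p[0, 1] == pytest.approx(1.0)

    def test_overlapping_pair(self):
        state = PackingState(
            positions=[[0.0, 0.0], [1.5, 0.0]], packing_diameters=[2.0, 2.0], delta=0.0
        )
        assert compute_gap_matrix(state)[0, 1] == pytest.approx(-0.5)

    def test_gap_includes_delta(self):
        state = PackingState(
            positions=[[0.0, 0.0], [3.0, 0.0]], packing_diameters=[2.0, 2.0], delta=0.4
        )
        assert compute_gap_matrix(state)[0, 1] == pytest.approx(0.6)

    def test_symmetry(self):
        state = random_state(15, seed=2)
        p = compute_gap_matrix(state)
        assert np.array_equal(p, p.T)


class TestVelocities:
    def test_lone_disk_attracted_at_fixed_speed(self):
        state = PackingState(positions=[[10.0, 0.0]], packing_diameters=[1.0], delta=0.0)
        vel = compute_velocities(state, CONFIG)
        assert vel[0] == pytest.approx([-0.01, 0.0])

    def test_overlapping_pair_repelled_at_fixed_speed(self):
        state = PackingState(
            positions=[[0.0, 0.0], [1.0, 0.0]], packing_diameters=[2.0, 2.0], delta=0.0
        )
        vel = compute_velocities(state, CONFIG)
        assert vel[0] == pytest.approx([-0.1, 0.0])
        assert vel[1] == pytest.approx([0.1, 0.0])

    def test_disk_at_center_stays(self):
        state = PackingState(positions=[[0.0, 0.0]], packing_diameters=[1.0], delta=0.0)
        assert np.array_equal(compute_velocities(state, CONFIG), [[0.0, 0.0]])

    def test_symmetric_overlaps_cancel(self):
        state = PackingState(
            positions=[[0.0, 0.0], [0.0, 1.0], [0.0, -1.0]],
            packing_diameters=[2.0, 2.0, 2.0],
            delta=0.0,
        )
        vel = compute_velocities(state, CONFIG)
        assert vel[0] == pytest.approx([0.0, 0.0], abs=1e-15)

    def test_translation_invariance_of_velocities(self):
        state = random_state(25, seed=4)
        shift = np.array([37.5, -12.25])
        shifted = PackingState(
            positions=state.positions + shift,
            packing_diameters=state.packing_diameters,
            delta=0.0,
            domain_center=tuple(shift),
        )
        v0 = compute_velocities(state, CONFIG)
        v1 = compute_velocities(shifted, CONFIG)
        assert np.allclose(v0, v1, atol=1e-9)


class TestStep:
    def test_resting_configuration_is_fixed_point(self):
        state = PackingState(positions=[[0.0, 0.0]], packing_diameters=[1.0], delta=0.0)
        assert np.array_equal(step(state, CONFIG).positions, state.positions)

    def test_lone_disk_approaches_center_by_v_att(self):
        state = PackingState(positions=[[5.0, 0.0]], packing_diameters=[1.0], delta=0.0)
        new = step(state, CONFIG)
        assert new.positions[0, 0] == pytest.approx(4.99)
        assert new.iteration == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_step_matches_python_oracle_exactly(self, seed):
        state = random_state(20, seed=seed)
        expected = state.positions + python_oracle_velocities(state, CONFIG)
        assert np.array_equal(step(state, CONFIG).positions, expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kernel_matches_step_bit_for_bit(self, seed):
        """Cell-list kernel and the numpy reference must agree exactly."""
        state = random_state(40, seed=seed)
        pos = np.ascontiguousarray(state.positions)
        eff = np.ascontiguousarray(state.effective_radii)
        for _ in range(20):
            state = step(state, CONFIG)
        migrate(pos, eff, 0.0, 0.0, CONFIG.v_att, CONFIG.v_rep, 20)
        assert np.array_equal(pos, state.positions)


class TestRunPacking:
    def test_trace_bookkeeping(self, small_run):
        _, _, trace = small_run
        assert len(trace) == 5000 // 1000 + 1
        assert trace.iterations[0] == 0
        assert np.all(np.diff(trace.iterations) > 0)

    def test_deterministic_for_fixed_seed(self):
        pop = build_population(GammaDiameterModel(3.0, 1.0).sample(60, seed=2))
        cfg = PackingConfig(iter_max=400, trace_every=200, seed=2)
        s1, t1 = run_packing(pop, cfg)
        s2, t2 = run_packing(pop, cfg)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(t1.fvf, t2.fvf)

    def test_density_increases_from_grid(self, small_run):
        _, _, trace = small_run
        assert trace.fvf[-1] > trace.fvf[0]

    def test_short_trajectory_translation_invariant(self):
        pop = build_population(GammaDiameterModel(3.0, 1.0).sample(40, seed=6))
        cfg = PackingConfig(iter_max=300, trace_every=300, seed=6)
        state = initialize_grid(pop, cfg)
        shift = np.array([50.0, -30.0])
        pos0 = np.ascontiguousarray(state.positions)
        pos1 = np.ascontiguousarray(state.positions + shift)
        eff = np.ascontiguousarray(state.effective_radii)
        migrate(pos0, eff, 0.0, 0.0, cfg.v_att, cfg.v_rep, 300)
        migrate(pos1, eff, shift[0], shift[1], cfg.v_att, cfg.v_rep, 300)
        assert np.allclose(pos1 - shift, pos0, atol=1e-6)


class TestConvergenceVariation:
    def test_constant_trace(self):
        trace = DensityTrace(np.arange(0, 1000, 100), np.full(10, 0.8))
        assert convergence_variation(trace, 0, 900) == 0.0

    def test_printed_example(self):
        trace = DensityTrace(np.array([26000, 35000]), np.array([0.8440, 0.8449]))
        assert convergence_variation(trace, 26000, 35000) == pytest.approx(0.0009)

    def test_empty_window_errors(self):
        trace = DensityTrace(np.array([0, 100]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            convergence_variation(trace, 500, 600)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 5), st.integers(6, 12))
    def test_window_variation_bounded_by_global(self, lo, hi):
        rng = np.random.default_rng(0)
        fvf = rng.uniform(0.5, 0.9, size=13)
        trace = DensityTrace(np.arange(13) * 100, fvf)
        v = convergence_variation(trace, lo * 100, hi * 100)
        assert 0 <= v <= fvf.max() - fvf.min()
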