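import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neqswitch as nq
from neqswitch.analysis import (
    ExpFit,
    FitDegenerateError,
    StokesSeries,
    compare_charge_sets,
    count_first_shell,
    delta_delta_a,
    delta_n_waters,
    differential_dipole,
    dipole_angle,
    evaluate_fit_at,
    fit_mono_exponential,
    mad_and_spread,
    rmsd_q,
    stokes_relaxation,
)
from neqswitch.charges import ChargeSet


def charge_set(values, net=None):
    v = np.asarray(values, float)
    return ChargeSet(charges=v, net_charge=float(v.sum()) if net is None else net)


same_length_charges = st.integers(2, 6).flatmap(
    lambda n: st.tuples(
        *[
            st.lists(st.floats(-1, 1, allow_nan=False), min_size=n, max_size=n)
            for _ in range(3)
        ]
    )
)


class TestDeltaDeltaA:
    def test_equal_estimate_and_reference_give_zero(self):
        assert delta_delta_a(0.7, 0.7) == 0.0

    def test_correction_arithmetic(self):
        assert delta_delta_a(0.3, 0.6, correction=0.5) == pytest.approx(0.2)


class TestChargeMetrics:
    def test_rmsd_examples(self):
        assert rmsd_q(charge_set([0.1]), charge_set([0.1])) == 0.0
        assert rmsd_q(charge_set([0.3]), charge_set([0.1])) == pytest.approx(0.2)
        a = charge_set([0.3, -0.1])
        b = charge_set([0.0, 0.0])
        assert rmsd_q(a, b) == pytest.approx(np.sqrt(0.05))

    def test_rmsd_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd_q(charge_set([0.1]), charge_set([0.1, 0.0]))

    @settings(deadline=None, max_examples=50)
    @given(same_length_charges)
    def test_rmsd_triangle_inequality(self, triple):
        a, b, c = (charge_set(v) for v in triple)
        assert rmsd_q(a, c) <= rmsd_q(a, b) + rmsd_q(b, c) + 1e-12

    def test_differential_dipole_hand_example(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        a = charge_set([0.1, -0.1])
        b = charge_set([0.0, 0.0])
        vec, mag = differential_dipole(a, b, coords)
        np.testing.assert_allclose(vec, [-0.1, 0.0, 0.0], atol=1e-15)
        assert mag == pytest.approx(0.480320, abs=1e-6)

    def test_differential_dipole_translation_invariance_for_neutral_diff(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, -1.0]])
        a, b = charge_set([0.1, -0.1]), charge_set([0.25, -0.25])
        v1, _ = differential_dipole(a, b, coords)
        v2, _ = differential_dipole(a, b, coords + np.array([5.0, -3.0, 2.0]))
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_identical_sets_give_zero_vector(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        a = charge_set([0.1, -0.1])
        vec, mag = differential_dipole(a, a, coords)
        assert mag == 0.0

    @pytest.mark.parametrize(
        "qa,qb,expected",
        [
            ([0.1, -0.1], [0.1, -0.1], 0.0),
            ([0.1, -0.1], [-0.1, 0.1], 180.0),
        ],
    )
    def test_dipole_angle_parallel_antiparallel(self, qa, qb, expected):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert dipole_angle(charge_set(qa), charge_set(qb), coords) == pytest.approx(
            expected
        )

    def test_dipole_angle_orthogonal(self):
        coords = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
        )
        a = charge_set([-0.1, 0.1, 0.0])  # dipole along x
        b = charge_set([-0.1, 0.0, 0.1])  # dipole along y
        assert dipole_angle(a, b, coords) == pytest.approx(90.0)

    def test_zero_dipole_angle_undefined(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            dipole_angle(charge_set([0.0, 0.0]), charge_set([0.1, -0.1]), coords)

    def test_compare_charge_sets_bundles_metrics(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        cmp_ = compare_charge_sets(charge_set([0.2, -0.2]), charge_set([0.1, -0.1]), coords)
        assert cmp_.rmsd_q == pytest.approx(0.1)
        assert cmp_.theta == pytest.approx(0.0, abs=1e-9)


class TestFirstShell:
    @pytest.mark.parametrize(
        "distance,expected", [(2.5, 1), (3.0, 1), (3.01, 0)]
    )
    def test_inclusive_cutoff_rule(self, distance, expected):
        solute = np.array([[0.0, 0.0, 0.0]])
        solvent = np.array([[distance, 0.0, 0.0]])
        assert count_first_shell(solvent, solute, cutoff=3.0) == expected

    def test_heavy_mask_restricts_solute_sites(self):
        solute = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        solvent = np.array([[5.0, 2.0, 0.0]])
        assert count_first_shell(solvent, solute, 3.0) == 1
        assert count_first_shell(
            solvent, solute, 3.0, heavy_mask=np.array([True, False])
        ) == 0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            count_first_shell(np.zeros((1, 3)), np.zeros((1, 3)), cutoff=0.0)

    def test_delta_n_waters_identical_trajectories(self):
        solute = np.zeros((1, 3))
        frames = [np.array([[1.0, 0, 0], [2.0, 0, 0]])] * 3
        assert delta_n_waters(frames, frames, solute) == 0.0

    def test_delta_n_waters_hand_built_frames(self):
        solute = np.zeros((1, 3))
        one = np.array([[1.0, 0, 0], [9.0, 0, 0]])  # 1 in shell
        two = np.array([[1.0, 0, 0], [2.0, 0, 0]])  # 2 in shell
        assert delta_n_waters([one, one], [two, two], solute) == pytest.approx(-1.0)

    def test_delta_n_waters_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            delta_n_waters([], [np.zeros((1, 3))], np.zeros((1, 3)))


class TestStokesRelaxation:
    def test_constant_series_shifts_to_zero(self):
        times = np.arange(100.0)
        series = stokes_relaxation(np.full((1, 100), 3.7), times)
        np.testing.assert_allclose(series.shifted, 0.0, atol=1e-12)

    def test_opposite_trajectories_cancel(self):
        times = np.arange(50.0)
        f = np.sin(times / 10.0)
        series = stokes_relaxation(np.vstack([f, -f]), times)
        np.testing.assert_allclose(series.mean_gap, 0.0, atol=1e-12)

    def test_default_baseline_window_covers_last_fifth(self):
        """A 10 ps series sampled every fs averages its last 2000 entries."""
        times = np.arange(1.0, 10001.0)
        values = np.linspace(5.0, 1.0, 10000)
        series = stokes_relaxation(values[None, :], times)
        assert series.baseline == pytest.approx(values[-2000:].mean())

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            stokes_relaxation(np.zeros((1, 10)), np.arange(10.0), (100.0, 200.0))

    def test_shifted_is_mean_minus_baseline(self):
        times = np.arange(20.0)
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 20))
        series = stokes_relaxation(data, times)
        np.testing.assert_allclose(
            series.shifted, data.mean(axis=0) - series.baseline, atol=1e-14
        )


class TestMonoExponentialFit:
    def test_exact_recovery_on_noiseless_decay(self):
        times = np.arange(0.0, 6000.0)
        series = StokesSeries(
            times=times, mean_gap=4.0 * np.exp(-times / 1000.0),
            baseline=0.0, n_trajectories=1,
        )
        fit = fit_mono_exponential(series, discard=500.0)
        assert fit.amplitude == pytest.approx(4.0, abs=1e-6)
        assert fit.tau == pytest.approx(1000.0, abs=1e-3)

    def test_discard_suppresses_fast_component(self):
        """With the first 0.5 ps removed, a two-timescale decay fits to the
        slow time constant."""
        times = np.arange(0.0, 8000.0)
        gap = 10.0 * np.exp(-times / 100.0) + 4.0 * np.exp(-times / 1000.0)
        series = StokesSeries(times=times, mean_gap=gap, baseline=0.0, n_trajectories=1)
        fit = fit_mono_exponential(series, discard=500.0)
        assert fit.tau == pytest.approx(1000.0, rel=0.10)

    def test_noisy_ensemble_average_recovers_parameters(self):
        """800 noisy trajectories (σ = 0.1) recover (ΔU0, τ) within 5 %."""
        rng = np.random.default_rng(3)
        times = np.arange(0.0, 8000.0)
        clean = 4.0 * np.exp(-times / 1000.0)
        data = clean[None, :] + rng.normal(0.0, 0.1, size=(800, times.size))
        series = stokes_relaxation(data, times, baseline_window=(7000.0, 7999.0))
        fit = fit_mono_exponential(series, discard=500.0)
        assert fit.amplitude == pytest.approx(4.0, rel=0.05)
        assert fit.tau == pytest.approx(1000.0, rel=0.05)

    def test_negative_series_is_degenerate(self):
        times = np.arange(0.0, 2000.0)
        series = StokesSeries(
            times=times, mean_gap=-np.ones_like(times), baseline=0.0, n_trajectories=1
        )
        with pytest.raises(FitDegenerateError):
            fit_mono_exponential(series, discard=500.0)

    def test_too_few_points_rejected(self):
        series = StokesSeries(
            times=np.arange(5.0), mean_gap=np.exp(-np.arange(5.0)),
            baseline=0.0, n_trajectories=1,
        )
        with pytest.raises(FitDegenerateError):
            fit_mono_exponential(series, discard=0.0)


class TestEvaluateFit:
    def test_t_zero_returns_amplitude(self):
        fit = ExpFit(amplitude=3.3, tau=800.0, discard_window=500.0, fit_rss=0.0)
        assert evaluate_fit_at(fit, 0.0) == pytest.approx(3.3)

    def test_hand_example(self):
        fit = ExpFit(amplitude=10.5, tau=1000.0, discard_window=500.0, fit_rss=0.0)
        assert evaluate_fit_at(fit, 2000.0) == pytest.approx(10.5 * np.exp(-2), abs=1e-9)

    def test_monotone_decreasing_for_positive_amplitude(self):
        fit = ExpFit(amplitude=2.0, tau=500.0, discard_window=0.0, fit_rss=0.0)
        values = [evaluate_fit_at(fit, t) for t in np.linspace(0, 5000, 20)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert evaluate_fit_at(fit, 1e9) == pytest.approx(0.0, abs=1e-12)


class TestMadAndSpread:
    def test_mixed_signs(self):
        s = mad_and_spread([0.1, -0.2, 0.3])
        assert (s.mad, s.spread_min, s.spread_max) == pytest.approx((0.2, 0.1, 0.3))

    def test_all_zero(self):
        s = mad_and_spread([0.0, 0.0])
        assert (s.mad, s.spread_min, s.spread_max) == (0.0, 0.0, 0.0)

    def test_singleton(self):
        s = mad_and_spread([-1.8])
        assert (s.mad, s.spread_min, s.spread_max) == pytest.approx((1.8, 1.8, 1.8))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad_and_spread([])


class TestBathRelaxationInvariants:
    def test_mm_and_intermediate_starts_share_tau_but_not_amplitude(
        self, stokes_benchmark_results
    ):
        """Bath reorientation time is a solvent property (τ agrees within 25 %
        between MM-start and intermediate-start ensembles) while the initial
        amplitude ΔU0 tracks the charge mismatch and is much larger for MM."""
        r = stokes_benchmark_results
        assert r["du0_mm"] > r["du0_mull"] > 0
        assert abs(r["tau_mm"] - r["tau_mull"]) <= 0.25 * max(
            r["tau_mm"], r["tau_mull"]
        )

    def test_high_level_starts_show_no_transient(self):
        """Relaxation ensembles started at high-level equilibrium have a flat
        ΔΔU(t): block means consistent with zero."""
        system = nq.polar_solute_64rotors()
        settings = nq.SamplerSettings(
            n_equil_steps=25000, n_prod_steps=26000, save_every=2000,
            n_replicates=8, seed=17,
        )
        pool = nq.sample_equilibrium(system, 1.0, settings)
        gaps = nq.relax_gap_ensemble(system, pool, n_steps=3000, seed=18)
        times = np.arange(3001.0)
        series = stokes_relaxation(gaps, times)
        # block-average the shifted series; each block mean should be within
        # ~3 stderr of zero (stderr from the trajectory scatter)
        n_blocks = 6
        for block in np.array_split(np.arange(times.size), n_blocks):
            block_mean = series.shifted[block].mean()
            per_traj = gaps[:, block].mean(axis=1)
            stderr = per_traj.std(ddof=1) / np.sqrt(gaps.shape[0])
            assert abs(block_mean) < 3.5 * stderr
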