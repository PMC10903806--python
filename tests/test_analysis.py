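"""Tests for similarity indicators, pleiotropy, clone variance, timescales."""

import numpy as np
import pytest

from devhourglass import (
    Trajectory,
    clone_variance,
    gene_timescales,
    pleiotropy_fraction,
    similarity_delta,
    similarity_matrix,
    similarity_pearson,
    slow_genes,
    timescale_bottleneck_correlation,
)
from devhourglass.analysis import (
    DELTA_EPSILON,
    TimescaleReport,
    profile_is_hourglass,
)


def traj_from_values(values, dt=0.1):
    values = np.asarray(values, dtype=float)
    return Trajectory(values=values, dt=dt, delta=np.zeros(values.shape[0]))


class TestSimilarityDelta:
    def test_identical_frames_hit_cap(self):
        t = traj_from_values(np.random.default_rng(0).random((3, 4, 5)))
        assert similarity_delta(t, t, 2, 2) == pytest.approx(1.0 / DELTA_EPSILON)

    def test_hand_computed_half_unit_difference(self):
        a = np.zeros((3, 4, 2))
        b = a.copy()
        b[1, 2, 1] = 0.5
        ta, tb = traj_from_values(a), traj_from_values(b)
        assert similarity_delta(ta, tb, 0, 1) == pytest.approx(2.0, rel=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        ta = traj_from_values(rng.random((3, 4, 5)))
        tb = traj_from_values(rng.random((3, 4, 5)))
        assert similarity_delta(ta, tb, 1, 3) == similarity_delta(tb, ta, 3, 1)

    def test_shape_mismatch_rejected(self):
        ta = traj_from_values(np.zeros((3, 4, 2)))
        tb = traj_from_values(np.zeros((3, 5, 2)))
        with pytest.raises(ValueError):
            similarity_delta(ta, tb, 0, 0)


class TestSimilarityPearson:
    def test_identical_vectors_give_one(self):
        t = traj_from_values(np.random.default_rng(1).random((5, 3, 2)))
        rho, ok = similarity_pearson(t, t, 0, 0)
        assert ok and rho == pytest.approx(1.0)

    def test_anticorrelated_gives_minus_one(self):
        a = np.zeros((3, 1, 1))
        a[:, 0, 0] = [1.0, 2.0, 3.0]
        b = np.zeros((3, 1, 1))
        b[:, 0, 0] = [3.0, 2.0, 1.0]  # -X + c
        rho, ok = similarity_pearson(
            traj_from_values(a), traj_from_values(b), 0, 0
        )
        assert ok and rho == pytest.approx(-1.0)

    def test_collinear_vectors(self):
        a = np.zeros((3, 1, 1))
        a[:, 0, 0] = [1.0, 2.0, 3.0]
        b = np.zeros((3, 1, 1))
        b[:, 0, 0] = [2.0, 4.0, 6.0]
        rho, ok = similarity_pearson(
            traj_from_values(a), traj_from_values(b), 0, 0
        )
        assert ok and rho == pytest.approx(1.0)

    def test_constant_vector_flagged_undefined(self):
        a = np.full((3, 2, 1), 0.5)
        rho, ok = similarity_pearson(
            traj_from_values(a), traj_from_values(a), 0, 0
        )
        assert not ok and rho == 0.0


class TestSimilarityMatrix:
    def test_self_comparison_ridge_is_diagonal(self):
        rng = np.random.default_rng(7)
        # strictly distinct frames so the self-match is unique
        t = traj_from_values(np.cumsum(rng.random((4, 6, 20)), axis=2) / 20)
        sm = similarity_matrix(t, t, "delta")
        np.testing.assert_array_equal(sm.ridge, sm.steps_a)

    def test_constructed_mid_run_match_gives_interior_bottleneck(self):
        """Two runs agreeing only on a middle segment peak there."""
        rng = np.random.default_rng(11)
        a = rng.random((3, 5, 30))
        b = rng.random((3, 5, 30))
        shared = rng.random((3, 5, 8))
        a[:, :, 11:19] = shared
        b[:, :, 11:19] = shared + rng.normal(0, 1e-3, shared.shape)
        sm = similarity_matrix(traj_from_values(a), traj_from_values(b))
        assert 11 <= sm.bottleneck_step <= 18
        assert sm.bottleneck_is_interior

    def test_monotone_divergence_gives_boundary_bottleneck(self):
        """Frames drifting apart from the start peak at the first frame."""
        base = np.random.default_rng(13).random((3, 5, 1))
        drift = np.linspace(0, 1, 25)
        a = np.repeat(base, 25, axis=2)
        b = a + drift[None, None, :] * 0.3
        sm = similarity_matrix(traj_from_values(a), traj_from_values(b))
        assert sm.bottleneck_step == 0
        assert not sm.bottleneck_is_interior

    def test_pearson_values_in_range(self):
        rng = np.random.default_rng(17)
        ta = traj_from_values(rng.random((5, 4, 10)))
        tb = traj_from_values(rng.random((5, 4, 10)))
        sm = similarity_matrix(ta, tb, "pearson")
        assert sm.values.min() >= -1.0 - 1e-12
        assert sm.values.max() <= 1.0 + 1e-12

    def test_empty_grid_rejected(self):
        t = traj_from_values(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            similarity_matrix(t, t, "delta", step_grid=[])

    def test_spatially_averaged_variant_same_bottleneck(self):
        """Summing expression over cells before differencing finds the same
        bottleneck on a constructed pair."""
        rng = np.random.default_rng(19)
        a = rng.random((4, 6, 30))
        b = rng.random((4, 6, 30))
        shared = rng.random((4, 6, 6))
        a[:, :, 12:18] = shared
        b[:, :, 12:18] = shared + rng.normal(0, 1e-4, shared.shape)
        ta, tb = traj_from_values(a), traj_from_values(b)
        sm_cellwise = similarity_matrix(ta, tb)
        sa = traj_from_values(a.sum(axis=1, keepdims=True))
        sb = traj_from_values(b.sum(axis=1, keepdims=True))
        sm_avg = similarity_matrix(sa, sb)
        assert 12 <= sm_cellwise.bottleneck_step < 18
        assert 12 <= sm_avg.bottleneck_step < 18


class TestPleiotropy:
    def make_traj(self, active_stages_per_gene, n_steps=160):
        """Genes switch on (value 1) during chosen step windows."""
        n_genes = len(active_stages_per_gene)
        values = np.zeros((n_genes, 4, n_steps + 1))
        for g, windows in enumerate(active_stages_per_gene):
            for lo, hi in windows:
                values[g, :, lo:hi] = 1.0
        return traj_from_values(values)

    def test_always_on_gene_is_pleiotropic_everywhere(self):
        t = self.make_traj([[(0, 161)], [(0, 161)]])
        _, frac = pleiotropy_fraction(t, n_stages=16, stage_window=(10, 160))
        np.testing.assert_array_equal(frac, 1.0)

    def test_exactly_half_is_not_pleiotropic(self):
        """Expressed at exactly 8 of 16 stages -> not pleiotropic (strict >)."""
        steps = np.linspace(10, 160, 16).round().astype(int)
        on_window = (int(steps[0]), int(steps[7]) + 1)  # covers stages 0..7
        t = self.make_traj([[on_window], [(0, 161)]])
        stage_steps, frac = pleiotropy_fraction(
            t, n_stages=16, stage_window=(10, 160)
        )
        # stage 0..7: gene 0 expressed but not pleiotropic, gene 1 both
        assert frac[0] == pytest.approx(0.5)
        # late stages: only the always-on gene
        assert frac[-1] == pytest.approx(1.0)

    def test_silent_trajectory_all_zero(self):
        t = self.make_traj([[], []])
        _, frac = pleiotropy_fraction(t, n_stages=16, stage_window=(10, 160))
        np.testing.assert_array_equal(frac, 0.0)

    def test_cell_permutation_invariance(self):
        rng = np.random.default_rng(23)
        values = rng.random((5, 8, 101))
        t1 = traj_from_values(values)
        t2 = traj_from_values(values[:, rng.permutation(8), :])
        _, f1 = pleiotropy_fraction(t1)
        _, f2 = pleiotropy_fraction(t2)
        np.testing.assert_array_equal(f1, f2)

    def test_too_few_stages_rejected(self):
        t = self.make_traj([[]])
        with pytest.raises(ValueError):
            pleiotropy_fraction(t, n_stages=1)


class TestCloneVariance:
    def test_zero_noise_zero_variance(self, toy_params, toy_genome, rng):
        res = clone_variance(toy_genome, toy_params, 3, rng, noise_sd=0.0)
        np.testing.assert_allclose(res.variance, 0.0, atol=1e-25)

    def test_hand_computed_two_clone_variance(self):
        """Two clones differing 0.4 vs 0.6 in one gene/cell: Var = 0.01."""
        x = np.stack([np.full((1, 1, 1), 0.4), np.full((1, 1, 1), 0.6)])
        from devhourglass.analysis import _pattern_variance

        assert _pattern_variance(x[:, :, :, 0]) == pytest.approx(0.01)

    def test_initial_variance_matches_injected_noise(self, toy_params, toy_genome):
        """Var(0) equals the empirical delta variance times the cell count."""
        rng = np.random.default_rng(31)
        sd = 0.05
        res = clone_variance(toy_genome, toy_params, 200, rng, noise_sd=sd)
        # expected: sum over genes and cells of per-gene delta variance
        n_free = toy_params.non_morphogen_indices.size
        expected = toy_params.n_cells * n_free * sd**2
        assert res.variance[0] == pytest.approx(expected, rel=0.25)

    def test_ongoing_noise_mode_grows_then_tracks(self, toy_params, toy_genome, rng):
        res = clone_variance(
            toy_genome, toy_params, 5, rng, noise_sd=0.01, noise_mode="ongoing"
        )
        assert res.variance[0] == pytest.approx(0.0, abs=1e-20)
        assert res.variance[1:].min() > 1e-6

    def test_too_few_clones_rejected(self, toy_params, toy_genome, rng):
        with pytest.raises(ValueError):
            clone_variance(toy_genome, toy_params, 1, rng)


class TestTimescales:
    def test_constant_gene_scores_zero(self):
        values = np.full((1, 2, 50), 0.7)
        report = gene_timescales(traj_from_values(values))
        assert report.mean[0] == 0.0

    def test_linear_ramp_counts_its_length(self):
        """0 -> 1 over 200 steps then flat: timescale 200."""
        ramp = np.concatenate([np.linspace(0, 1, 201), np.full(100, 1.0)])
        values = ramp[None, None, :]
        report = gene_timescales(traj_from_values(values))
        assert report.mean[0] == 200

    def test_flickering_sign_scores_at_most_one(self):
        osc = 0.5 + 0.2 * (-1.0) ** np.arange(60)
        values = osc[None, None, :]
        report = gene_timescales(traj_from_values(values))
        assert report.mean[0] <= 1

    def test_subthreshold_drift_ignored(self):
        slow = np.linspace(0, 0.00005, 80)  # |dx/dt| = 6.4e-6 < 1e-3
        values = slow[None, None, :]
        report = gene_timescales(traj_from_values(values))
        assert report.mean[0] == 0.0

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            gene_timescales(traj_from_values(np.zeros((1, 1, 2))))


class TestSlowGenes:
    def report(self, means):
        means = np.asarray(means, dtype=float)
        return TimescaleReport(mean=means, sd=np.zeros_like(means))

    def test_largest_ratio_gap_selects_top_group(self):
        r = self.report([800, 700, 650, 600, 40, 35, 30, 25])
        np.testing.assert_array_equal(sorted(slow_genes(r)), [0, 1, 2, 3])

    def test_equal_timescales_need_explicit_count(self):
        r = self.report([100, 100, 100, 100])
        assert slow_genes(r).size == 0
        assert slow_genes(r, n_slow=2).size == 2

    def test_single_gene_returns_itself(self):
        r = self.report([50])
        np.testing.assert_array_equal(slow_genes(r), [0])

    def test_explicit_count_overrides_gap(self):
        r = self.report([800, 700, 650, 600, 40, 35, 30, 25])
        np.testing.assert_array_equal(slow_genes(r, n_slow=2), [0, 1])


class TestTimescaleBottleneckCorrelation:
    def test_collinear_points_correlate_perfectly(self):
        samples = [(10.0, 20.0), (20.0, 40.0), (30.0, 60.0)]
        rho, slope, ok = timescale_bottleneck_correlation(samples)
        assert ok and rho == pytest.approx(1.0) and slope == pytest.approx(2.0)

    def test_order_invariance(self):
        s = [(10.0, 25.0), (20.0, 38.0), (30.0, 66.0), (40.0, 71.0)]
        r1 = timescale_bottleneck_correlation(s)
        r2 = timescale_bottleneck_correlation(s[::-1])
        assert r1 == pytest.approx(r2)

    def test_degenerate_variance_flagged(self):
        rho, slope, ok = timescale_bottleneck_correlation(
            [(10.0, 5.0), (10.0, 6.0), (10.0, 7.0)]
        )
        assert not ok

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            timescale_bottleneck_correlation([(1.0, 2.0), (3.0, 4.0)])


class TestHourglassProfileRule:
    def test_interior_peak_with_margin_positive(self):
        steps = np.arange(101)
        profile = np.ones(101)
        profile[50] = 2.0
        assert profile_is_hourglass(profile, steps)

    def test_boundary_peak_negative(self):
        steps = np.arange(101)
        profile = np.linspace(2, 1, 101)
        assert not profile_is_hourglass(profile, steps)

    def test_marginless_peak_negative(self):
        steps = np.arange(101)
        profile = np.ones(101)
        profile[50] = 1.01  # above ends, but below the 5% margin
        assert not profile_is_hourglass(profile, steps)
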