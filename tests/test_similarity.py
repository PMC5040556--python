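import numpy as np
import pytest

from somatomap import (
    PatternGroundTruth,
    compare_to_controls,
    glm_betas,
    make_block_schedule,
    make_digit_strip,
    mean_overlap,
    pair_correlated_second_moment,
    pattern_component_similarity,
    simulate_block_patterns,
    simulate_run,
    stack_runs,
)
from somatomap.similarity import SimilarityMatrix, off_diagonal_cells

from conftest import noiseless_noise


def matrix_from_cells(cells):
    """Build a SimilarityMatrix from 10 unique off-diagonal values."""
    r = np.eye(5)
    iu = np.triu_indices(5, k=1)
    r[iu] = cells
    r.T[iu] = cells
    return SimilarityMatrix(r=r)


class TestGLMBetas:
    def test_recovers_single_digit_amplitude(self):
        sched = make_block_schedule(6, 3, 12.0, order_seed=2)
        truth = make_digit_strip((5, 1, 1), band_width_voxels=1, amplitude=2.5,
                                 tuning_width=0.0)
        vol = simulate_run(sched, truth, tr=1.5, noise=noiseless_noise())
        betas = glm_betas(vol, sched)
        # voxel k prefers digit k+1
        for v in range(5):
            assert betas[v, v] == pytest.approx(2.5, abs=0.05)
            others = np.delete(betas[:, v], v)
            np.testing.assert_allclose(others, 0.0, atol=0.05)

    def test_pure_noise_betas_are_unbiased(self):
        sched = make_block_schedule(6, 3, 12.0, order_seed=2)
        quiet = make_digit_strip((10, 5, 1), band_width_voxels=2, amplitude=0.0)
        means = []
        for seed in range(50):
            from somatomap import NoiseModel

            vol = simulate_run(
                sched, quiet, tr=1.5,
                noise=NoiseModel(sigma=1.0, drift_amplitude=0.0, seed=seed),
            )
            means.append(glm_betas(vol, sched).mean())
        assert abs(np.mean(means)) < 0.05

    def test_all_rest_schedule_rejected(self):
        rest_only = make_block_schedule(1, 1, 12.0, order_seed=0)
        truth = make_digit_strip((5, 1, 1), band_width_voxels=1)
        vol = simulate_run(rest_only, truth, tr=1.5, noise=noiseless_noise(),
                           n_volumes=8)
        with pytest.raises(ValueError):
            glm_betas(vol, rest_only)


class TestPatternComponentSimilarity:
    def patterns(self, seed=0, r=0.5, noise=0.5, n_voxels=500, n_runs=4):
        truth = PatternGroundTruth(
            second_moment=pair_correlated_second_moment(r, (0, 1)),
            n_voxels=n_voxels, n_runs=n_runs, noise_sigma=noise,
        )
        return stack_runs(list(simulate_block_patterns(truth, seed=seed)))

    def test_identical_patterns_flagged_degenerate(self):
        # every digit identical -> nothing left after common removal
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        betas = np.stack([np.stack([base] * 5) for _ in range(3)])
        with pytest.warns(UserWarning):
            sim = pattern_component_similarity(stack_runs(list(betas)))
        assert sim.undefined.all()

    def test_proportional_digit_patterns_correlate_fully(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=200)
        scales = np.array([1.0, 2.0, 4.0, 8.0, 16.0])  # none equal to the mean
        betas = np.stack(
            [np.outer(scales, u) for _ in range(3)]
        )  # digit patterns proportional to one shared pattern
        sim = pattern_component_similarity(stack_runs(list(betas)))
        off = off_diagonal_cells(sim)
        np.testing.assert_allclose(np.abs(off), 1.0, atol=1e-9)

    def test_orthogonal_patterns_give_near_zero_overlap(self):
        truth = PatternGroundTruth(
            second_moment=np.eye(5), n_voxels=5000, n_runs=4,
            noise_sigma=0.0, common_amplitude=0.0,
        )
        sim = pattern_component_similarity(
            stack_runs(list(simulate_block_patterns(truth, seed=2)))
        )
        # centering induces a known -0.25 correlation between orthogonal digits
        off = off_diagonal_cells(sim)
        np.testing.assert_allclose(off, -0.25, atol=0.05)

    def test_common_component_invariance_is_exact(self):
        pats = self.patterns(seed=3)
        rng = np.random.default_rng(4)
        contaminated = pats.betas + rng.normal(size=(1, 1, 500)) * 7.0
        a = pattern_component_similarity(pats)
        b = pattern_component_similarity(stack_runs(list(contaminated)))
        np.testing.assert_allclose(a.r, b.r, atol=1e-9)

    def test_scale_invariance(self):
        pats = self.patterns(seed=5)
        a = pattern_component_similarity(pats)
        b = pattern_component_similarity(stack_runs(list(pats.betas * 3.7)))
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_cross_validation_unbiasedness(self):
        """Mean estimated G matches the centered true second moment."""
        g_true = pair_correlated_second_moment(0.5, (0, 1))
        c = np.eye(5) - np.ones((5, 5)) / 5
        target = c @ g_true @ c
        gs = []
        for seed in range(200):
            truth = PatternGroundTruth(
                second_moment=g_true, n_voxels=500, n_runs=4, noise_sigma=0.5
            )
            pats = stack_runs(list(simulate_block_patterns(truth, seed=seed)))
            gs.append(pattern_component_similarity(pats).g)
        mean_g = np.mean(gs, axis=0)
        se = np.std(gs, axis=0) / np.sqrt(len(gs))
        assert (np.abs(mean_g - target) <= 2.5 * se + 1e-3).all()

    def test_single_run_rejected(self):
        pats = self.patterns(seed=0)
        with pytest.raises(ValueError):
            pattern_component_similarity(stack_runs([pats.betas[0]]))

    def test_tiny_roi_rejected(self):
        rng = np.random.default_rng(6)
        betas = rng.normal(size=(2, 5, 10))
        with pytest.raises(ValueError):
            pattern_component_similarity(stack_runs(list(betas)))


class TestMeanOverlap:
    def test_constant_off_diagonal(self):
        m = matrix_from_cells(np.full(10, 0.42))
        assert mean_overlap(m) == pytest.approx(0.42)

    def test_distinct_values_average(self):
        cells = np.arange(0.1, 1.05, 0.1)
        assert mean_overlap(matrix_from_cells(cells)) == pytest.approx(0.55)

    def test_identity_matrix_gives_zero(self):
        assert mean_overlap(matrix_from_cells(np.zeros(10))) == 0.0

    def test_undefined_cells_propagate(self):
        cells = np.full(10, 0.3)
        cells[0] = np.nan
        with pytest.warns(UserWarning):
            assert np.isnan(mean_overlap(matrix_from_cells(cells)))


class TestCompareToControls:
    def fingerprints(self, n=10, seed=0, noise=0.2):
        rng = np.random.default_rng(seed)
        template = np.linspace(0.1, 0.8, 10)
        return [
            matrix_from_cells(template + noise * rng.normal(size=10))
            for _ in range(n)
        ]

    def test_identical_case_and_controls(self):
        controls = [matrix_from_cells(np.linspace(0.1, 0.8, 10)) for _ in range(4)]
        res = compare_to_controls(controls[0], controls, n_iterations=1000, seed=0)
        assert res.case_mean_rho == pytest.approx(1.0)
        assert res.within_control_range

    def test_rank_reversed_case_falls_outside(self):
        controls = self.fingerprints(n=8, noise=0.05)
        reversed_case = matrix_from_cells(np.linspace(0.8, 0.1, 10))
        res = compare_to_controls(reversed_case, controls, n_iterations=2000, seed=1)
        assert res.case_mean_rho < 0
        assert not res.within_control_range

    def test_typical_case_within_range(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            template = np.linspace(0.1, 0.8, 10)
            controls = [
                matrix_from_cells(template + 0.2 * rng.normal(size=10))
                for _ in range(10)
            ]
            case = matrix_from_cells(template + 0.2 * rng.normal(size=10))
            res = compare_to_controls(case, controls, n_iterations=2000, seed=seed)
            flags.append(res.within_control_range)
        assert np.mean(flags) >= 0.9

    def test_spearman_invariant_to_monotone_transform(self):
        controls = self.fingerprints(n=5, seed=3)
        case = self.fingerprints(n=1, seed=4)[0]
        res_a = compare_to_controls(case, controls, n_iterations=1000, seed=0)
        warped = [matrix_from_cells(np.exp(off_diagonal_cells(m))) for m in controls]
        case_w = matrix_from_cells(np.exp(off_diagonal_cells(case)))
        res_b = compare_to_controls(case_w, warped, n_iterations=1000, seed=0)
        assert res_a.case_mean_rho == pytest.approx(res_b.case_mean_rho)
        np.testing.assert_allclose(res_a.pair_rhos, res_b.pair_rhos)

    def test_too_few_controls_rejected(self):
        controls = self.fingerprints(n=2)
        with pytest.raises(ValueError):
            compare_to_controls(controls[0], controls, n_iterations=1000)
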