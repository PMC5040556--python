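import numpy as np
import pytest

from somatomap import (
    Volume4D,
    assign_digits,
    average_profiles,
    build_reference_models,
    fdr_threshold,
    fisher_z,
    gradient_map,
    lag_crosscorrelate,
    make_digit_strip,
    reverse_lag_profile,
    simulate_run,
    winner_take_all,
)
from somatomap.paradigm import MovementEvent, MovementSchedule
from somatomap.travelling_wave import LagProfile, bh_reject, map_digits

from conftest import LEAD_IN, TR, brute_force_bh, noiseless_noise


def delta_profile(peak_lag, n_lags=30, grid=(1, 1, 1)):
    z = np.zeros(grid + (n_lags,))
    z[..., peak_lag] = 1.0
    return LagProfile(z=z, tr=1.5, on_lags=6, n_volumes=256)


class TestReferenceModels:
    def test_thirty_lags_for_canonical_cycle(self, bank):
        assert bank.n_lags == 30

    def test_thirty_five_lags_for_standard_field(self):
        b = build_reference_models(1.3, 45.5, 8, 9.1)
        assert b.n_lags == 35

    def test_incommensurate_cycle_rejected(self):
        with pytest.raises(ValueError):
            build_reference_models(1.4, 45.0, 8, 9.0)

    def test_models_are_circular_shifts_in_steady_state(self):
        b = build_reference_models(1.5, 45.0, 4, 9.0, lead_in=0.0)
        # after one full cycle the response is periodic: model l at volume i
        # equals model 0 at volume i - l
        start = 2 * 30
        for lag in (1, 7, 29):
            np.testing.assert_allclose(
                b.models[lag][start : start + 30],
                b.models[0][start - lag : start - lag + 30],
                atol=1e-9,
            )

    def test_models_peak_within_on_period_plus_delay(self, bank):
        # lag-0 model must rise after lead-in, around the HRF peak delay
        t = np.arange(bank.n_volumes) * bank.tr
        first_peak = t[np.argmax(bank.models[0][: int(70 / bank.tr)])]
        assert LEAD_IN < first_peak < LEAD_IN + 9.0 + 10.0


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @pytest.mark.parametrize("r", [0.1, 0.37, 0.9])
    def test_odd_symmetry_and_monotonicity(self, r):
        assert fisher_z(-r) == -fisher_z(r)
        assert fisher_z(r + 0.05) > fisher_z(r)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


class TestLagCrossCorrelate:
    def test_self_correlation_peaks_at_own_lag(self, bank):
        data = (bank.models[7] + 5.0).reshape(1, 1, 1, -1)
        prof = lag_crosscorrelate(Volume4D(data=data, tr=TR), bank)
        assert np.argmax(prof.z[0, 0, 0]) == 7

    def test_constant_voxel_yields_zero_profile(self, bank):
        data = np.full((1, 1, 1, bank.n_volumes), 2.0)
        prof = lag_crosscorrelate(Volume4D(data=data, tr=TR), bank)
        np.testing.assert_array_equal(prof.z, 0.0)

    def test_shape_mismatch_rejected(self, bank):
        vol = Volume4D(data=np.zeros((1, 1, 1, bank.n_volumes + 1)), tr=TR)
        with pytest.raises(ValueError):
            lag_crosscorrelate(vol, bank)

    def test_tr_mismatch_rejected(self, bank):
        vol = Volume4D(data=np.zeros((1, 1, 1, bank.n_volumes)), tr=2.0)
        with pytest.raises(ValueError):
            lag_crosscorrelate(vol, bank)

    def test_noiseless_strip_voxel_peaks_in_own_digit_bin(
        self, noiseless_runs, bank, noiseless_truth
    ):
        vol, _ = noiseless_runs[0]  # forward run
        prof = lag_crosscorrelate(vol, bank)
        values = assign_digits(prof)
        winner = np.argmax(values, axis=-1) + 1
        np.testing.assert_array_equal(winner, noiseless_truth.preferred_digit)


class TestReversal:
    def test_involution(self):
        rng = np.random.default_rng(0)
        prof = LagProfile(
            z=rng.normal(size=(2, 2, 1, 30)), tr=1.5, on_lags=6, n_volumes=256
        )
        twice = reverse_lag_profile(reverse_lag_profile(prof))
        np.testing.assert_array_equal(twice.z, prof.z)

    def test_forward_backward_symmetry_noiseless(self, noiseless_runs, bank):
        """Reversed backward-run profiles must peak at the forward lags."""
        fwd, _ = noiseless_runs[0]
        bwd, _ = noiseless_runs[1]
        prof_f = lag_crosscorrelate(fwd, bank)
        prof_b = reverse_lag_profile(lag_crosscorrelate(bwd, bank))
        np.testing.assert_array_equal(
            np.argmax(prof_f.z, axis=-1), np.argmax(prof_b.z, axis=-1)
        )


class TestAverageProfiles:
    def test_single_profile_identity(self):
        p = delta_profile(4)
        np.testing.assert_array_equal(average_profiles([p]).z, p.z)

    def test_profile_plus_negation_cancels(self):
        p = delta_profile(4)
        neg = LagProfile(z=-p.z, tr=p.tr, on_lags=p.on_lags, n_volumes=p.n_volumes)
        np.testing.assert_array_equal(average_profiles([p, neg]).z, 0.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([delta_profile(0), delta_profile(0, grid=(2, 1, 1))])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([])


class TestAssignDigits:
    def test_six_lags_per_digit(self):
        values = assign_digits(delta_profile(0))
        assert values.shape[-1] == 5

    def test_lag14_maps_to_digit3(self):
        values = assign_digits(delta_profile(14))[0, 0, 0]
        assert np.argmax(values) + 1 == 3

    def test_uniform_profile_gives_equal_values(self):
        prof = delta_profile(0)
        prof.z[:] = 0.3
        values = assign_digits(prof)[0, 0, 0]
        np.testing.assert_allclose(values, values[0])

    def test_onset_lags_map_to_their_digits(self):
        # block-onset lags 0, 6, 12, 18, 24 are the noiseless peak positions
        for d, lag in enumerate([0, 6, 12, 18, 24], start=1):
            values = assign_digits(delta_profile(lag))[0, 0, 0]
            assert np.argmax(values) + 1 == d

    def test_indivisible_lags_rejected(self):
        prof = LagProfile(z=np.zeros((1, 1, 1, 32)), tr=1.5, on_lags=6, n_volumes=256)
        with pytest.raises(ValueError):
            assign_digits(prof, n_digits=5)

    def test_backward_reference_reverses_bins(self):
        fwd = assign_digits(delta_profile(14), direction_reference="forward")
        bwd = assign_digits(delta_profile(14), direction_reference="backward")
        np.testing.assert_array_equal(fwd[..., ::-1], bwd)


class TestWinnerTakeAll:
    def test_highest_value_wins(self):
        values = np.array([[[[0.1, 0.9, 0.2, 0.1, 0.0]]]])
        assert winner_take_all(values).winner[0, 0, 0] == 2

    def test_tie_breaks_to_lowest_digit(self):
        values = np.array([[[[0.1, 0.5, 0.2, 0.5, 0.0]]]])
        assert winner_take_all(values).winner[0, 0, 0] == 2

    def test_below_threshold_unassigned(self):
        values = np.array([[[[0.1, 0.2, 0.15, 0.1, 0.0]]]])
        dpm = winner_take_all(values, threshold_z=0.5)
        assert dpm.winner[0, 0, 0] == 0
        assert not dpm.digit_masks.any()

    def test_masks_partition_assigned_voxels(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(6, 6, 1, 5))
        dpm = winner_take_all(values, threshold_z=0.0)
        # pairwise disjoint
        assert (dpm.digit_masks.sum(axis=0) <= 1).all()
        # union equals above-threshold set, and winners match their masks
        np.testing.assert_array_equal(dpm.digit_masks.any(axis=0), dpm.winner > 0)
        for d in range(1, 6):
            assert (dpm.winner[dpm.digit_masks[d - 1]] == d).all()


class TestFDR:
    def test_bh_matches_hand_worked_example(self):
        # thresholds q*k/m = .0125, .025, .0375, .05: p=0.04 misses its
        # rank-3 threshold, so the step-up stops after the first two
        p = np.array([0.01, 0.02, 0.04, 0.8])
        expected = brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(expected, [True, True, False, False])
        np.testing.assert_array_equal(bh_reject(p, 0.05), expected)

    def test_all_small_p_survive(self):
        assert bh_reject(np.full(10, 0.001), q=0.05).all()

    def test_bh_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.integers(1, 9)
            p = rng.uniform(size=m)
            for q in (0.01, 0.05, 0.2):
                np.testing.assert_array_equal(
                    bh_reject(p, q), brute_force_bh(p, q)
                )

    def test_fdr_threshold_respects_candidate_partition(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0.0, 0.01, size=(5, 5, 2, 5))
        values[0, 0, 0, 2] = 1.0  # one clearly active voxel preferring D3
        dpm = winner_take_all(values, n_volumes=256)
        thresholded = fdr_threshold(dpm, q=0.05)
        assert thresholded.digit_masks[2][0, 0, 0]
        # masks stay disjoint and consistent with winners
        assert (thresholded.digit_masks.sum(axis=0) <= 1).all()

    def test_invalid_q_rejected(self):
        dpm = winner_take_all(np.zeros((1, 1, 1, 5)), n_volumes=256)
        with pytest.raises(ValueError):
            fdr_threshold(dpm, q=1.5)


class TestGradientMap:
    def test_peak_lag_wins(self):
        assert gradient_map(delta_profile(14)).winning_lag[0, 0, 0] == 14

    def test_constant_profile_ties_to_lag_zero(self):
        prof = delta_profile(0)
        prof.z[:] = 1.0
        assert gradient_map(prof).winning_lag[0, 0, 0] == 0

    def test_monotone_along_noiseless_strip(self, noiseless_runs, bank):
        prof = lag_crosscorrelate(noiseless_runs[0][0], bank)
        lags = gradient_map(prof).winning_lag[:, 0, 0]
        assert (np.diff(lags) >= 0).all()


class TestCircularEquivariance:
    def test_rotating_digit_sequence_rotates_winning_lags(self):
        """Rotating the cycle by one block shifts every winning lag by 6."""
        truth = make_digit_strip((5, 1, 1), band_width_voxels=1, tuning_width=0.0)
        base = [1, 2, 3, 4, 5]
        rotated = [2, 3, 4, 5, 1]

        def schedule_for(seq):
            events = []
            for c in range(4):
                for k, d in enumerate(seq):
                    events.append(MovementEvent(d, "left", c * 45.0 + k * 9.0, 9.0))
            return MovementSchedule(
                events=tuple(events), cycle_duration=45.0, n_cycles=4,
                lead_in=0.0, direction="none",
            )

        bank = build_reference_models(1.5, 45.0, 4, 9.0, lead_in=0.0)
        lags = {}
        for name, seq in [("base", base), ("rotated", rotated)]:
            vol = simulate_run(
                schedule_for(seq), truth, tr=1.5, noise=noiseless_noise(),
                n_volumes=bank.n_volumes,
            )
            prof = lag_crosscorrelate(vol, bank)
            lags[name] = gradient_map(prof).winning_lag[:, 0, 0]
        np.testing.assert_array_equal(lags["rotated"], (lags["base"] - 6) % 30)


class TestParameterRecovery:
    def test_noiseless_full_recovery(self, noiseless_runs, bank, noiseless_truth):
        dpm, _ = map_digits(list(noiseless_runs), bank, q=None)
        np.testing.assert_array_equal(dpm.winner, noiseless_truth.preferred_digit)
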