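"""Observer model: filters, gain, evidence, accumulator, trial simulation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rlci.stimgen import LEFT, RIGHT, CueSpec, StimulusMovie, make_trial_movie
from rlci.observer import (
    ModelParams,
    accumulate_and_decide,
    apply_attention_gain,
    attention_onset_frame,
    evidence_signal,
    invalid_profile,
    perceptual_response,
    regenerate_trial,
    simulate_session,
    simulate_trial,
    spatial_filter_profile,
    spatial_bar_kernels,
    temporal_filter_profile,
    temporal_kernel,
    valid_profile,
)

FD = 1000.0 / 30.0


class TestSpatialFilter:
    def test_equal_sds_cancel_at_origin(self):
        assert spatial_filter_profile(0.0, 2.0, 2.0) == pytest.approx(0.0)

    def test_peak_value_at_fitted_parameters(self):
        # 1 - sigma_c^2/sigma_s^2 with the fitted valid-condition values
        got = spatial_filter_profile(0.0, 2.94, 16.9)
        assert got == pytest.approx(1 - 2.94**2 / 16.9**2, rel=1e-12)
        assert got == pytest.approx(0.96974, abs=5e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-50, 50))
    def test_even_symmetry(self, x):
        assert spatial_filter_profile(x, 2.94, 16.9) == pytest.approx(
            spatial_filter_profile(-x, 2.94, 16.9), rel=1e-12, abs=1e-15
        )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            spatial_filter_profile(0.0, -1.0, 2.0)


class TestTemporalFilter:
    def test_zero_at_origin(self):
        assert temporal_filter_profile(0, 0.505, 2.38, 5) == 0.0

    def test_single_lobe_when_B_zero(self):
        t = np.arange(0, 200)
        assert np.all(temporal_filter_profile(t, 0.0, 2.38, 5) >= 0)

    def test_sign_change_at_closed_form_root(self):
        # bracket root: t/tau = sqrt((n+2)!/(n! B)) = sqrt(42/B) for n=5
        B, tau = 0.505, 2.38
        expected = tau * math.sqrt(42.0 / B)
        assert expected == pytest.approx(21.7, abs=0.05)
        lo, hi = 1.0, 40.0
        for _ in range(80):  # bisection on the implemented function
            mid = 0.5 * (lo + hi)
            if temporal_filter_profile(mid, B, tau, 5) > 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(expected, rel=1e-9)

    def test_kernel_truncation_keeps_peak(self, model_params):
        k = temporal_kernel(model_params)
        assert k[0] == 0.0
        assert np.abs(k[-1]) < 1e-2 * np.abs(k).max()
        assert 30 < len(k) < 120


class TestPerceptualResponse:
    def _impulse_movie(self, short_params, bar, frame):
        shape = (2, short_params.n_bars, short_params.n_frames)
        z = np.zeros(shape)
        c = np.zeros(shape)
        c[LEFT, bar, frame] = 1.0
        return StimulusMovie(
            noise=z, contrast=c, target_side=LEFT, target_onset_frame=0,
            params=short_params,
        )

    def test_zero_stimulus_gives_zero_response(self, short_params, model_params):
        m = self._impulse_movie(short_params, 5, 10)
        m.contrast[:] = 0.0
        R = perceptual_response(m, model_params)
        assert np.all(R == 0)

    def test_linearity_in_contrast_and_gain(self, short_params, model_params):
        m = self._impulse_movie(short_params, 5, 10)
        R1 = perceptual_response(m, model_params)
        m2 = self._impulse_movie(short_params, 5, 10)
        m2.contrast *= 3.0
        assert np.allclose(perceptual_response(m2, model_params), 3.0 * R1)
        g = 2.0 * np.ones((2, short_params.n_frames))
        assert np.allclose(
            perceptual_response(m, model_params, gain_timeline=g), 2.0 * R1
        )

    def test_impulse_response_is_separable_product(self, short_params, model_params):
        # independent oracle: direct evaluation of the closed-form
        # space and time profiles at every output sample
        bar, t0 = 6, 9
        m = self._impulse_movie(short_params, bar, t0)
        R = perceptual_response(m, model_params)
        pb = short_params.pixels_per_bar
        radius = int(math.ceil(4 * model_params.sigma_s))
        x = np.arange(short_params.n_pixels)
        spatial = np.zeros(short_params.n_pixels)
        for k in range(bar * pb, (bar + 1) * pb):
            d = x - k
            contrib = spatial_filter_profile(d, model_params.sigma_c, model_params.sigma_s)
            contrib[np.abs(d) > radius] = 0.0
            spatial += contrib
        ft = temporal_kernel(model_params)
        temporal = np.zeros(short_params.n_frames)
        upto = min(len(ft), short_params.n_frames - t0)
        temporal[t0 : t0 + upto] = ft[:upto]
        expected = np.outer(spatial, temporal)
        assert np.allclose(R[LEFT], expected, atol=1e-10)
        assert np.all(R[RIGHT] == 0)


class TestAttentionGain:
    def test_no_cue_all_ones(self, model_params):
        g = apply_attention_gain(None, model_params, 45, FD)
        assert np.all(g == 1.0)

    def test_switch_exactly_50_ms_after_cue_onset(self, model_params):
        cue = CueSpec(side=RIGHT, onset_frame=20, offset_frame=23)
        g = apply_attention_gain(cue, model_params, 135, FD)
        # first amplified frame starts at >= cue onset + 50 ms
        f0 = attention_onset_frame(20, model_params, FD)
        assert f0 == 22  # 50 ms = 1.5 frames -> next frame boundary
        assert np.all(g[RIGHT, :f0] == 1.0)
        assert np.all(g[RIGHT, f0:] == model_params.gain)
        assert np.all(g[LEFT] == 1.0)
        assert (f0 * FD) >= 20 * FD + 50.0 - 1e-9
        assert ((f0 - 1) * FD) < 20 * FD + 50.0

    def test_unit_gain_is_identity(self):
        p = dataclasses.replace(valid_profile(), gain=1.0)
        cue = CueSpec(side=LEFT, onset_frame=10, offset_frame=13)
        assert np.all(apply_attention_gain(cue, p, 60, FD) == 1.0)


class TestEvidence:
    def test_equal_fields_give_zero(self):
        R = np.random.default_rng(0).normal(size=(8, 20))
        assert np.allclose(evidence_signal(R, R), 0.0)

    def test_antisymmetry_and_toy_values(self):
        Rl = np.array([[1.0, -2.0], [3.0, 0.5]])
        Rr = np.array([[-4.0, 1.0], [0.0, 2.0]])
        # manual: |1|+|3| - (|-4|+|0|) = 0 ; |-2|+|0.5| - (|1|+|2|) = -0.5
        got = evidence_signal(Rl, Rr)
        assert np.allclose(got, [0.0, -0.5])
        assert np.allclose(evidence_signal(Rr, Rl), -got)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evidence_signal(np.zeros((2, 3)), np.zeros((2, 4)))


class TestAccumulator:
    def test_geometric_closed_form_constant_input(self):
        p = dataclasses.replace(valid_profile(), noise_sd=0.0, bound=1e12)
        c, F = 3.7, 120
        out = accumulate_and_decide(np.full(F, c), p, eps=np.zeros(F))
        T = np.arange(1, F + 1)
        expected = c * (1 - p.gamma**T) / (1 - p.gamma)
        assert np.allclose(out.evidence, expected, rtol=1e-9)

    def test_gamma_zero_is_memoryless(self):
        p = dataclasses.replace(valid_profile(), gamma=0.0, noise_sd=0.0, bound=5.0)
        dR = np.array([1.0, 2.0, -3.0, 6.0, 0.0])
        out = accumulate_and_decide(dR, p, eps=np.zeros(5), frame_duration_ms=FD)
        assert out.decision_frame == 4  # first |dR| >= 5 at frame 4
        assert out.choice == LEFT

    def test_first_passage_matches_scalar_scan(self):
        # oracle: plain python loop over the same recursion
        p = dataclasses.replace(valid_profile(), noise_sd=0.0, gamma=0.4, bound=12.0)
        rng = np.random.default_rng(5)
        dR = rng.normal(0, 6.0, size=200)
        E, T_oracle, choice_oracle = 0.0, None, None
        for i, v in enumerate(dR):
            E = p.gamma * E + v
            if abs(E) >= p.bound:
                T_oracle, choice_oracle = i + 1, (LEFT if E > 0 else RIGHT)
                break
        out = accumulate_and_decide(dR, p, eps=np.zeros(200), frame_duration_ms=FD)
        assert out.decision_frame == T_oracle
        assert out.choice == choice_oracle
        assert out.rt_ms == pytest.approx(T_oracle * FD + 250.0)

    def test_motor_delay_contributes_exactly_250_ms(self):
        p = dataclasses.replace(valid_profile(), noise_sd=0.0, gamma=0.0, bound=1.0)
        dR = np.zeros(30)
        dR[9] = 2.0
        out = accumulate_and_decide(dR, p, eps=np.zeros(30), frame_duration_ms=FD)
        assert out.rt_ms - out.decision_frame * FD == pytest.approx(250.0)

    def test_lapse_when_bound_unreached(self):
        p = dataclasses.replace(valid_profile(), noise_sd=0.0)
        out = accumulate_and_decide(np.zeros(135), p, eps=np.zeros(135))
        assert out.lapsed and out.choice is None and out.rt_ms is None

    def test_noise_leak_variant_decays_noise(self):
        p = dataclasses.replace(
            valid_profile(), gamma=0.5, noise_sd=1.0, bound=1e9, leak_noise=True
        )
        eps = np.array([1.0, 0.0, 0.0, 0.0])
        out = accumulate_and_decide(np.zeros(4), p, eps=eps)
        assert np.allclose(out.evidence, [1.0, 0.5, 0.25, 0.125])


class TestTrialSimulation:
    def test_deterministic_stimulus_gives_deterministic_choice(self, short_params):
        p = dataclasses.replace(
            valid_profile(), noise_sd=0.0, bound=12.0, deadline_ms=1500.0
        )
        m = make_trial_movie(short_params, 21, cue_mode="none", target_side=LEFT)
        m.noise[:] = 0.0
        m.contrast[:] = 0.0
        from rlci.stimgen import add_target

        m = add_target(m, LEFT, 0, short_params)
        rec, out = simulate_trial(m, p, eps=np.zeros(short_params.n_frames))
        assert rec["choice"] == LEFT and rec["correct"] and not rec["lapsed"]

    def test_valid_cue_no_slower_than_no_gain(self, short_params):
        # zero internal noise, fixed stimulus: amplifying the target field
        # cannot delay the first passage
        m = make_trial_movie(short_params, 33, cue_mode="valid", target_side=RIGHT)
        base = dataclasses.replace(
            valid_profile(), noise_sd=0.0, bound=120.0, deadline_ms=1500.0
        )
        nogain = dataclasses.replace(base, gain=1.0)
        z = np.zeros(short_params.n_frames)
        _, with_gain = simulate_trial(m, base, eps=z)
        _, without = simulate_trial(m, nogain, eps=z)
        if with_gain.lapsed:
            assert without.lapsed
        elif not without.lapsed:
            assert with_gain.rt_ms <= without.rt_ms

    def test_session_trials_regenerate_bit_identically(self, valid_session_2000):
        sess = valid_session_2000
        for i in (0, 17, 555):
            row = sess.trials.iloc[i]
            rec, _ = regenerate_trial(
                int(row.seed), sess.stim_params, sess.model_params, cue_mode="valid"
            )
            assert rec["choice"] == row.choice or (rec["lapsed"] and row.lapsed)
            if not row.lapsed:
                assert rec["rt_ms"] == row.rt_ms
            assert rec["target_side"] == row.target_side

    def test_session_is_reproducible(self, stim_params, model_params):
        a = simulate_session(60, stim_params, model_params, seed=8, cue_mode="schedule")
        b = simulate_session(60, stim_params, model_params, seed=8, cue_mode="schedule")
        assert a.trials.equals(b.trials)
        assert np.array_equal(a.noise, b.noise)

    def test_session_error_rate_low_at_fitted_parameters(self, valid_session_2000):
        t = valid_session_2000.trials
        responded = ~t.lapsed
        error_rate = 1.0 - t.correct[responded].mean()
        assert error_rate <= 0.10

    def test_invalid_profile_matches_printed_vector(self):
        p = invalid_profile()
        assert (p.sigma_c, p.sigma_s, p.B, p.tau) == (2.92, 15.7, 0.490, 2.41)
        assert (p.gamma, p.bound, p.noise_sd, p.gain) == (0.212, 353.5, 9.80, 1.0)

    def test_bad_model_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(sigma_c=5.0, sigma_s=3.0)
        with pytest.raises(ValueError):
            ModelParams(gamma=1.0)
        with pytest.raises(ValueError):
            ModelParams(gain=0.0)


def test_spatial_bar_kernels_match_direct_sum(stim_params, model_params):
    M = spatial_bar_kernels(stim_params, model_params.sigma_c, model_params.sigma_s)
    pb = stim_params.pixels_per_bar
    radius = int(math.ceil(4 * model_params.sigma_s))
    b = 7
    x = np.arange(stim_params.n_pixels)
    expected = np.zeros(stim_params.n_pixels)
    for k in range(b * pb, (b + 1) * pb):
        d = x - k
        w = spatial_filter_profile(d, model_params.sigma_c, model_params.sigma_s)
        w[np.abs(d) > radius] = 0.0
        expected += w
    assert np.allclose(M[b], expected, atol=1e-12)
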