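"""Synthetic-trial generator: exponential truth series and raw-signal
synthesis consistency."""

import dataclasses

import numpy as np
import pytest

from splitbelt.config import EpochSpec
from splitbelt.preprocess import surface_to_lab
from splitbelt.synth import (AdaptationParams, GenerationError, ParamCurve,
                             default_adaptation_params, generate_stride_series,
                             punch_gaps, synthesize_trial)


def one_curve_params(curve: ParamCurve, name: str = "p") -> AdaptationParams:
    return AdaptationParams(curves={name: curve})


def plan(adapt=60, post=20, base=10):
    return (EpochSpec("baseline_mid", base, 0.7, 0.7),
            EpochSpec("adaptation", adapt, 0.47, 0.93),
            EpochSpec("post_adaptation", post, 0.7, 0.7))


class TestGenerateStrideSeries:
    def test_initial_value_is_p0(self):
        params = one_curve_params(ParamCurve(0.0, p0=-0.2, p_ss=-0.05, tau=50.0))
        truth = generate_stride_series(params, plan(), seed=0)
        adapt = truth.table[truth.table["epoch"] == "adaptation"]["p"].to_numpy()
        assert adapt[0] == pytest.approx(-0.2)

    def test_exponential_value_at_one_time_constant(self):
        """p(50) = p_ss + (p0 - p_ss) e^-1 = -0.05 - 0.15 e^-1 = -0.10518..."""
        params = one_curve_params(ParamCurve(0.0, p0=-0.2, p_ss=-0.05, tau=50.0))
        truth = generate_stride_series(params, plan(adapt=60), seed=0)
        adapt = truth.table[truth.table["epoch"] == "adaptation"]["p"].to_numpy()
        assert adapt[50] == pytest.approx(-0.05 - 0.15 * np.exp(-1.0), abs=1e-12)
        assert adapt[50] == pytest.approx(-0.1051819, abs=1e-7)

    def test_tiny_time_constant_reaches_steady_state_after_first_stride(self):
        params = one_curve_params(ParamCurve(0.0, p0=1.0, p_ss=0.25, tau=1e-9))
        truth = generate_stride_series(params, plan(), seed=0)
        adapt = truth.table[truth.table["epoch"] == "adaptation"]["p"].to_numpy()
        assert adapt[0] == pytest.approx(1.0)
        np.testing.assert_allclose(adapt[1:], 0.25, atol=1e-12)

    def test_post_adaptation_washout(self):
        params = one_curve_params(ParamCurve(0.1, p0=0, p_ss=0, tau=10,
                                             a0=0.5, tau_w=20.0))
        truth = generate_stride_series(params, plan(post=100), seed=0)
        post = truth.table[truth.table["epoch"] == "post_adaptation"]["p"].to_numpy()
        assert post[0] == pytest.approx(0.6)
        assert post[60] == pytest.approx(0.1 + 0.5 * np.exp(-3.0), abs=1e-12)

    def test_baselines_stationary(self):
        params = one_curve_params(ParamCurve(0.3, 0, 0, 1, baseline_slow=0.2))
        epochs = (EpochSpec("baseline_slow", 5, 0.47, 0.47),) + plan()
        truth = generate_stride_series(params, epochs, seed=0)
        t = truth.table
        np.testing.assert_allclose(t[t["epoch"] == "baseline_mid"]["p"], 0.3)
        np.testing.assert_allclose(t[t["epoch"] == "baseline_slow"]["p"], 0.2)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(GenerationError):
            ParamCurve(0.0, 0.0, 0.0, tau=0.0)

    def test_seed_reproducibility(self):
        params = default_adaptation_params(0.0, noisy=True)
        a = generate_stride_series(params, plan(), seed=5)
        b = generate_stride_series(params, plan(), seed=5)
        assert a.table.equals(b.table)
        c = generate_stride_series(params, plan(), seed=6)
        assert not a.table.equals(c.table)

    def test_truth_length_equals_planned_strides(self):
        params = default_adaptation_params(0.0, noisy=False)
        truth = generate_stride_series(params, plan(adapt=907, post=10, base=5), seed=0)
        assert (truth.table["epoch"] == "adaptation").sum() == 907
        assert len(truth.table) == 922


class TestSynthesizeTrial:
    def test_surface_to_lab_rotation_arithmetic(self):
        """A surface unit vector along the belt maps to (cos, 0, sin) in lab."""
        x, z = surface_to_lab(np.array([1.0]), np.array([0.0]), 8.5)
        theta = np.deg2rad(8.5)
        assert (x[0], z[0]) == (pytest.approx(np.cos(theta)),
                                pytest.approx(np.sin(theta)))

    def test_event_times_strictly_increasing(self, clean_trial):
        _, realized, _, _ = clean_trial
        for leg in ("paretic", "nonparetic"):
            t = realized.events.loc[realized.events["leg"] == leg, "time_s"]
            assert (t.diff().dropna() > 0).all()

    def test_normal_force_crosses_thirty_newtons_at_scheduled_heel_strike(
            self, flat_config, clean_trial):
        """Raw normal force rises through 30 N within 5 ms of each scheduled
        heel strike."""
        _, realized, recording, _ = clean_trial
        force = recording.forces["left"]  # paretic side of the fixture
        hs = realized.events.query("leg == 'paretic' and kind == 'heel_strike'")
        for t in hs["time_s"].to_numpy()[:50]:
            i = int(round(t * 1000))
            window = force.f_normal[i:i + 6]
            assert window[0] < 30.0 and np.any(window >= 30.0)

    def test_swing_force_is_zero_between_stances(self, clean_trial):
        _, realized, recording, _ = clean_trial
        fn = recording.forces["left"].f_normal
        hs = realized.events.query("leg == 'paretic' and kind == 'heel_strike'")
        t0 = hs["time_s"].iloc[0]
        # just before a mid-epoch heel strike the leg is in swing
        t5 = hs["time_s"].iloc[5]
        i = int(round(t5 * 1000))
        assert np.all(fn[i - 60:i - 10] == 0.0)
        assert fn[int(round(t0 * 1000)) - 50] == 0.0

    def test_missing_required_curve_rejected(self, flat_config):
        params = one_curve_params(ParamCurve(0.1, 0, 0, 1), name="sla")
        truth = generate_stride_series(params, flat_config.epoch_plan, seed=0)
        with pytest.raises(GenerationError, match="missing curves"):
            synthesize_trial(truth, flat_config, seed=0)

    def test_too_short_stride_duration_rejected(self, flat_config):
        params = default_adaptation_params(0.0, noisy=False)
        # shrink all geometry so steps become ~40 mm: stride period ~0.1 s
        tiny = {
            k: dataclasses.replace(c, baseline=c.baseline * 0.04,
                                   p0=c.p0 * 0.04, p_ss=c.p_ss * 0.04,
                                   baseline_slow=None)
            for k, c in params.curves.items()
        }
        params = dataclasses.replace(params, curves=tiny)
        truth = generate_stride_series(params, flat_config.epoch_plan, seed=0)
        with pytest.raises(GenerationError, match="too short"):
            synthesize_trial(truth, flat_config, seed=0, params=params)

    def test_bit_identical_under_same_seed(self, flat_config):
        params = default_adaptation_params(0.0, noisy=True)
        cfg = dataclasses.replace(flat_config, epoch_plan=plan(adapt=20, post=5, base=5))
        truth = generate_stride_series(params, cfg.epoch_plan, seed=9)
        rec_a, real_a = synthesize_trial(truth, cfg, seed=10, params=params)
        rec_b, real_b = synthesize_trial(truth, cfg, seed=10, params=params)
        assert real_a.table.equals(real_b.table)
        for name in rec_a.markers:
            np.testing.assert_array_equal(rec_a.markers[name].positions,
                                          rec_b.markers[name].positions)
        for side in rec_a.forces:
            np.testing.assert_array_equal(rec_a.forces[side].f_ap,
                                          rec_b.forces[side].f_ap)

    def test_sign_convention_validation(self):
        with pytest.raises(GenerationError, match="landing"):
            AdaptationParams(curves={"alpha_paretic": ParamCurve(-5.0, 1.0, 1.0, 10)})
        with pytest.raises(GenerationError, match="trailing"):
            AdaptationParams(curves={"x_paretic": ParamCurve(5.0, -1.0, -1.0, 10)})


def test_punch_gaps_masks_only_interior_frames(clean_trial):
    _, _, recording, _ = clean_trial
    series = recording.markers["ankle_L"]
    gapped = punch_gaps(series, n_gaps=5, max_gap_frames=4, seed=1)
    assert gapped.valid.sum() < len(gapped.valid)
    assert gapped.valid[0] and gapped.valid[-1]
    assert np.isnan(gapped.positions[~gapped.valid]).all()
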