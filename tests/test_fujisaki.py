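import numpy as np
import pytest
from scipy.integrate import quad

from tonecortex.fujisaki import (FujisakiCommandSet, command_track,
                                 estimate_commands, phrase_response,
                                 synthesize_f0, tone_response, tone_template)
from tonecortex.io_formats import SampledTrack


class TestResponses:
    def test_phrase_zero_at_origin_and_before(self):
        assert phrase_response(0.0, 3.0) == 0.0
        assert phrase_response(-0.1, 3.0) == 0.0

    @pytest.mark.parametrize("alpha", [1.0, 3.0, 10.0])
    def test_phrase_unit_area(self, alpha):
        val, _ = quad(lambda t: phrase_response(t, alpha), 0, 60 / alpha)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_phrase_maximum(self):
        # d/dt [a^2 t e^(-a t)] = 0 at t = 1/a, value a/e
        t = np.linspace(0, 2, 20001)
        y = phrase_response(t, 3.0)
        assert t[np.argmax(y)] == pytest.approx(1 / 3, abs=1e-3)
        assert y.max() == pytest.approx(3.0 / np.e, abs=1e-5)

    def test_tone_zero_at_origin(self):
        assert tone_response(0.0, 20.0, 0.9) == 0.0

    def test_tone_closed_form(self):
        # 1 - 3 e^-2 at beta=20, t=0.1
        assert tone_response(0.1, 20.0, 0.9) == pytest.approx(
            1 - 3 * np.exp(-2), abs=1e-9)

    def test_tone_monotone_and_clamped(self):
        t = np.linspace(0, 2, 10000)
        y = tone_response(t, 20.0, 0.9)
        assert np.all(np.diff(y) >= -1e-15)
        assert y.max() <= 0.9 + 1e-15
        assert y[-1] == pytest.approx(0.9)


class TestForward:
    def test_no_commands_is_baseline(self):
        cs = FujisakiCommandSet(Fb=120.0)
        t = np.linspace(0, 1, 101)
        assert np.allclose(synthesize_f0(cs, t), 120.0)

    def test_single_command_example(self):
        cs = FujisakiCommandSet(Fb=120.0, beta=20.0, gamma=0.9,
                                tone_commands=[(0.4, 0.0, 0.4)])
        f0 = synthesize_f0(cs, np.array([0.1]))[0]
        assert f0 == pytest.approx(120.0 * np.exp(0.4 * 0.5939941502901619),
                                   rel=1e-9)

    def test_log_domain_additivity(self):
        t = np.linspace(0, 1, 101)
        a = FujisakiCommandSet(Fb=100.0, tone_commands=[(0.3, 0.1, 0.4)])
        b = FujisakiCommandSet(Fb=100.0, tone_commands=[(-0.2, 0.3, 0.7)])
        both = FujisakiCommandSet(Fb=100.0,
                                  tone_commands=a.tone_commands + b.tone_commands)
        ratio = synthesize_f0(both, t) / 100.0
        assert np.allclose(ratio, (synthesize_f0(a, t) / 100.0)
                           * (synthesize_f0(b, t) / 100.0))

    def test_amplitude_scaling_linear_in_log(self):
        t = np.linspace(0, 1, 101)
        base = FujisakiCommandSet(Fb=100.0, tone_commands=[(0.3, 0.1, 0.5)])
        scaled = FujisakiCommandSet(Fb=100.0, tone_commands=[(0.6, 0.1, 0.5)])
        assert np.allclose(np.log(synthesize_f0(scaled, t) / 100.0),
                           2 * np.log(synthesize_f0(base, t) / 100.0))


class TestCommandTrack:
    def test_no_commands_zero(self):
        cs = FujisakiCommandSet(Fb=120.0)
        assert np.all(command_track(cs, np.linspace(0, 1, 11)) == 0)

    def test_single_rectangle(self):
        cs = FujisakiCommandSet(Fb=120.0, tone_commands=[(0.5, 0.1, 0.3)])
        t = np.arange(0, 0.5, 0.01)
        a = command_track(cs, t)
        assert np.allclose(a[(t >= 0.1) & (t < 0.3)], 0.5)
        assert np.allclose(a[(t < 0.1) | (t >= 0.3)], 0.0)

    def test_overlap_hand_sum(self):
        cs = FujisakiCommandSet(Fb=120.0,
                                tone_commands=[(0.5, 0.0, 0.2), (-0.3, 0.1, 0.3)])
        t = np.arange(0, 0.4, 0.01)
        a = command_track(cs, t)
        assert np.allclose(a[(t >= 0.1) & (t < 0.2)], 0.2)
        assert np.allclose(a[(t >= 0.0) & (t < 0.1)], 0.5)
        assert np.allclose(a[(t >= 0.2) & (t < 0.3)], -0.3)


class TestTemplates:
    def test_tone1_long_positive(self):
        cs = tone_template(1, 0.5)
        assert len(cs.tone_commands) == 1
        at, t1, t2 = cs.tone_commands[0]
        assert at > 0 and (t2 - t1) >= 0.8 * 0.5

    def test_tone3_long_negative(self):
        cs = tone_template(3, 0.5)
        assert len(cs.tone_commands) == 1
        assert cs.tone_commands[0][0] < 0

    def test_tone2_neg_then_pos(self):
        cs = tone_template(2, 0.5)
        (a1, _, e1), (a2, s2, _) = cs.tone_commands
        assert a1 < 0 < a2 and e1 <= s2

    def test_tone4_pos_then_neg(self):
        cs = tone_template(4, 0.5)
        (a1, _, e1), (a2, s2, _) = cs.tone_commands
        assert a1 > 0 > a2 and e1 <= s2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tone_template(5, 0.5)
        with pytest.raises(ValueError):
            tone_template(1, 1.5)


class TestInverse:
    @pytest.mark.parametrize("tone", [1, 2, 3, 4])
    def test_noiseless_round_trip(self, tone):
        tmpl = tone_template(tone, 0.5, Fb=118.0)
        t = np.arange(0, 0.5, 0.01)
        ct = SampledTrack(synthesize_f0(tmpl, t), 0.0, 100.0)
        cmds, diag = estimate_commands(ct, init=tmpl)
        assert diag["rmse"] < 1e-6
        for (a, t1, t2), (ea, e1, e2) in zip(tmpl.tone_commands,
                                             cmds.tone_commands):
            assert abs(ea - a) < 1e-3
            assert abs(e1 - t1) < 0.01 and abs(e2 - t2) < 0.01

    def test_constant_contour(self):
        ct = SampledTrack(np.full(60, 120.0), 0.0, 100.0)
        cmds, diag = estimate_commands(ct, n_tone_commands=1, n_starts=3)
        assert cmds.Fb == pytest.approx(120.0, rel=0.01)
        assert abs(cmds.tone_commands[0][0]) < 0.02

    def test_all_unvoiced_rejected(self):
        ct = SampledTrack(np.full(60, np.nan), 0.0, 100.0)
        with pytest.raises(ValueError, match="voiced"):
            estimate_commands(ct)

    def test_contract_on_fitted_commands(self):
        tmpl = tone_template(2, 0.5)
        t = np.arange(0, 0.5, 0.01)
        rng = np.random.default_rng(5)
        f0 = synthesize_f0(tmpl, t) * np.exp(0.02 * rng.standard_normal(t.size))
        f0[rng.random(t.size) < 0.1] = np.nan
        ct = SampledTrack(f0, 0.0, 100.0)
        cmds, _ = estimate_commands(ct, init=tmpl, seed=5)
        for _, t1, t2 in cmds.tone_commands:
            assert t1 < t2
        assert 0 < cmds.gamma <= 1

    def test_auto_selects_two_commands_for_rising_tone(self):
        tmpl = tone_template(2, 0.5, Fb=120.0)
        t = np.arange(0, 0.5, 0.01)
        ct = SampledTrack(synthesize_f0(tmpl, t), 0.0, 100.0)
        _, diag = estimate_commands(ct, n_tone_commands="auto", seed=0)
        assert diag["n_commands"] == 2

    def test_noisy_recovery_median_within_ten_percent(self):
        rng = np.random.default_rng(11)
        errs = []
        for k in range(12):
            tone = k % 4 + 1
            tmpl = tone_template(tone, 0.45, Fb=float(rng.normal(120, 10)))
            true = FujisakiCommandSet(
                tmpl.Fb, tmpl.alpha, tmpl.beta, tmpl.gamma,
                tone_commands=[(a * (1 + 0.15 * rng.standard_normal()), t1, t2)
                               for a, t1, t2 in tmpl.tone_commands])
            t = np.arange(0, 0.45, 0.01)
            f0 = synthesize_f0(true, t) * np.exp(0.02 * rng.standard_normal(t.size))
            f0[rng.random(t.size) < 0.1] = np.nan
            ct = SampledTrack(f0, 0.0, 100.0)
            cmds, _ = estimate_commands(ct, init=tmpl, seed=k)
            for (a, _, _), (ea, _, _) in zip(true.tone_commands,
                                             cmds.tone_commands):
                errs.append(abs(ea - a) / abs(a))
        assert np.median(errs) <= 0.10


def test_command_set_validation():
    with pytest.raises(ValueError):
        FujisakiCommandSet(Fb=-1.0)
    with pytest.raises(ValueError):
        FujisakiCommandSet(Fb=100.0, gamma=1.5)
    with pytest.raises(ValueError):
        FujisakiCommandSet(Fb=100.0, tone_commands=[(0.5, 0.3, 0.2)])


def test_json_round_trip():
    cs = FujisakiCommandSet(Fb=115.0, tone_commands=[(0.4, 0.0, 0.3)],
                            phrase_commands=[(0.5, -0.2)])
    back = FujisakiCommandSet.from_dict(cs.to_dict())
    assert back == cs
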