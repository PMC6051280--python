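"""Glottal quotients, perturbation measures and matching objectives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voicefold import (GlottalQuotients, InsufficientCycles, ObjectiveWeights,
                       PerturbationMeasures, compute_quotients, cycle_series,
                       detect_cycles, objective_fy, objective_fyp, perturbation)
from conftest import triangle_train


class TestCycleDetection:
    def test_triangle_landmarks_within_one_sample(self):
        fs = 25000.0
        u = triangle_train(125.0, fs, 0.5, oq=0.6, peak_frac=0.4)  # T0 = 200
        cycles = detect_cycles(u, fs)
        assert len(cycles) >= 55
        for c in cycles[1:-1]:
            assert c.period == pytest.approx(200, abs=1)
            assert (c.peak - c.opening) == pytest.approx(80, abs=1)
            assert (c.closing - c.opening) == pytest.approx(120, abs=1)

    def test_simulated_flow_cycle_count(self, sym_result):
        u = sym_result.signal("Ug")
        cycles = detect_cycles(u, sym_result.fs)
        f0_implied = len(cycles) / (u.size / sym_result.fs)
        # cycle rate tracks the phonation frequency (within edge effects)
        from voicefold import estimate_f0
        f0 = estimate_f0(u, sym_result.fs)
        assert f0_implied == pytest.approx(f0, rel=0.05)

    def test_all_zero_signal_rejected(self):
        with pytest.raises(InsufficientCycles):
            detect_cycles(np.zeros(10000), 25000.0)

    def test_too_few_cycles_rejected(self):
        u = triangle_train(100.0, 25000.0, 0.02)
        with pytest.raises(InsufficientCycles):
            detect_cycles(u, 25000.0)


class TestQuotients:
    def test_triangle_closed_forms(self):
        fs = 25000.0
        u = triangle_train(125.0, fs, 0.5, oq=0.6, peak_frac=0.4)
        q = compute_quotients(detect_cycles(u, fs), fs)
        # OQ = 0.6, SQ = 0.4/0.2 = 2, ClQ = 0.2, NAQ = 0.2 exactly
        tol = 1.0 / (0.2 * fs / 125.0)   # one sample of the closing phase
        assert q.F0 == pytest.approx(125.0, rel=0.01)
        assert q.OQ == pytest.approx(0.6, abs=2 * tol)
        assert q.SQ == pytest.approx(2.0, rel=0.05)
        assert q.ClQ == pytest.approx(0.2, abs=2 * tol)
        assert q.NAQ == pytest.approx(0.2, abs=2 * tol)

    @pytest.mark.parametrize("f0", [50.0, 125.0, 250.0, 400.0])
    def test_triangle_family_across_pitch(self, f0):
        fs = 25000.0
        u = triangle_train(f0, fs, max(0.5, 8 / f0), oq=0.6, peak_frac=0.4)
        q = compute_quotients(detect_cycles(u, fs), fs)
        samples_per_period = fs / f0
        tol = 3.0 / (0.2 * samples_per_period)
        assert q.OQ == pytest.approx(0.6, abs=tol)
        assert q.NAQ == pytest.approx(0.2, abs=tol)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_invariance(self, scale):
        fs = 25000.0
        u = triangle_train(125.0, fs, 0.3)
        q1 = compute_quotients(detect_cycles(u, fs), fs)
        q2 = compute_quotients(detect_cycles(scale * u, fs), fs)
        for name in ("F0", "OQ", "SQ", "ClQ", "NAQ"):
            assert getattr(q1, name) == pytest.approx(getattr(q2, name),
                                                      rel=1e-9)

    def test_simulated_flow_quotients_sane(self, sym_result):
        q = compute_quotients(
            detect_cycles(sym_result.signal("Ug"), sym_result.fs),
            sym_result.fs)
        assert 0 < q.ClQ <= q.OQ <= 1
        assert q.SQ > 0 and 0 < q.NAQ <= 1


class TestPerturbation:
    def test_constant_series_is_zero(self):
        s = {k: np.full(10, v) for k, v in
             (("F0", 100.0), ("OQ", 0.6), ("SQ", 2.0), ("ClQ", 0.2),
              ("NAQ", 0.2))}
        p = perturbation(s)
        assert all(v == 0.0 for v in p.as_dict().values())

    def test_alternating_closed_form(self):
        a, b = 0.5, 0.7
        s = {k: np.array([a, b] * 5) for k in
             ("F0", "OQ", "SQ", "ClQ", "NAQ")}
        p = perturbation(s)
        expected = 2 * abs(a - b) / (a + b)
        assert p.JOQ == pytest.approx(expected, rel=1e-9)

    def test_noiseless_simulation_is_nearly_periodic(self, sym_result):
        cycles = detect_cycles(sym_result.signal("Ug"), sym_result.fs)
        p = perturbation(cycle_series(cycles, sym_result.fs))
        for name, v in p.as_dict().items():
            assert v <= 1e-3, name

    def test_zero_mean_series_rejected(self):
        s = {k: np.array([1.0, -1.0, 1.0, -1.0]) for k in
             ("F0", "OQ", "SQ", "ClQ", "NAQ")}
        with pytest.raises(ValueError):
            perturbation(s)

    def test_too_short_series_rejected(self):
        s = {k: np.array([1.0, 1.0]) for k in
             ("F0", "OQ", "SQ", "ClQ", "NAQ")}
        with pytest.raises(InsufficientCycles):
            perturbation(s)


def _q(F0=100.0, OQ=0.6, SQ=2.0, ClQ=0.2, NAQ=0.2):
    return GlottalQuotients(F0=F0, OQ=OQ, SQ=SQ, ClQ=ClQ, NAQ=NAQ)


def _p(v=0.02):
    return PerturbationMeasures(JF0=v, JOQ=v, JSQ=v, JClQ=v, JNAQ=v)


class TestObjectives:
    def test_self_match_is_zero(self):
        assert objective_fy(_q(), _q()) == 0.0

    def test_ten_percent_error_closed_form(self):
        """All five statistics off by 10 %: FY = 0.125*0.4 + 0.5*0.1 = 0.1."""
        target = _q()
        sim = _q(F0=110.0, OQ=0.66, SQ=2.2, ClQ=0.22, NAQ=0.22)
        assert objective_fy(target, sim) == pytest.approx(0.1, rel=1e-9)

    def test_time_and_frequency_weights_balance(self):
        w = ObjectiveWeights()
        assert 4 * w.w1 == pytest.approx(w.w2)

    def test_denominators_use_target(self):
        target, sim = _q(OQ=0.5), _q(OQ=0.6)
        # |0.5-0.6|/0.5 with target in the denominator
        assert objective_fy(target, sim) == pytest.approx(0.125 * 0.1 / 0.5)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            objective_fy(_q(OQ=0.0), _q())

    def test_fyp_self_match_and_arithmetic(self):
        assert objective_fyp(_q(), _q(), _p(), _p()) == 0.0
        # FY = 0.1 and every J off by 10 %: FYp = 0.5*0.1 + 0.5*0.5 = 0.3
        sim = _q(F0=110.0, OQ=0.66, SQ=2.2, ClQ=0.22, NAQ=0.22)
        val = objective_fyp(_q(), sim, _p(0.02), _p(0.022))
        assert val == pytest.approx(0.3, rel=1e-9)

    def test_fyp_reduces_to_weighted_fy(self):
        w = ObjectiveWeights(w4=0.0)
        sim = _q(F0=110.0)
        assert objective_fyp(_q(), sim, _p(), _p(0.05), w) == pytest.approx(
            w.w3 * objective_fy(_q(), sim, w))

    def test_zero_target_j_dropped_with_warning(self):
        tp = PerturbationMeasures(JF0=0.0, JOQ=0.02, JSQ=0.02, JClQ=0.02,
                                  JNAQ=0.02)
        with pytest.warns(UserWarning):
            v = objective_fyp(_q(), _q(), tp, _p())
        assert np.isfinite(v)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_objective_amplitude_invariance_end_to_end(self, scale):
        fs = 25000.0
        u = triangle_train(125.0, fs, 0.3)
        qa = compute_quotients(detect_cycles(u, fs), fs)
        qb = compute_quotients(detect_cycles(scale * u, fs), fs)
        assert objective_fy(qa, qb) == pytest.approx(0.0, abs=1e-9)
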