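"""Model right-hand-side tests, including an independent symbolic transcription
of the full equation system that serves as a dual-transcription oracle."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from osteochemo import model
from osteochemo.model import (
    ExposureState,
    chemo_kill_rate,
    cycle_phase_factor,
    cytotoxic_enhancement,
    rhs_treated,
    rhs_untreated,
    saturation_kill,
)
from osteochemo.parameters import BaseParameterSet, default_chemo_parameters


# ---------------------------------------------------------------------------
# Independent symbolic transcription (kept deliberately separate from the
# package implementation; every term is written out from the equation system).

def _symbolic_treated_rhs():
    MN, M, TN, Th, Tr, Tc, DN, D, C, N, Ig, m1, m2, H, A1, A2, A3 = sp.symbols(
        "MN M TN Th Tr Tc DN D C N Ig m1 m2 H A1 A2 A3", nonnegative=True)
    states = (MN, M, TN, Th, Tr, Tc, DN, D, C, N, Ig, m1, m2, H, A1, A2, A3)

    bp = {n: sp.Symbol(n) for n in (
        "A_MN A_TN A_DN l_MIg l_Mm1 l_ThM l_ThD l_Trm1 l_TcTh l_TcM l_TcD "
        "l_DC l_DH l_C l_Cm1 l_Cm2 l_IgTh l_IgTc l_m1Th l_m1M l_m1C "
        "l_m2Th l_m2M l_m2C l_HM l_HD l_HN d_MN d_M d_TN d_ThTr d_Thm1 d_Th "
        "d_Tr d_TcTr d_Tcm1 d_Tc d_DN d_DC d_D d_CTc d_CIg d_C d_N d_Ig "
        "d_m1 d_m2 d_H C0 a_NC").split()}
    cp = {n: sp.Symbol(n) for n in (
        "f a tau b1 b2 b3 K_C K_MN K_M K_TN K_Th K_Tr K_Tc K_DN K_D "
        "d_CTcA3 a_NCA d_A1 d_A2 d_A3 v1 v2 v3").split()}
    g = {**bp, **cp}

    kill = lambda K: sp.Symbol(K) * (
        (g["f"] - g["tau"] / g["a"] + 1 / (24 * g["a"])) * (1 - sp.exp(-g["b1"] * A1))
        + (1 - sp.exp(-g["b2"] * A2)) + (1 - sp.exp(-g["b3"] * A3)))
    ctc_eff = g["d_CTc"] * (1 + g["d_CTcA3"] * (1 - sp.exp(-g["b3"] * A3)))

    eqs = [
        g["A_MN"] - (g["l_MIg"] * Ig + g["l_Mm1"] * m1) * MN - g["d_MN"] * MN
        - kill("K_MN") * MN,
        (g["l_MIg"] * Ig + g["l_Mm1"] * m1) * MN - g["d_M"] * M - kill("K_M") * M,
        g["A_TN"] - (g["l_ThM"] * M + g["l_ThD"] * D) * TN - g["l_Trm1"] * m1 * TN
        - (g["l_TcTh"] * Th + g["l_TcM"] * M + g["l_TcD"] * D) * TN
        - g["d_TN"] * TN - kill("K_TN") * TN,
        (g["l_ThM"] * M + g["l_ThD"] * D) * TN
        - (g["d_ThTr"] * Tr + g["d_Thm1"] * m1 + g["d_Th"]) * Th - kill("K_Th") * Th,
        g["l_Trm1"] * m1 * TN - g["d_Tr"] * Tr - kill("K_Tr") * Tr,
        (g["l_TcTh"] * Th + g["l_TcM"] * M + g["l_TcD"] * D) * TN
        - (g["d_TcTr"] * Tr + g["d_Tcm1"] * m1 + g["d_Tc"]) * Tc - kill("K_Tc") * Tc,
        g["A_DN"] - (g["l_DC"] * C + g["l_DH"] * H) * DN - g["d_DN"] * DN
        - kill("K_DN") * DN,
        (g["l_DC"] * C + g["l_DH"] * H) * DN - (g["d_DC"] * C + g["d_D"]) * D
        - kill("K_D") * D,
        (g["l_C"] + g["l_Cm1"] * m1 + g["l_Cm2"] * m2) * C * (1 - C / g["C0"])
        - (g["d_CIg"] * Ig + g["d_C"] + ctc_eff * Tc) * C - kill("K_C") * C,
        g["a_NC"] * (g["d_CIg"] * Ig + g["d_C"] + ctc_eff * Tc) * C
        + g["a_NCA"] * kill("K_C") * C - g["d_N"] * N,
        g["l_IgTh"] * Th + g["l_IgTc"] * Tc - g["d_Ig"] * Ig,
        g["l_m1Th"] * Th + g["l_m1M"] * M + g["l_m1C"] * C - g["d_m1"] * m1,
        g["l_m2Th"] * Th + g["l_m2M"] * M + g["l_m2C"] * C - g["d_m2"] * m2,
        g["l_HM"] * M + g["l_HD"] * D + g["l_HN"] * N - g["d_H"] * H,
        g["v1"] - g["d_A1"] * A1,
        g["v2"] - g["d_A2"] * A2,
        g["v3"] - g["d_A3"] * A3,
    ]
    order = ("A_MN A_TN A_DN l_MIg l_Mm1 l_ThM l_ThD l_Trm1 l_TcTh l_TcM "
             "l_TcD l_DC l_DH l_C l_Cm1 l_Cm2 l_IgTh l_IgTc l_m1Th l_m1M "
             "l_m1C l_m2Th l_m2M l_m2C l_HM l_HD l_HN d_MN d_M d_TN d_ThTr "
             "d_Thm1 d_Th d_Tr d_TcTr d_Tcm1 d_Tc d_DN d_DC d_D d_CTc d_CIg "
             "d_C d_N d_Ig d_m1 d_m2 d_H C0 a_NC f a tau b1 b2 b3 K_C K_MN "
             "K_M K_TN K_Th K_Tr K_Tc K_DN K_D d_CTcA3 a_NCA d_A1 d_A2 d_A3 "
             "v1 v2 v3").split()
    fn = sp.lambdify((states, [g[n] for n in order]), eqs, "numpy")
    return fn, order


_BASE_FIELD_MAP = {
    "A_MN": "A_MN", "A_TN": "A_TN", "A_DN": "A_DN",
    "l_MIg": "lambda_MIg", "l_Mm1": "lambda_Mmu1", "l_ThM": "lambda_ThM",
    "l_ThD": "lambda_ThD", "l_Trm1": "lambda_Trmu1", "l_TcTh": "lambda_TcTh",
    "l_TcM": "lambda_TcM", "l_TcD": "lambda_TcD", "l_DC": "lambda_DC",
    "l_DH": "lambda_DH", "l_C": "lambda_C", "l_Cm1": "lambda_Cmu1",
    "l_Cm2": "lambda_Cmu2", "l_IgTh": "lambda_IgTh", "l_IgTc": "lambda_IgTc",
    "l_m1Th": "lambda_mu1Th", "l_m1M": "lambda_mu1M", "l_m1C": "lambda_mu1C",
    "l_m2Th": "lambda_mu2Th", "l_m2M": "lambda_mu2M", "l_m2C": "lambda_mu2C",
    "l_HM": "lambda_HM", "l_HD": "lambda_HD", "l_HN": "lambda_HN",
    "d_MN": "delta_MN", "d_M": "delta_M", "d_TN": "delta_TN",
    "d_ThTr": "delta_ThTr", "d_Thm1": "delta_Thmu1", "d_Th": "delta_Th",
    "d_Tr": "delta_Tr", "d_TcTr": "delta_TcTr", "d_Tcm1": "delta_Tcmu1",
    "d_Tc": "delta_Tc", "d_DN": "delta_DN", "d_DC": "delta_DC",
    "d_D": "delta_D", "d_CTc": "delta_CTc", "d_CIg": "delta_CIg",
    "d_C": "delta_C", "d_N": "delta_N", "d_Ig": "delta_Ig",
    "d_m1": "delta_mu1", "d_m2": "delta_mu2", "d_H": "delta_H",
    "C0": "C0", "a_NC": "alpha_NC",
}
_CHEMO_FIELD_MAP = {
    "f": "f", "a": "a", "b1": "beta1", "b2": "beta2", "b3": "beta3",
    "K_C": "K_C", "K_MN": "K_MN", "K_M": "K_M", "K_TN": "K_TN",
    "K_Th": "K_Th", "K_Tr": "K_Tr", "K_Tc": "K_Tc", "K_DN": "K_DN",
    "K_D": "K_D", "d_CTcA3": "delta_CTcA3", "a_NCA": "alpha_NCA",
    "d_A1": "delta_A1", "d_A2": "delta_A2", "d_A3": "delta_A3",
}


def _oracle_rhs(x, p, chemo, tau, v):
    fn, order = _SYMBOLIC
    vals = []
    for name in order:
        if name in _BASE_FIELD_MAP:
            vals.append(getattr(p, _BASE_FIELD_MAP[name]))
        elif name in _CHEMO_FIELD_MAP:
            vals.append(getattr(chemo, _CHEMO_FIELD_MAP[name]))
        elif name == "tau":
            vals.append(tau)
        else:
            vals.append({"v1": v[0], "v2": v[1], "v3": v[2]}[name])
    return np.array(fn(tuple(x), vals), dtype=float)


_SYMBOLIC = _symbolic_treated_rhs()


def _random_params(rng):
    fields = {f: rng.uniform(0.01, 1.0) for f in _BASE_FIELD_MAP.values()}
    fields["C0"] = rng.uniform(10.0, 50.0)
    fields["alpha_NC"] = rng.uniform(0.1, 0.9)
    return BaseParameterSet(**fields)


# ---------------------------------------------------------------------------


class TestKillTerms:
    def test_no_drug_no_kill(self):
        assert saturation_kill(1.8328, 0.0) == 0.0

    def test_derived_value(self):
        assert saturation_kill(1.8328, 1.0) == pytest.approx(1 - np.exp(-1.8328))

    def test_saturation_limit(self):
        assert saturation_kill(0.1467, 1e6) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0, 5), st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, beta, a_lo, d):
        lo, hi = saturation_kill(beta, a_lo), saturation_kill(beta, a_lo + d)
        assert 0.0 <= lo <= hi < 1.0 + 1e-15

    def test_phase_factor_examples(self):
        a = 0.6667
        assert cycle_phase_factor(0.5, 1.0 / 6.0, a) == pytest.approx(0.3125, abs=2e-4)
        assert cycle_phase_factor(0.5, 0.5 * a, a) == pytest.approx(1 / (24 * a))
        assert cycle_phase_factor(0.5, 0.0, a) == pytest.approx(0.5 + 1 / (24 * a))

    def test_phase_factor_rejects_bad_cycle_time(self):
        with pytest.raises(ValueError):
            cycle_phase_factor(0.5, 0.0, 0.0)

    def test_kill_rate_examples(self):
        ch = default_chemo_parameters()
        exp = ExposureState.from_times([0.0, 0.0, 0.0], ch)
        assert chemo_kill_rate(0.9, ch, exp, 0.0, 0.0, 0.0) == 0.0
        # doxorubicin saturation alone gives the full one-log-kill rate
        assert chemo_kill_rate(0.9, ch, exp, 0.0, 1e9, 0.0) == pytest.approx(0.9)
        assert chemo_kill_rate(0.9, ch, exp, 0.0, 1.0, 0.0) == pytest.approx(
            0.9 * (1 - np.exp(-ch.beta2)), rel=1e-12)

    @given(st.floats(0, 3), st.floats(0, 3), st.floats(0, 3))
    @settings(max_examples=60, deadline=None)
    def test_kill_rate_bounded(self, A1, A2, A3):
        ch = default_chemo_parameters()
        exp = ExposureState.from_times([0.05, 0.0, 0.0], ch)
        k = chemo_kill_rate(ch.K_C, ch, exp, A1, A2, A3)
        phase = cycle_phase_factor(ch.f, exp.tau[0], ch.a)
        assert 0.0 <= k <= ch.K_C * (phase + 2.0) + 1e-12

    def test_enhancement_examples(self):
        assert cytotoxic_enhancement(0.3, 1.0, 0.1467, 0.0) == pytest.approx(0.3)
        assert cytotoxic_enhancement(0.3, 1.0, 0.1467, 1e9) == pytest.approx(0.6)
        # delta_CTcA3=0.5 and 40% saturation -> 1.2x baseline
        A3 = -np.log(0.6) / 0.1467
        assert cytotoxic_enhancement(0.3, 0.5, 0.1467, A3) == pytest.approx(0.36)


class TestExposureState:
    def test_clock_capping(self):
        ch = default_chemo_parameters()
        exp = ExposureState.from_times([1.0, 0.0, 0.0], ch)
        assert exp.tau[0] == pytest.approx(ch.f * ch.a)
        exp2 = ExposureState.from_times([0.05, 0.0, 0.0], ch)
        assert exp2.tau[0] == pytest.approx(0.05)

    def test_invalid_clocks_rejected(self):
        with pytest.raises(ValueError):
            ExposureState(T=[1.0], tau=[2.0])


class TestUntreatedRHS:
    def test_zero_state_leaves_only_sources(self, rng):
        p = _random_params(rng)
        dx = rhs_untreated(np.zeros(17), p)
        expected = np.zeros(17)
        expected[0], expected[2], expected[6] = p.A_MN, p.A_TN, p.A_DN
        np.testing.assert_allclose(dx, expected)

    def test_cancer_at_capacity_only_dies(self, rng):
        p = _random_params(rng)
        x = np.zeros(17)
        x[8] = p.C0
        assert rhs_untreated(x, p)[8] == pytest.approx(-p.delta_C * p.C0, rel=1e-12)

    def test_matches_symbolic_transcription(self, rng):
        ch = default_chemo_parameters()
        for _ in range(20):
            p = _random_params(rng)
            x = rng.uniform(0.0, 5.0, 17)
            x[14:] = 0.0
            got = rhs_untreated(x, p)
            want = _oracle_rhs(x, p, ch, 0.0, np.zeros(3))
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)


class TestTreatedRHS:
    def test_reduces_exactly_to_untreated(self, rng):
        ch = default_chemo_parameters()
        exp = ExposureState.from_times([0.2, 0.2, 0.2], ch)
        for _ in range(10):
            p = _random_params(rng)
            x = rng.uniform(0.0, 5.0, 17)
            x[14:] = 0.0
            treated = rhs_treated(x, p, ch, exp, np.zeros(3))
            untreated = rhs_untreated(x, p)
            assert np.array_equal(treated, untreated)  # bitwise

    def test_drug_subsystem_fixed_point(self, rng):
        ch = default_chemo_parameters()
        p = _random_params(rng)
        v = np.array([2.0, 3.0, 4.0])
        x = np.zeros(17)
        x[14:] = v / ch.drug_decay
        dx = rhs_treated(x, p, ch, ExposureState.from_times([0.0] * 3, ch), v)
        np.testing.assert_allclose(dx[14:], 0.0, atol=1e-12)

    def test_matches_symbolic_transcription(self, rng):
        ch = default_chemo_parameters()
        for _ in range(20):
            p = _random_params(rng)
            x = rng.uniform(0.0, 5.0, 17)
            T = rng.uniform(0.0, 1.0)
            v = rng.uniform(0.0, 10.0, 3)
            exp = ExposureState.from_times([T, T, T], ch)
            got = rhs_treated(x, p, ch, exp, v)
            want = _oracle_rhs(x, p, ch, float(exp.tau[0]), v)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)

    def test_necrotic_influx_bookkeeping(self, rng):
        """Chemo contribution to dN/dt is alpha_NCA times the chemo kill flux of C."""
        ch = default_chemo_parameters()
        for _ in range(10):
            p = _random_params(rng)
            x = rng.uniform(0.1, 5.0, 17)
            exp = ExposureState.from_times([0.1] * 3, ch)
            v = np.zeros(3)
            dx_on = rhs_treated(x, p, ch, exp, v)
            x_off = x.copy()
            x_off[14:] = 0.0
            dx_off = rhs_treated(x_off, p, ch, exp, v)
            kill_flux = ch.K_C * model.kill_bracket(ch, exp.tau[0], *x[14:]) * x[8]
            # enhanced cytotoxic term also feeds N via alpha_NC
            enh = cytotoxic_enhancement(p.delta_CTc, ch.delta_CTcA3, ch.beta3, x[16])
            extra_base = p.alpha_NC * (enh - p.delta_CTc) * x[5] * x[8]
            dN_chemo = dx_on[9] - dx_off[9]
            assert dN_chemo == pytest.approx(
                ch.alpha_NCA * kill_flux + extra_base, rel=1e-9)

    def test_broadcasts_over_columns(self, rng):
        ch = default_chemo_parameters()
        p = _random_params(rng)
        X = rng.uniform(0.0, 5.0, (17, 4))
        exp = ExposureState.from_times([0.1] * 3, ch)
        v = rng.uniform(0, 5, 3)
        batch = rhs_treated(X, p, ch, exp, v)
        for j in range(4):
            np.testing.assert_allclose(
                batch[:, j], rhs_treated(X[:, j], p, ch, exp, v), rtol=1e-12)
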