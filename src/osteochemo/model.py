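"""State vector and right-hand sides of the tumor-immune-chemotherapy system.

The model tracks 17 states in a fixed canonical order: naive macrophages M_N,
macrophages M, naive T cells T_N, helper T cells T_h, regulatory T cells T_r,
cytotoxic cells T_c, naive dendritic cells D_N, dendritic cells D, cancer
cells C, necrotic cells N, IFN-γ I_γ, cytokine groups μ1 and μ2, HMGB1 H, and
the three drug concentrations A1 (methotrexate), A2 (doxorubicin), A3
(cisplatin) in mg/L.

Untreated dynamics: mass-action activation of mature immune cells from naive
pools, logistic cancer growth promoted by μ1/μ2, cancer killing by cytotoxic
cells and IFN-γ, necrotic influx as a fraction α_NC of dying cancer cells,
and linear cytokine production/decay.

Chemotherapy adds, for cancer and each immune population X, an exponential
kill term K_X·[φ·(1−e^{−β1·A1}) + (1−e^{−β2·A2}) + (1−e^{−β3·A3})]·X, where
the cell-cycle phase factor φ = f − τ/a + 1/(24a) applies only to the
cell-cycle-specific methotrexate; cisplatin additionally amplifies the
cytotoxic-cell kill rate by (1 + δ_CTcA3·(1−e^{−β3·A3})); drugs follow
dA/dt = v_A(t) − δ_A·A.

All RHS functions broadcast over a trailing axis: ``x`` may be shape (17,) or
(17, k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import BaseParameterSet, ChemoParameterSet

__all__ = [
    "STATE_NAMES",
    "IDX",
    "CELL_STATES",
    "IMMUNE_STATES",
    "ExposureState",
    "saturation_kill",
    "cycle_phase_factor",
    "chemo_kill_rate",
    "cytotoxic_enhancement",
    "rhs_untreated",
    "rhs_treated",
]

STATE_NAMES = (
    "M_N", "M", "T_N", "T_h", "T_r", "T_c", "D_N", "D",
    "C", "N", "I_g", "mu1", "mu2", "H", "A1", "A2", "A3",
)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: The ten cell compartments (used for "total cell population" outputs).
CELL_STATES = ("M_N", "M", "T_N", "T_h", "T_r", "T_c", "D_N", "D", "C", "N")
#: The eight immune populations subject to chemo-induced death, in the order
#: matching ChemoParameterSet.IMMUNE_KILL_FIELDS.
IMMUNE_STATES = ("M_N", "M", "T_N", "T_h", "T_r", "T_c", "D_N", "D")

N_STATES = len(STATE_NAMES)
N_BASE = 14  # cells + cytokines (drug concentrations excluded)


@dataclass(frozen=True)
class ExposureState:
    """Per-drug exposure clocks.

    ``T`` is the time in days since the current (most recent) infusion of each
    drug began (0 before any infusion); ``tau`` = min(T, f·a) caps the
    methotrexate cell-cycle clock at the vulnerable window length.
    Arrays are ordered (methotrexate, doxorubicin, cisplatin).
    """

    T: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        T = np.atleast_1d(np.asarray(self.T, dtype=float))
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "tau", tau)
        if np.any(T < 0) or np.any(tau < 0) or np.any(tau > T + 1e-12):
            raise ValueError("exposure clocks require 0 <= tau <= T")

    @classmethod
    def from_times(cls, T, chemo: ChemoParameterSet) -> "ExposureState":
        T = np.atleast_1d(np.asarray(T, dtype=float))
        return cls(T=T, tau=np.minimum(T, chemo.f * chemo.a))


def saturation_kill(beta, A):
    """Exponential-kill saturation term 1 − e^{−βA} ∈ [0, 1).

    Nearly linear (≈ βA) at low concentration, saturating to 1 at high
    concentration.
    """
    return -np.expm1(-np.asarray(beta) * np.asarray(A))


def cycle_phase_factor(f: float, tau, a: float):
    """Cell-cycle phase factor φ = f − τ/a + 1/(24a) for a cycle-specific drug.

    ``f`` is the initial vulnerable-phase fraction, ``a`` the cell-cycle time
    in days, and τ = min(T, f·a) the capped exposure clock; the 1/(24a) term
    keeps one hour's worth of cells vulnerable once the initial fraction has
    been exhausted. Isolated here so alternative readings of the factor can be
    swapped in one place.
    """
    if a <= 0:
        raise ValueError("cell cycle time a must be > 0")
    return f - np.asarray(tau) / a + 1.0 / (24.0 * a)


def kill_bracket(chemo: ChemoParameterSet, tau_mtx, A1, A2, A3):
    """The shared exponential-kill bracket
    φ·(1−e^{−β1·A1}) + (1−e^{−β2·A2}) + (1−e^{−β3·A3}),
    with φ the methotrexate phase factor at the capped clock ``tau_mtx``."""
    phase = cycle_phase_factor(chemo.f, tau_mtx, chemo.a)
    return (phase * saturation_kill(chemo.beta1, A1)
            + saturation_kill(chemo.beta2, A2)
            + saturation_kill(chemo.beta3, A3))


def chemo_kill_rate(K, chemo: ChemoParameterSet, exposure: ExposureState, A1, A2, A3):
    """Chemo-induced per-capita death rate (day⁻¹) for one population.

    K·[φ·(1−e^{−β1·A1}) + (1−e^{−β2·A2}) + (1−e^{−β3·A3})] with φ the
    methotrexate phase factor evaluated at the methotrexate exposure clock.
    The same form applies to cancer (K = K_C) and every immune population.
    """
    return K * kill_bracket(chemo, exposure.tau[0], A1, A2, A3)


def cytotoxic_enhancement(delta_CTc, delta_CTcA3, beta3, A3):
    """Cisplatin-amplified cytotoxic kill rate δ_CTc·(1 + δ_CTcA3·(1−e^{−β3·A3})).

    At δ_CTcA3 = 1 and saturating cisplatin the cytotoxic-cell cancer-killing
    rate doubles.
    """
    return delta_CTc * (1.0 + delta_CTcA3 * saturation_kill(beta3, A3))


def _rhs_core(x, p: BaseParameterSet, delta_CTc_eff, kill_cancer, kill_immune,
              alpha_NCA, v, drug_decay):
    """Shared RHS assembly for the treated and untreated systems.

    The untreated system is the special case delta_CTc_eff = δ_CTc,
    kill_* = 0, v = 0: every term is then evaluated in the identical floating
    point order, so the reduction is exact.
    """
    x = np.asarray(x, dtype=float)
    (M_N, M, T_N, T_h, T_r, T_c, D_N, D, C, N, I_g, mu1, mu2, H,
     A1, A2, A3) = x

    dx = np.empty_like(x)

    m_act = p.lambda_MIg * I_g + p.lambda_Mmu1 * mu1
    dx[0] = p.A_MN - m_act * M_N - p.delta_MN * M_N - kill_immune[0] * M_N
    dx[1] = m_act * M_N - p.delta_M * M - kill_immune[1] * M

    th_act = p.lambda_ThM * M + p.lambda_ThD * D
    tr_act = p.lambda_Trmu1 * mu1
    tc_act = p.lambda_TcTh * T_h + p.lambda_TcM * M + p.lambda_TcD * D
    dx[2] = (p.A_TN - th_act * T_N - tr_act * T_N - tc_act * T_N
             - p.delta_TN * T_N - kill_immune[2] * T_N)
    dx[3] = (th_act * T_N
             - (p.delta_ThTr * T_r + p.delta_Thmu1 * mu1 + p.delta_Th) * T_h
             - kill_immune[3] * T_h)
    dx[4] = tr_act * T_N - p.delta_Tr * T_r - kill_immune[4] * T_r
    dx[5] = (tc_act * T_N
             - (p.delta_TcTr * T_r + p.delta_Tcmu1 * mu1 + p.delta_Tc) * T_c
             - kill_immune[5] * T_c)

    d_act = p.lambda_DC * C + p.lambda_DH * H
    dx[6] = p.A_DN - d_act * D_N - p.delta_DN * D_N - kill_immune[6] * D_N
    dx[7] = d_act * D_N - (p.delta_DC * C + p.delta_D) * D - kill_immune[7] * D

    growth = (p.lambda_C + p.lambda_Cmu1 * mu1 + p.lambda_Cmu2 * mu2) * C * (1.0 - C / p.C0)
    base_death = delta_CTc_eff * T_c + p.delta_CIg * I_g + p.delta_C
    dx[8] = growth - base_death * C - kill_cancer * C
    dx[9] = p.alpha_NC * base_death * C + alpha_NCA * kill_cancer * C - p.delta_N * N

    dx[10] = p.lambda_IgTh * T_h + p.lambda_IgTc * T_c - p.delta_Ig * I_g
    dx[11] = p.lambda_mu1Th * T_h + p.lambda_mu1M * M + p.lambda_mu1C * C - p.delta_mu1 * mu1
    dx[12] = p.lambda_mu2Th * T_h + p.lambda_mu2M * M + p.lambda_mu2C * C - p.delta_mu2 * mu2
    dx[13] = p.lambda_HM * M + p.lambda_HD * D + p.lambda_HN * N - p.delta_H * H

    dx[14] = v[0] - drug_decay[0] * A1
    dx[15] = v[1] - drug_decay[1] * A2
    dx[16] = v[2] - drug_decay[2] * A3
    return dx


_ZERO3 = np.zeros(3)
_ZERO8 = np.zeros(8)


def rhs_untreated(x, p: BaseParameterSet):
    """Time derivatives of the drug-free system (drug states decay freely)."""
    return _rhs_core(x, p, p.delta_CTc, 0.0, _ZERO8, 0.0, _ZERO3, _ZERO3)


def rhs_treated_tau(x, p: BaseParameterSet, chemo: ChemoParameterSet,
                    tau_mtx, infusion_rates):
    """Treated-system derivatives with the methotrexate clock passed directly.

    Fast path for integrators that track τ themselves; semantics identical to
    :func:`rhs_treated`. The kill bracket is shared by cancer and every
    immune population, each scaled by its own K.
    """
    x = np.asarray(x, dtype=float)
    A1, A2, A3 = x[14], x[15], x[16]
    bracket = kill_bracket(chemo, tau_mtx, A1, A2, A3)
    kill_cancer = chemo.K_C * bracket
    kill_immune = [K * bracket for K in chemo.immune_kill]
    delta_CTc_eff = cytotoxic_enhancement(p.delta_CTc, chemo.delta_CTcA3, chemo.beta3, A3)
    return _rhs_core(
        x, p, delta_CTc_eff, kill_cancer, kill_immune, chemo.alpha_NCA,
        infusion_rates, chemo.drug_decay,
    )


def rhs_treated(x, p: BaseParameterSet, chemo: ChemoParameterSet,
                exposure: ExposureState, infusion_rates):
    """Time derivatives of the chemotherapy-extended system.

    ``infusion_rates`` is the per-drug input v_A(t) in mg/L per day. Reduces
    bit-exactly to :func:`rhs_untreated` when all drug concentrations and
    infusion rates vanish.
    """
    return rhs_treated_tau(x, p, chemo, exposure.tau[0],
                           np.asarray(infusion_rates, dtype=float))
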