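"""Synthetic cluster scenarios for the osteosarcoma tumor-immune model.

The study conditions this package targets are three clusters of osteosarcoma
tumors with distinct immune-infiltration patterns: one whose cancer grows
fast even when small (cluster 1) and two slower-growing ones, with cluster 2
carrying the largest tumors. The cluster-specific base-model rate constants
were fitted to deconvolved gene-expression data in prior work and are not
available as numbers, so this module *constructs* parameter sets with the
same dynamical structure instead of estimating them:

1. a cluster profile declares immune compartment fractions, tissue
   percentages, a tumor growth rate, and dimensionless turnover knobs
   (per-capita activation rates, loss splits, cytokine turnovers);
2. the profile is turned into a target steady state (immune populations =
   fractions × α_dim; cancer/necrotic populations via the tissue-percentage
   ratios; reference cohort cancer populations for the large/medium/small
   variants);
3. :func:`backsolve_parameters` chooses the naive-cell source rates and the
   own-death/decay rates so that the untreated system is exactly at
   equilibrium at the target state.

The construction is homogeneous in α_dim: scaling all populations and the
carrying capacity together rescales the bilinear rates inversely, leaving
scaled trajectories identical — which is what makes α_dim a pure bookkeeping
constant.

Synthetic profiles are illustrative stand-ins, not estimates of any real
cluster's immune composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import IDX, IMMUNE_STATES, N_STATES
from .parameters import BaseParameterSet, ChemoParameterSet, default_chemo_parameters
from .units import ALPHA_DIM_DEFAULT

__all__ = [
    "ClusterProfile",
    "ClusterScenario",
    "CLUSTER_PROFILES",
    "generate_fraction_table",
    "backsolve_parameters",
    "build_scenario",
    "make_cluster_suite",
]


@dataclass(frozen=True)
class ClusterProfile:
    """Declarative description of one synthetic immune cluster.

    ``immune_fractions`` are mean compartment proportions of the total immune
    population (summing to 1 over the eight modeled immune compartments —
    the 22 deconvolution cell types are aggregated to the model's compartment
    level). ``growth_rate`` is the total per-capita logistic growth
    coefficient λ_C + λ_Cμ1·μ1∞ + λ_Cμ2·μ2∞ in day⁻¹. Cancer populations of
    the large/medium/small tumor variants are given in cells.
    """

    cluster_id: int
    growth_label: str  # "fast" or "slow"
    growth_rate: float  # day⁻¹
    immune_fractions: dict
    pct_cancer: float
    pct_necrotic: float
    pct_normal: float
    cancer_large: float
    cancer_medium: float
    cancer_small: float
    # Dirichlet concentration for per-tumor fraction draws
    fraction_concentration: float = 200.0


# Per-capita turnover knobs shared by every synthetic cluster. Chosen once to
# give immunologically plausible timescales: slow macrophage turnover, naive
# pools recovering within days, cytokines equilibrating within hours, necrotic
# clearance of about a day, and an HMGB1 pool dominated by necrotic release.
KNOBS = {
    "cc_ratio": 0.5,            # C∞ / C0
    "growth_split": (0.90, 0.05, 0.05),       # λ_C, μ1-, μ2-driven shares
    "cancer_death_split": (0.10, 0.05, 0.85),  # T_c, IFN-γ, intrinsic shares
    "alpha_NC": 0.5,
    "delta_N": 1.0,             # day⁻¹ necrotic clearance
    "r_M": 0.02, "m_act_split": (0.2, 0.8), "delta_MN": 0.1,
    "r_Th": 0.10, "th_act_split": (0.15, 0.85),
    "r_Tr": 0.02,
    "r_Tc": 0.12, "tc_act_split": (0.3, 0.05, 0.65),
    "delta_TN": 0.3,
    "th_loss_split": (0.35, 0.35, 0.30),  # T_r-, μ1-, self-inhibition shares
    "tc_loss_split": (0.35, 0.25, 0.40),
    "r_D": 0.30, "d_act_split": (0.15, 0.85), "delta_DN": 0.2,
    "d_loss_split": (0.2, 0.8),         # tumor-factor vs intrinsic
    "delta_Ig": 4.0, "ig_split": (0.5, 0.5),
    "delta_mu1": 5.0, "delta_mu2": 5.0, "mu_split": (0.15, 0.15, 0.70),
    "delta_H": 10.0, "h_split": (0.1, 0.1, 0.8),
    # cytokine steady levels per unit alpha_dim (arbitrary abundance units)
    "ig_level": 5.7e-4, "mu1_level": 5.7e-4, "mu2_level": 4.5e-4, "h_level": 2.8e-4,
}


CLUSTER_PROFILES: dict[int, ClusterProfile] = {
    1: ClusterProfile(
        cluster_id=1, growth_label="fast", growth_rate=0.035,
        immune_fractions={"M_N": 0.19, "M": 0.34, "T_N": 0.17, "T_h": 0.09,
                          "T_r": 0.07, "T_c": 0.06, "D_N": 0.05, "D": 0.03},
        pct_cancer=75.9, pct_necrotic=1.9, pct_normal=1.0,
        cancer_large=1.34e10, cancer_medium=6.9e9, cancer_small=2.7e8,
    ),
    2: ClusterProfile(
        cluster_id=2, growth_label="slow", growth_rate=0.022,
        immune_fractions={"M_N": 0.15, "M": 0.25, "T_N": 0.20, "T_h": 0.12,
                          "T_r": 0.06, "T_c": 0.12, "D_N": 0.06, "D": 0.04},
        pct_cancer=90.6, pct_necrotic=1.6, pct_normal=1.0,
        cancer_large=1.6e10, cancer_medium=6.96e9, cancer_small=3.07e8,
    ),
    3: ClusterProfile(
        cluster_id=3, growth_label="slow", growth_rate=0.018,
        immune_fractions={"M_N": 0.12, "M": 0.20, "T_N": 0.20, "T_h": 0.14,
                          "T_r": 0.04, "T_c": 0.18, "D_N": 0.07, "D": 0.05},
        pct_cancer=75.9, pct_necrotic=1.4, pct_normal=1.0,
        cancer_large=1.34e10, cancer_medium=5.05e9, cancer_small=1.93e8,
    ),
}


@dataclass
class ClusterScenario:
    """A fully constructed synthetic cluster: states + back-solved parameters."""

    cluster_id: int
    growth_label: str
    immune_fractions: dict
    pct_cancer: float
    pct_necrotic: float
    pct_normal: float
    params: BaseParameterSet
    chemo: ChemoParameterSet
    steady_state: np.ndarray          # = the "large tumor" initial condition
    initial_states: dict = field(default_factory=dict)  # small/medium/large
    alpha_dim: float = ALPHA_DIM_DEFAULT
    seed: int | None = None

    @property
    def x_inf(self) -> np.ndarray:
        return self.steady_state[:14]


class BacksolveError(ValueError):
    pass


def backsolve_parameters(target_state, rates: BaseParameterSet) -> BaseParameterSet:
    """Complete a parameter set so the untreated system is at equilibrium at
    ``target_state``.

    ``rates`` supplies the interaction/production coefficients (all λ's, the
    cross-inhibition δ's, C0, α_NC); the naive sources A_MN/A_TN/A_DN and the
    own-death/decay rates δ_M, δ_Th, δ_Tr, δ_Tc, δ_D, δ_C, δ_N, δ_Iγ, δ_μ1,
    δ_μ2, δ_H are solved from the 14 equilibrium equations. An equation whose
    balance would require a negative rate raises :class:`BacksolveError`
    naming the offending state.
    """
    x = np.asarray(target_state, dtype=float)
    if x.shape[0] < 14 or np.any(x[:14] <= 0):
        raise BacksolveError("target state must be positive in all 14 base states")
    p = rates
    M_N, M, T_N, T_h, T_r, T_c, D_N, D, C, N, I_g, mu1, mu2, H = x[:14]
    if C >= p.C0:
        raise BacksolveError("target cancer population must lie below C0")

    m_act = p.lambda_MIg * I_g + p.lambda_Mmu1 * mu1
    th_act = p.lambda_ThM * M + p.lambda_ThD * D
    tr_act = p.lambda_Trmu1 * mu1
    tc_act = p.lambda_TcTh * T_h + p.lambda_TcM * M + p.lambda_TcD * D
    d_act = p.lambda_DC * C + p.lambda_DH * H

    solved = {
        "A_MN": (m_act + p.delta_MN) * M_N,
        "delta_M": m_act * M_N / M,
        "A_TN": (th_act + tr_act + tc_act + p.delta_TN) * T_N,
        "delta_Th": th_act * T_N / T_h - p.delta_ThTr * T_r - p.delta_Thmu1 * mu1,
        "delta_Tr": tr_act * T_N / T_r,
        "delta_Tc": tc_act * T_N / T_c - p.delta_TcTr * T_r - p.delta_Tcmu1 * mu1,
        "A_DN": (d_act + p.delta_DN) * D_N,
        "delta_D": d_act * D_N / D - p.delta_DC * C,
        "delta_C": ((p.lambda_C + p.lambda_Cmu1 * mu1 + p.lambda_Cmu2 * mu2)
                    * (1.0 - C / p.C0)
                    - p.delta_CTc * T_c - p.delta_CIg * I_g),
        "delta_Ig": (p.lambda_IgTh * T_h + p.lambda_IgTc * T_c) / I_g,
        "delta_mu1": (p.lambda_mu1Th * T_h + p.lambda_mu1M * M + p.lambda_mu1C * C) / mu1,
        "delta_mu2": (p.lambda_mu2Th * T_h + p.lambda_mu2M * M + p.lambda_mu2C * C) / mu2,
        "delta_H": (p.lambda_HM * M + p.lambda_HD * D + p.lambda_HN * N) / H,
    }
    death_C = p.delta_CTc * T_c + p.delta_CIg * I_g + solved["delta_C"]
    solved["delta_N"] = p.alpha_NC * death_C * C / N
    for name, v in solved.items():
        if v < 0:
            eq = {"delta_Th": "T_h", "delta_Tc": "T_c", "delta_D": "D",
                  "delta_C": "C"}.get(name, name)
            raise BacksolveError(
                f"equilibrium at the target would need negative {name} "
                f"(equation for {eq}); weaken the cross-inhibition rates")
    return p.replace(**solved)


def _target_steady_state(profile: ClusterProfile, alpha_dim: float,
                         knobs: dict) -> np.ndarray:
    """Target equilibrium state from a profile (before back-solving rates)."""
    x = np.zeros(N_STATES)
    for name in IMMUNE_STATES:
        x[IDX[name]] = profile.immune_fractions[name] * alpha_dim
    # cancer populations in the profiles are quoted at the default alpha_dim;
    # they scale with it so the construction stays homogeneous of degree 1
    x[IDX["C"]] = profile.cancer_large * (alpha_dim / ALPHA_DIM_DEFAULT)
    x[IDX["I_g"]] = knobs["ig_level"] * alpha_dim
    x[IDX["mu1"]] = knobs["mu1_level"] * alpha_dim
    x[IDX["mu2"]] = knobs["mu2_level"] * alpha_dim
    x[IDX["H"]] = knobs["h_level"] * alpha_dim
    # necrotic pool consistent with the chosen clearance rate
    d_tot = profile.growth_rate * (1.0 - knobs["cc_ratio"])
    x[IDX["N"]] = knobs["alpha_NC"] * d_tot * x[IDX["C"]] / knobs["delta_N"]
    return x


def _interaction_rates(profile: ClusterProfile, x: np.ndarray,
                       knobs: dict) -> BaseParameterSet:
    """Interaction/production coefficients implied by the profile knobs at x."""
    g = lambda name: x[IDX[name]]
    M_N, M, T_N, T_h = g("M_N"), g("M"), g("T_N"), g("T_h")
    T_r, T_c, D_N, D = g("T_r"), g("T_c"), g("D_N"), g("D")
    C, N, I_g, mu1, mu2, H = g("C"), g("N"), g("I_g"), g("mu1"), g("mu2"), g("H")
    k = knobs
    lam = profile.growth_rate
    d_tot = lam * (1.0 - k["cc_ratio"])
    L_Th = k["r_Th"] * T_N / T_h
    L_Tc = k["r_Tc"] * T_N / T_c
    L_D = k["r_D"] * D_N / D
    return BaseParameterSet(
        lambda_MIg=k["m_act_split"][0] * k["r_M"] / I_g,
        lambda_Mmu1=k["m_act_split"][1] * k["r_M"] / mu1,
        delta_MN=k["delta_MN"],
        lambda_ThM=k["th_act_split"][0] * k["r_Th"] / M,
        lambda_ThD=k["th_act_split"][1] * k["r_Th"] / D,
        lambda_Trmu1=k["r_Tr"] / mu1,
        lambda_TcTh=k["tc_act_split"][0] * k["r_Tc"] / T_h,
        lambda_TcM=k["tc_act_split"][1] * k["r_Tc"] / M,
        lambda_TcD=k["tc_act_split"][2] * k["r_Tc"] / D,
        delta_TN=k["delta_TN"],
        delta_ThTr=k["th_loss_split"][0] * L_Th / T_r,
        delta_Thmu1=k["th_loss_split"][1] * L_Th / mu1,
        delta_TcTr=k["tc_loss_split"][0] * L_Tc / T_r,
        delta_Tcmu1=k["tc_loss_split"][1] * L_Tc / mu1,
        lambda_DC=k["d_act_split"][0] * k["r_D"] / C,
        lambda_DH=k["d_act_split"][1] * k["r_D"] / H,
        delta_DN=k["delta_DN"],
        delta_DC=k["d_loss_split"][0] * L_D / C,
        lambda_C=k["growth_split"][0] * lam,
        lambda_Cmu1=k["growth_split"][1] * lam / mu1,
        lambda_Cmu2=k["growth_split"][2] * lam / mu2,
        C0=C / k["cc_ratio"],
        delta_CTc=k["cancer_death_split"][0] * d_tot / T_c,
        delta_CIg=k["cancer_death_split"][1] * d_tot / I_g,
        alpha_NC=k["alpha_NC"],
        lambda_IgTh=k["ig_split"][0] * k["delta_Ig"] * I_g / T_h,
        lambda_IgTc=k["ig_split"][1] * k["delta_Ig"] * I_g / T_c,
        lambda_mu1Th=k["mu_split"][0] * k["delta_mu1"] * mu1 / T_h,
        lambda_mu1M=k["mu_split"][1] * k["delta_mu1"] * mu1 / M,
        lambda_mu1C=k["mu_split"][2] * k["delta_mu1"] * mu1 / C,
        lambda_mu2Th=k["mu_split"][0] * k["delta_mu2"] * mu2 / T_h,
        lambda_mu2M=k["mu_split"][1] * k["delta_mu2"] * mu2 / M,
        lambda_mu2C=k["mu_split"][2] * k["delta_mu2"] * mu2 / C,
        lambda_HM=k["h_split"][0] * k["delta_H"] * H / M,
        lambda_HD=k["h_split"][1] * k["delta_H"] * H / D,
        lambda_HN=k["h_split"][2] * k["delta_H"] * H / N,
    )


def build_scenario(cluster_id: int, *, alpha_dim: float = ALPHA_DIM_DEFAULT,
                   knobs: dict | None = None, seed: int | None = None,
                   profile: ClusterProfile | None = None) -> ClusterScenario:
    """Construct one synthetic cluster scenario from its profile."""
    profile = profile or CLUSTER_PROFILES[cluster_id]
    knobs = {**KNOBS, **(knobs or {})}
    x_star = _target_steady_state(profile, alpha_dim, knobs)
    rates = _interaction_rates(profile, x_star, knobs)
    params = backsolve_parameters(x_star, rates)

    def variant(cancer: float) -> np.ndarray:
        x = x_star.copy()
        x[IDX["C"]] = cancer * (alpha_dim / ALPHA_DIM_DEFAULT)
        x[IDX["N"]] = x_star[IDX["N"]] * x[IDX["C"]] / x_star[IDX["C"]]
        return x

    return ClusterScenario(
        cluster_id=profile.cluster_id,
        growth_label=profile.growth_label,
        immune_fractions=dict(profile.immune_fractions),
        pct_cancer=profile.pct_cancer,
        pct_necrotic=profile.pct_necrotic,
        pct_normal=profile.pct_normal,
        params=params,
        chemo=default_chemo_parameters(),
        steady_state=x_star,
        initial_states={
            "small": variant(profile.cancer_small),
            "medium": variant(profile.cancer_medium),
            "large": x_star.copy(),
        },
        alpha_dim=alpha_dim,
        seed=seed,
    )


def make_cluster_suite(seed: int = 0, alpha_dim: float = ALPHA_DIM_DEFAULT
                       ) -> dict[int, ClusterScenario]:
    """The three synthetic clusters: one fast-growing, two slower ones."""
    return {cid: build_scenario(cid, alpha_dim=alpha_dim, seed=seed)
            for cid in CLUSTER_PROFILES}


def generate_fraction_table(n_tumors: int, profile: ClusterProfile,
                            seed: int) -> pd.DataFrame:
    """Per-tumor immune compartment fractions plus tissue-percentage records.

    Fractions are Dirichlet draws around the cluster means (each tumor's
    fractions sum to 1); tissue percentages are truncated-normal draws around
    the cluster means. Fully reproducible for a fixed seed.
    """
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(IMMUNE_STATES)
    means = np.array([profile.immune_fractions[n] for n in names])
    fracs = rng.dirichlet(means * profile.fraction_concentration, size=n_tumors)
    df = pd.DataFrame(fracs, columns=names)
    df.insert(0, "tumor_id", [f"c{profile.cluster_id}_t{i:03d}" for i in range(n_tumors)])
    df["pct_cancer"] = np.clip(rng.normal(profile.pct_cancer, 5.0, n_tumors), 10.0, 98.0)
    df["pct_necrotic"] = np.clip(rng.normal(profile.pct_necrotic, 0.4, n_tumors), 0.1, 20.0)
    df["pct_normal"] = np.clip(rng.normal(profile.pct_normal, 0.15, n_tumors), 0.2, 10.0)
    df["cluster_id"] = profile.cluster_id
    df["seed"] = seed
    return df
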