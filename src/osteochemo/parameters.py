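"""Parameter containers for the tumor-immune-chemotherapy system.

``BaseParameterSet`` holds every rate constant of the untreated 14-equation
network (λ = activation/production, δ = inhibition/decay/death, A_* = naive
source rates, C0 = logistic carrying capacity). ``ChemoParameterSet`` holds the
chemotherapy extension: per-drug exponential-kill efficacies β (L/mg),
chemo-induced death rates K (day⁻¹), the methotrexate cell-cycle pair (f, a),
the cisplatin enhancement δ_CTcA3, the chemo-necrosis fraction α_NCA, and the
drug decay rates δ_A. ``ScalingConstants`` carries the non-dimensionalization
scales.

YAML/JSON config round-trips go through :func:`load_config` /
:func:`save_config`; unknown keys and out-of-range values are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, fields
from functools import cached_property
from pathlib import Path

import numpy as np
import yaml

from .units import DRUGS, dose_bsa_to_concentration  # noqa: F401 (re-exported context)

__all__ = [
    "BaseParameterSet",
    "ChemoParameterSet",
    "ScalingConstants",
    "default_chemo_parameters",
    "load_config",
    "save_config",
]


@dataclass
class BaseParameterSet:
    """Rate constants of the untreated tumor-immune network.

    Units: source rates A_* in cells/day; bilinear λ/δ rates in
    (partner unit · day)⁻¹; linear decay/death rates in day⁻¹; C0 in cells.
    """

    # naive-cell sources
    A_MN: float = 0.0
    A_TN: float = 0.0
    A_DN: float = 0.0
    # activation / production rates (λ)
    lambda_MIg: float = 0.0
    lambda_Mmu1: float = 0.0
    lambda_ThM: float = 0.0
    lambda_ThD: float = 0.0
    lambda_Trmu1: float = 0.0
    lambda_TcTh: float = 0.0
    lambda_TcM: float = 0.0
    lambda_TcD: float = 0.0
    lambda_DC: float = 0.0
    lambda_DH: float = 0.0
    lambda_C: float = 0.0
    lambda_Cmu1: float = 0.0
    lambda_Cmu2: float = 0.0
    lambda_IgTh: float = 0.0
    lambda_IgTc: float = 0.0
    lambda_mu1Th: float = 0.0
    lambda_mu1M: float = 0.0
    lambda_mu1C: float = 0.0
    lambda_mu2Th: float = 0.0
    lambda_mu2M: float = 0.0
    lambda_mu2C: float = 0.0
    lambda_HM: float = 0.0
    lambda_HD: float = 0.0
    lambda_HN: float = 0.0
    # inhibition / death / decay rates (δ)
    delta_MN: float = 0.0
    delta_M: float = 0.0
    delta_TN: float = 0.0
    delta_ThTr: float = 0.0
    delta_Thmu1: float = 0.0
    delta_Th: float = 0.0
    delta_Tr: float = 0.0
    delta_TcTr: float = 0.0
    delta_Tcmu1: float = 0.0
    delta_Tc: float = 0.0
    delta_DN: float = 0.0
    delta_DC: float = 0.0
    delta_D: float = 0.0
    delta_CTc: float = 0.0
    delta_CIg: float = 0.0
    delta_C: float = 0.0
    delta_N: float = 0.0
    delta_Ig: float = 0.0
    delta_mu1: float = 0.0
    delta_mu2: float = 0.0
    delta_H: float = 0.0
    # logistic growth ceiling and drug-free necrotic fraction
    C0: float = 1.0
    alpha_NC: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            setattr(self, f.name, v)
            if not math.isfinite(v):
                raise ValueError(f"BaseParameterSet.{f.name} must be finite")
            if v < 0:
                raise ValueError(f"BaseParameterSet.{f.name} must be >= 0, got {v}")
        if self.C0 <= 0:
            raise ValueError("C0 must be > 0")
        if self.alpha_NC > 1:
            raise ValueError("alpha_NC must lie in [0, 1]")

    def replace(self, **changes) -> "BaseParameterSet":
        return dataclasses.replace(self, **changes)


def _table2_defaults() -> dict:
    from .units import decay_rate_from_half_life, efficacy_per_mass

    mtx, dox, cddp = DRUGS["methotrexate"], DRUGS["doxorubicin"], DRUGS["cisplatin"]
    return {
        "f": 0.5,
        "a": 0.6667,
        "beta1": efficacy_per_mass(mtx.efficacy_per_mol, mtx.molar_mass),
        "beta2": efficacy_per_mass(dox.efficacy_per_mol, dox.molar_mass),
        "beta3": efficacy_per_mass(cddp.efficacy_per_mol, cddp.molar_mass),
        "K_C": 0.9,
        "K_MN": 0.6,
        "K_M": 0.6,
        "K_TN": 0.6,
        "K_Th": 0.6,
        "K_Tr": 0.6,
        "K_Tc": 0.6,
        "K_DN": 0.6,
        "K_D": 0.6,
        "delta_CTcA3": 1.0,
        "alpha_NCA": 0.8,
        "delta_A1": decay_rate_from_half_life(mtx.half_life),
        "delta_A2": decay_rate_from_half_life(dox.half_life),
        "delta_A3": decay_rate_from_half_life(cddp.half_life),
    }


@dataclass
class ChemoParameterSet:
    """Chemotherapy parameters (defaults derived from the drug registry).

    β are efficacies in L/mg, K are chemo-induced death rates in day⁻¹
    (immune K's may not exceed K_C — chemotherapy preferentially kills fast
    proliferating cancer cells), f is the vulnerable-phase fraction, a the
    cell-cycle time in days, δ_A the per-drug decay rates in day⁻¹.
    Resistance scenarios are expressed by overriding β2/β3.
    """

    f: float
    a: float
    beta1: float
    beta2: float
    beta3: float
    K_C: float
    K_MN: float
    K_M: float
    K_TN: float
    K_Th: float
    K_Tr: float
    K_Tc: float
    K_DN: float
    K_D: float
    delta_CTcA3: float
    alpha_NCA: float
    delta_A1: float
    delta_A2: float
    delta_A3: float

    IMMUNE_KILL_FIELDS = ("K_MN", "K_M", "K_TN", "K_Th", "K_Tr", "K_Tc", "K_DN", "K_D")

    def __post_init__(self) -> None:
        for fld in fields(self):
            v = float(getattr(self, fld.name))
            setattr(self, fld.name, v)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"ChemoParameterSet.{fld.name} must be finite and >= 0")
        if not 0 <= self.f <= 1:
            raise ValueError("f must lie in [0, 1]")
        if not 0 <= self.alpha_NCA <= 1:
            raise ValueError("alpha_NCA must lie in [0, 1]")
        if self.a <= 0:
            raise ValueError("cell cycle time a must be > 0")
        for k in self.IMMUNE_KILL_FIELDS:
            if getattr(self, k) > self.K_C:
                raise ValueError(f"{k} may not exceed K_C (immune kill <= tumor kill)")

    @cached_property
    def betas(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta3])

    @cached_property
    def drug_decay(self) -> np.ndarray:
        return np.array([self.delta_A1, self.delta_A2, self.delta_A3])

    @cached_property
    def immune_kill(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.IMMUNE_KILL_FIELDS])

    def replace(self, **changes) -> "ChemoParameterSet":
        return dataclasses.replace(self, **changes)


def default_chemo_parameters(**overrides) -> ChemoParameterSet:
    """Chemotherapy parameter set at its standard values, with optional overrides."""
    vals = _table2_defaults()
    unknown = set(overrides) - set(vals)
    if unknown:
        raise KeyError(f"unknown chemotherapy parameters: {sorted(unknown)}")
    vals.update(overrides)
    return ChemoParameterSet(**vals)


#: Chemotherapy parameters entering local sensitivity analysis. The cell-cycle
#: time ``a`` is excluded: it is a direct measurement, not an estimated rate.
SENSITIVITY_PARAMETERS = (
    "f",
    "beta1",
    "beta2",
    "beta3",
    "K_C",
    "K_MN",
    "K_M",
    "K_TN",
    "K_Th",
    "K_Tr",
    "K_Tc",
    "K_DN",
    "K_D",
    "delta_CTcA3",
    "alpha_NCA",
    "delta_A1",
    "delta_A2",
    "delta_A3",
)


@dataclass
class ScalingConstants:
    """Non-dimensionalization scales.

    ``x_inf`` are the untreated steady-state values X∞ of the 14 cell/cytokine
    states (canonical order); ``v_star`` are the per-drug first-injection-day
    amounts v_A* in mg/L per day; ``alpha_dim`` converts immune fractions to
    cell counts. A drug absent from the regimen gets v_star = δ_A so its scale
    factor is exactly 1.
    """

    x_inf: np.ndarray
    v_star: np.ndarray
    alpha_dim: float = 1.765e8

    def __post_init__(self) -> None:
        self.x_inf = np.asarray(self.x_inf, dtype=float)
        self.v_star = np.asarray(self.v_star, dtype=float)
        if self.x_inf.shape != (14,):
            raise ValueError("x_inf must have 14 entries (cell/cytokine states)")
        if self.v_star.shape != (3,):
            raise ValueError("v_star must have 3 entries (one per drug)")
        if not (np.all(self.x_inf > 0) and np.all(self.v_star > 0) and self.alpha_dim > 0):
            raise ValueError("all scaling constants must be strictly positive")


# ---------------------------------------------------------------------------
# Config file I/O

_SECTION_TYPES = {
    "base": BaseParameterSet,
    "chemo": ChemoParameterSet,
}


def _build_section(cls, payload: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    return cls(**payload)  # dataclass __post_init__ enforces ranges


def load_config(path) -> dict:
    """Read a YAML/JSON parameter file with 'base' and/or 'chemo' sections.

    Returns a dict mapping section name to the validated parameter object.
    Unknown sections, unknown keys, and out-of-range values raise ValueError.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config root of {path} must be a mapping")
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {
        name: _build_section(_SECTION_TYPES[name], payload, name)
        for name, payload in raw.items()
    }


def save_config(path, *, base: BaseParameterSet | None = None,
                chemo: ChemoParameterSet | None = None) -> None:
    """Write parameter objects to a YAML (or .json) config file."""
    doc: dict = {}
    if base is not None:
        doc["base"] = dataclasses.asdict(base)
    if chemo is not None:
        doc["chemo"] = dataclasses.asdict(chemo)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
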