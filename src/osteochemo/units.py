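"""Unit constants, drug definitions, and the conversion formulas used throughout.

Chemotherapy doses are prescribed per body surface area (mg/m²) while the model
tracks drug concentration at the tumor site per liter of body volume (mg/L).
Conversions here assume an average adult male (BSA 1.9 m², volume 59.7 L).
Drug efficacy coefficients from the exponential-kill literature are given per
µmol and converted to per-mg via molar mass; first-order decay rates come from
elimination half-lives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class UnitConstants:
    """Physiological and unit-system constants for dose conversions."""

    body_surface_area: float = 1.9  # m²
    body_volume: float = 59.7  # L
    hours_per_day: float = 24.0
    micromol_per_mol: float = 1e6
    mg_per_g: float = 1e3

    def __post_init__(self) -> None:
        for name in (
            "body_surface_area",
            "body_volume",
            "hours_per_day",
            "micromol_per_mol",
            "mg_per_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"UnitConstants.{name} must be strictly positive")


@dataclass(frozen=True)
class DrugDefinition:
    """Static pharmacological description of one chemotherapy agent.

    ``efficacy_per_mol`` is the exponential-kill coefficient in L/µmol;
    ``half_life`` is the elimination half-life in days. Only methotrexate is
    cell-cycle specific (kills cells in a vulnerable phase only).
    """

    drug_id: str
    molar_mass: float  # g/mol
    half_life: float  # days
    efficacy_per_mol: float  # L/µmol
    cell_cycle_specific: bool = False

    def __post_init__(self) -> None:
        if self.drug_id not in DRUG_IDS:
            raise ValueError(f"unknown drug_id {self.drug_id!r}; expected one of {DRUG_IDS}")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.efficacy_per_mol < 0:
            raise ValueError("efficacy_per_mol must be >= 0")


DRUG_IDS = ("methotrexate", "doxorubicin", "cisplatin")

#: Canonical drug registry. Half-lives: MTX 11.5 h, DOX 2 h, CDDP 25 min.
DRUGS: dict[str, DrugDefinition] = {
    "methotrexate": DrugDefinition(
        "methotrexate",
        molar_mass=454.4,
        half_life=11.5 / 24.0,
        efficacy_per_mol=1.126,
        cell_cycle_specific=True,
    ),
    "doxorubicin": DrugDefinition(
        "doxorubicin",
        molar_mass=580.0,
        half_life=2.0 / 24.0,
        efficacy_per_mol=1.063,
    ),
    "cisplatin": DrugDefinition(
        "cisplatin",
        molar_mass=300.0,
        half_life=25.0 / 1440.0,
        efficacy_per_mol=0.044,
    ),
}

#: Fixed ordering of the three drug concentration states (A1, A2, A3).
DRUG_ORDER = ("methotrexate", "doxorubicin", "cisplatin")


def dose_bsa_to_concentration(dose: float, constants: UnitConstants | None = None) -> float:
    """Convert a body-surface-area dose (mg/m²) to a body-volume concentration (mg/L).

    A dose D mg/m² delivered to a patient of surface area S and volume V yields
    D·S/V mg per liter of body volume, e.g. 75 mg/m² -> 2.3869 mg/L for the
    default adult male.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    c = constants or UnitConstants()
    return dose * c.body_surface_area / c.body_volume


def decay_rate_from_half_life(half_life: float) -> float:
    """First-order decay rate (day⁻¹) from an elimination half-life in days."""
    if half_life <= 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return math.log(2.0) / half_life


def efficacy_per_mass(
    eff_per_mol: float, molar_mass: float, constants: UnitConstants | None = None
) -> float:
    """Convert an efficacy coefficient from L/µmol to L/mg via the molar mass."""
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be > 0, got {molar_mass}")
    if eff_per_mol < 0:
        raise ValueError(f"eff_per_mol must be >= 0, got {eff_per_mol}")
    c = constants or UnitConstants()
    return eff_per_mol * c.micromol_per_mol / (molar_mass * c.mg_per_g)


def cells_from_tumor_volume(volume_ml: float, cell_diameter_um: float) -> float:
    """Estimate the cell count of a tumor of given volume.

    One cell is modeled as a cube with side equal to the cell diameter: a
    275 mL tumor of 35 µm osteoblast-like cells holds about 6.4e9 cells. (A
    spherical cell model would not reproduce that figure; the cube does.)
    """
    if volume_ml <= 0:
        raise ValueError(f"volume_ml must be > 0, got {volume_ml}")
    if cell_diameter_um <= 0:
        raise ValueError(f"cell_diameter_um must be > 0, got {cell_diameter_um}")
    side_cm = cell_diameter_um * 1e-4
    return volume_ml / side_cm**3


def scale_fractions_to_populations(
    immune_fractions,
    pct_cancer: float,
    pct_necrotic: float,
    pct_normal: float,
    alpha_dim: float,
    percent_scale: bool = True,
):
    """Turn deconvolved immune fractions and tissue percentages into populations.

    Each immune compartment population is fraction × alpha_dim; the total
    immune population I is their sum; cancer and necrotic populations follow
    the tissue-percentage ratios C = I·(%cancer/%normal), N = I·(%necrotic/%normal),
    where the normal-cell percentage stands for the total immune share.

    Parameters
    ----------
    immune_fractions : mapping or sequence of nonnegative fractions
    percent_scale : if True the pct_* arguments are on a 0-100 scale, else 0-1.

    Returns
    -------
    (populations, I, C, N) where ``populations`` mirrors the input container type.
    """
    scale = 100.0 if percent_scale else 1.0
    pcts = {"pct_cancer": pct_cancer, "pct_necrotic": pct_necrotic, "pct_normal": pct_normal}
    for name, v in pcts.items():
        if v < 0 or v > scale:
            raise ValueError(f"{name}={v} outside [0, {scale}]")
    if pct_normal == 0:
        raise ZeroDivisionError(
            "pct_normal (the total immune share) is zero: cannot form the "
            "cancer/immune and necrotic/immune ratios"
        )
    if isinstance(immune_fractions, dict):
        vals = list(immune_fractions.values())
        keys = list(immune_fractions.keys())
    else:
        vals = list(immune_fractions)
        keys = None
    if any(f < 0 for f in vals):
        raise ValueError("immune fractions must be >= 0")
    pops = [f * alpha_dim for f in vals]
    total_i = sum(pops)
    cancer = total_i * pct_cancer / pct_normal
    necrotic = total_i * pct_necrotic / pct_normal
    populations = dict(zip(keys, pops)) if keys is not None else pops
    return populations, total_i, cancer, necrotic


#: Cancer cells per unit total-immune fraction used to dimensionalize
#: deconvolved fractions (matches a 6.4e9-cell mean tumor).
ALPHA_DIM_DEFAULT = 1.765e8
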