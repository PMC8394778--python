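"""L1-regularized dose optimization for a fixed regimen template.

Given a treatment schedule whose per-infusion doses of each drug scale with
one decision variable per drug, find bounded doses v minimizing

    L(v, t) = (Ĉ(v, t) − C_target)² + κ·Σ_i |v_i|,    0 ≤ v_i ≤ U_i,

where Ĉ(v, t) is the simulated cancer population at the evaluation time t
(typically the planned surgery day) and the L1 term trades tumor-size error
against total dose burden (toxicity). On the feasible box v ≥ 0 the L1 term
equals Σ v_i and is smooth, so a bound-constrained quasi-Newton method with
seeded multi-starts is used directly; internally the squared error is
computed on the normalized scale (Ĉ/C_target − 1)² — i.e. the raw loss
divided by C_target² — to decondition the ~10⁹-cell magnitudes without
moving the minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .engine import simulate
from .parameters import BaseParameterSet, ChemoParameterSet, ScalingConstants
from .regimens import Regimen

__all__ = ["DEFAULT_DOSE_BOUNDS", "ModelContext", "OptimizationSpec",
           "OptimizationResult", "loss", "optimize"]

#: Maximum tolerable per-infusion-day doses in mg/m².
DEFAULT_DOSE_BOUNDS = {"methotrexate": 20000.0, "doxorubicin": 45.0, "cisplatin": 75.0}


@dataclass
class ModelContext:
    """Everything needed to simulate a candidate dosing: patient + model."""

    initial: np.ndarray
    params: BaseParameterSet
    chemo: ChemoParameterSet
    scaling: ScalingConstants | None = None
    rtol: float = 1e-6
    atol: float = 1e-9

    @classmethod
    def from_scenario(cls, scenario, size: str = "large", **kw) -> "ModelContext":
        from .engine import scaling_from

        initial = scenario.initial_states[size]
        scaling = scaling_from(scenario.steady_state, None, scenario.chemo)
        return cls(initial=np.asarray(initial, dtype=float), params=scenario.params,
                   chemo=scenario.chemo, scaling=scaling, **kw)


@dataclass
class OptimizationSpec:
    """Dose-optimization problem definition.

    One dose variable per drug in ``drugs``; every infusion event of that
    drug in the regimen template receives the candidate per-infusion dose.
    """

    regimen: Regimen
    t_eval: float
    C_target: float
    kappa: float = 0.0
    drugs: tuple = ("methotrexate", "doxorubicin", "cisplatin")
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_DOSE_BOUNDS))
    n_starts: int = 8
    seed: int = 0
    extra_starts: tuple = ()  # optional warm starts (dose vectors)

    def __post_init__(self):
        if self.C_target <= 0:
            raise ValueError("C_target must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.t_eval <= self.regimen.treatment_start:
            raise ValueError("t_eval must lie after treatment start")
        for d in self.drugs:
            if self.bounds.get(d, -1.0) <= 0:
                raise ValueError(f"missing or non-positive bound for {d}")

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[d] for d in self.drugs])


@dataclass
class LossValue:
    total: float            # raw scale, (cells)² units
    squared_error: float
    penalty: float
    total_normalized: float  # raw/C_target² — the scale the optimizer sees
    achieved_C: float

    def __iter__(self):  # allows tuple-unpacking in drivers
        yield from (self.total, self.squared_error, self.penalty)


@dataclass
class OptimizationResult:
    doses: dict
    achieved_C: float
    loss: LossValue
    iterations: int
    n_evaluations: int
    converged: bool
    start_losses: list
    seed: int


def _simulate_C(v: np.ndarray, spec: OptimizationSpec, ctx: ModelContext) -> float:
    doses = {d: float(x) for d, x in zip(spec.drugs, v)}
    regimen = spec.regimen.with_doses(doses)
    horizon = max(spec.t_eval, regimen.end) + 1e-6
    try:
        traj = simulate(ctx.initial, ctx.params, ctx.chemo, regimen,
                        horizon=horizon, scaling=ctx.scaling,
                        rtol=ctx.rtol, atol=ctx.atol, output_dt=2.0)
    except Exception as err:
        raise RuntimeError(f"loss evaluation failed at doses {doses}") from err
    return traj.value("C", spec.t_eval)


def loss(v, spec: OptimizationSpec, ctx: ModelContext) -> LossValue:
    """Evaluate the regularized loss at a dose vector (within bounds)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < -1e-9) or np.any(v > spec.upper * (1 + 1e-9)):
        raise ValueError(f"doses {v} violate the bounds [0, {spec.upper}]")
    v = np.clip(v, 0.0, spec.upper)
    c_hat = _simulate_C(v, spec, ctx)
    sq = (c_hat - spec.C_target) ** 2
    pen = spec.kappa * np.abs(v).sum()
    total = sq + pen
    return LossValue(total=total, squared_error=sq, penalty=pen,
                     total_normalized=total / spec.C_target**2, achieved_C=c_hat)


def optimize(spec: OptimizationSpec, ctx: ModelContext) -> OptimizationResult:
    """Minimize the loss over the dose box with seeded multi-start L-BFGS-B.

    Start points: zero dose, the template's nominal doses, the box midpoint,
    any user-supplied warm starts, and seeded uniform draws up to
    ``spec.n_starts``. Deterministic for a fixed seed. The returned loss is
    recomputed from scratch at the optimum.
    """
    U = spec.upper
    n_eval = 0

    def objective(u):
        nonlocal n_eval
        n_eval += 1
        return loss(np.clip(u, 0.0, 1.0) * U, spec, ctx).total_normalized

    nominal = {}
    for ev in spec.regimen.events:
        nominal.setdefault(ev.drug_id, ev.dose)
    starts = [np.zeros(len(U)),
              np.clip(np.array([nominal.get(d, 0.0) for d in spec.drugs]) / U, 0, 1),
              np.full(len(U), 0.5)]
    starts += [np.clip(np.asarray(w, dtype=float) / U, 0.0, 1.0)
               for w in spec.extra_starts]
    rng = np.random.default_rng(spec.seed)
    while len(starts) < spec.n_starts:
        starts.append(rng.uniform(size=len(U)))
    starts = starts[: max(spec.n_starts, len(spec.extra_starts) + 3)]

    best = None
    records = []
    failures = []
    for u0 in starts:
        try:
            res = minimize(objective, u0, method="L-BFGS-B",
                           bounds=[(0.0, 1.0)] * len(U),
                           options={"maxiter": 60, "ftol": 1e-12, "gtol": 1e-8,
                                    "eps": 1e-4})
        except RuntimeError as err:
            failures.append(err)
            continue
        records.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all optimizer starts failed; first error: {failures[0]}")

    v_star = np.clip(best.x, 0.0, 1.0) * U
    final = loss(v_star, spec, ctx)
    return OptimizationResult(
        doses={d: float(x) for d, x in zip(spec.drugs, v_star)},
        achieved_C=final.achieved_C,
        loss=final,
        iterations=int(best.nit),
        n_evaluations=n_eval,
        converged=bool(best.success),
        start_losses=records,
        seed=spec.seed,
    )
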