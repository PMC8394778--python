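"""Integration of the treated/untreated systems over piecewise-smooth schedules.

Infusion sources v_A(t) are discontinuous at event boundaries and the
methotrexate phase factor has a kink where its exposure clock saturates, so
the integrator is restarted at every such breakpoint instead of asking an
adaptive solver to step across them. All solves are performed on the
non-dimensional system (states divided by their untreated steady-state values
X∞; drugs scaled by v*/δ_A) for numerical stability, with dimensional
quantities at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (IDX, N_BASE, N_STATES, STATE_NAMES, rhs_treated,
                    rhs_treated_tau, rhs_untreated)
from .parameters import BaseParameterSet, ChemoParameterSet, ScalingConstants
from .regimens import Regimen, Schedule
from .units import UnitConstants

__all__ = [
    "Trajectory",
    "simulate",
    "untreated_steady_state",
    "scaling_from",
    "scale_vector",
    "nondimensionalize",
    "redimensionalize",
    "drug_administration_windows",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
#: Relative tolerance below which small integrator-induced negatives are
#: zeroed; anything more negative (relative to the state scale) is an error.
NEGATIVE_CLAMP = 1e-9


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time-stamped dimensional states with solver metadata.

    ``states`` has shape (n_times, 17), one row per time point, in the
    canonical state order.
    """

    times: np.ndarray
    states: np.ndarray
    regimen: Regimen | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, N_STATES):
            raise ValueError("states must be (n_times, 17)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    def at(self, t: float) -> np.ndarray:
        """State linearly interpolated at time t."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"t={t} outside trajectory span")
        return np.array([np.interp(t, self.times, self.states[:, i])
                         for i in range(N_STATES)])

    def value(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self[name]))

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        """Tidy (time, variable, value) DataFrame."""
        import pandas as pd

        n = self.times.size
        return pd.DataFrame({
            "time": np.repeat(self.times, N_STATES),
            "variable": np.tile(np.array(STATE_NAMES), n),
            "value": self.states.ravel(),
        })


# ---------------------------------------------------------------------------
# Non-dimensionalization


def scale_vector(scaling: ScalingConstants, chemo: ChemoParameterSet) -> np.ndarray:
    """Per-state scale s: X̄ = X/s. Base states use X∞; drug j uses v*_j/δ_Aj
    (so Ā = A·δ_A/v*)."""
    s = np.empty(N_STATES)
    s[:N_BASE] = scaling.x_inf
    s[N_BASE:] = scaling.v_star / chemo.drug_decay
    if np.any(s <= 0):
        raise ValueError("scale vector must be strictly positive")
    return s


def nondimensionalize(obj, scaling: ScalingConstants, chemo: ChemoParameterSet):
    """Scale a state vector or Trajectory; exact inverse of :func:`redimensionalize`."""
    s = scale_vector(scaling, chemo)
    if isinstance(obj, Trajectory):
        return Trajectory(obj.times, obj.states / s, obj.regimen,
                          {**obj.meta, "scaled": True})
    return np.asarray(obj, dtype=float) / s


def redimensionalize(obj, scaling: ScalingConstants, chemo: ChemoParameterSet):
    s = scale_vector(scaling, chemo)
    if isinstance(obj, Trajectory):
        return Trajectory(obj.times, obj.states * s, obj.regimen,
                          {**obj.meta, "scaled": False})
    return np.asarray(obj, dtype=float) * s


def scaling_from(steady_state, regimen: Regimen | None, chemo: ChemoParameterSet,
                 constants: UnitConstants | None = None,
                 alpha_dim: float = 1.765e8) -> ScalingConstants:
    """Build ScalingConstants from an untreated steady state and a regimen."""
    x = np.asarray(steady_state, dtype=float)
    v_star = Schedule(regimen, chemo, constants).v_star(constants)
    return ScalingConstants(x_inf=x[:N_BASE], v_star=v_star, alpha_dim=alpha_dim)


# ---------------------------------------------------------------------------
# Simulation


def _segment_grid(t0: float, t1: float, max_step_out: float) -> np.ndarray:
    n = max(2, int(np.ceil((t1 - t0) / max_step_out)) + 1)
    return np.linspace(t0, t1, n)


def simulate(
    initial,
    params: BaseParameterSet,
    chemo: ChemoParameterSet,
    regimen: Regimen | None,
    horizon: float,
    *,
    scaling: ScalingConstants | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t0: float = 0.0,
    output_dt: float = 0.25,
    method: str = "LSODA",
    scaled: bool = True,
    constants: UnitConstants | None = None,
) -> Trajectory:
    """Integrate the treated system from ``initial`` (dimensional) over
    ``[t0, t0+horizon]`` days.

    The time axis is split at every infusion start/end and every methotrexate
    clock-saturation kink, and the solver is restarted on each smooth segment.
    With ``scaled=True`` (default) the integration is carried out on the
    non-dimensional system using ``scaling`` (derived from ``initial`` if not
    given — appropriate when ``initial`` is the untreated steady state);
    ``scaled=False`` integrates the dimensional equations directly.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    x0 = np.asarray(initial, dtype=float)
    if x0.shape != (N_STATES,):
        raise ValueError("initial state must have 17 components")
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")

    schedule = Schedule(regimen, chemo, constants)
    if scaled:
        if scaling is None:
            scaling = scaling_from(x0, regimen, chemo, constants)
        s = scale_vector(scaling, chemo)
    else:
        s = np.ones(N_STATES)

    t_end = t0 + horizon
    bps = schedule.breakpoints
    cuts = np.unique(np.concatenate(([t0], bps[(bps > t0) & (bps < t_end)], [t_end])))

    times = [np.array([t0])]
    states = [(x0 / s)[None, :]]
    y = x0 / s
    n_steps = 0
    for a, b in zip(cuts[:-1], cuts[1:]):
        v_seg, tau_const, tau_origin = schedule.segment_info(a, b)

        if tau_origin is None:
            def rhs(t, yv, _v=v_seg, _tau=tau_const):
                return rhs_treated_tau(np.maximum(yv, 0.0) * s, params, chemo,
                                       _tau, _v) / s
        else:
            def rhs(t, yv, _v=v_seg, _o=tau_origin):
                return rhs_treated_tau(np.maximum(yv, 0.0) * s, params, chemo,
                                       t - _o, _v) / s

        grid = _segment_grid(a, b, output_dt)
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=grid, dense_output=False)
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{a:.6g}, {b:.6g}] days: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError(f"non-finite state on [{a:.6g}, {b:.6g}] days")
        y = sol.y[:, -1]
        n_steps += sol.t.size
        times.append(sol.t[1:])
        states.append(sol.y[:, 1:].T)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    floor = -NEGATIVE_CLAMP * np.maximum(1.0, np.abs(y_all).max(axis=0))
    if np.any(y_all < floor[None, :]):
        bad = STATE_NAMES[int(np.argmax((y_all < floor[None, :]).any(axis=0)))]
        raise SimulationError(f"state {bad} went significantly negative")
    np.clip(y_all, 0.0, None, out=y_all)
    x_all = y_all * s

    return Trajectory(
        t_all, x_all, regimen,
        meta={
            "rtol": rtol, "atol": atol, "method": method, "scaled": scaled,
            "n_segments": cuts.size - 1, "n_output_points": n_steps,
            "event_boundaries": cuts[1:-1].tolist(),
        },
    )


def untreated_steady_state(
    params: BaseParameterSet,
    guess,
    *,
    settle_days: float = 2000.0,
    rtol: float = 1e-10,
    tol: float = 1e-8,
) -> np.ndarray:
    """Untreated steady state X∞ by long-horizon integration plus root polishing.

    Integrates the drug-free system from ``guess`` for ``settle_days``, then
    polishes with a damped Newton-type root solve on the scaled residual.
    Raises if the final residual exceeds ``tol`` relative to the state scale.
    """
    x0 = np.asarray(guess, dtype=float)
    if np.any(x0[:N_BASE] <= 0):
        raise ValueError("guess must be positive in the 14 cell/cytokine states")

    scale = x0.copy()
    scale[N_BASE:] = 1.0

    def rhs(t, y):
        return rhs_untreated(np.maximum(y, 0.0) * scale, params) / scale

    sol = solve_ivp(rhs, (0.0, settle_days), x0 / scale, method="LSODA",
                    rtol=rtol, atol=1e-12)
    if not sol.success:
        raise SimulationError(f"settling integration failed: {sol.message}")
    y = sol.y[:, -1]

    def residual(yb):
        return rhs_untreated(np.maximum(yb, 0.0) * scale, params) / scale

    polished = root(residual, y, method="hybr", tol=1e-12)
    if polished.success and np.all(polished.x * scale >= 0):
        y = polished.x

    x = np.maximum(y * scale, 0.0)
    res = np.linalg.norm(rhs_untreated(x, params) / np.maximum(scale, 1e-300))
    if res > tol:
        raise SimulationError(
            f"steady state did not converge: scaled residual {res:.3e} > {tol:.1e}")
    return x


# ---------------------------------------------------------------------------
# Reporting helpers


def drug_administration_windows(regimen: Regimen, tail: float = 3.0):
    """Contiguous drug-administration blocks of a regimen.

    Returns a list of (block_start, block_end + tail) windows, where a block
    groups events whose windows touch or overlap within one day. The tail
    covers the pharmacokinetic decay after the last infusion of the block.
    """
    evs = sorted((s, e) for _, s, e, _ in regimen.expanded_events())
    blocks: list[list[float]] = []
    for s, e in evs:
        if blocks and s <= blocks[-1][1] + 1.0:
            blocks[-1][1] = max(blocks[-1][1], e)
        else:
            blocks.append([s, e])
    return [(s, e + tail) for s, e in blocks]
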