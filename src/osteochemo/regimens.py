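"""Treatment regimens: infusion events, preset schedules, and the time-dependent
drug inputs v_A(t) and exposure clocks they induce.

Three clinical presets are provided:

* **MAP** — 35-day cycles; 37.5 mg/m² doxorubicin and 60 mg/m² cisplatin per
  day on days 1-2, 12,000 mg/m² methotrexate on days 22 and 29, all as 4-h
  infusions; two neoadjuvant cycles by default.
* **AP** — three 21-day cycles; 25 mg/m² doxorubicin as a daily bolus on days
  1-3 and 100 mg/m² cisplatin as a continuous 24-h infusion on day 1.
* **single-agent methotrexate** — 10 mg/m² over 4 h once per week for four
  weeks. NOTE: the 10 mg/m² figure follows the protocol description this
  preset encodes; single-agent
  high-dose methotrexate is usually reported in g/m² elsewhere in the
  literature, so treat this preset's absolute dose with caution.

A bolus is modeled as a 1-h infusion rather than an impulse so the ODE source
term stays bounded. The exposure clock T of a drug restarts at the beginning
of each of its infusion events and keeps running after the event ends until
the next one starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ExposureState
from .parameters import ChemoParameterSet
from .units import DRUG_ORDER, UnitConstants, dose_bsa_to_concentration

__all__ = [
    "InfusionEvent",
    "Regimen",
    "build_map",
    "build_ap",
    "build_mtx_single",
    "infusion_rate",
    "exposure_clock",
    "load_regimen",
    "save_regimen",
]

FOUR_HOURS = 4.0 / 24.0
BOLUS_DURATION = 1.0 / 24.0
DEFAULT_TREATMENT_START = 7.0  # days post-diagnosis (biopsy turnaround)

#: Treatment-start presets in days post-diagnosis (1 week / 1 month / 3 / 6).
START_TIME_PRESETS = {"1wk": 7.0, "1mo": 30.0, "3mo": 91.0, "6mo": 182.0}


@dataclass(frozen=True)
class InfusionEvent:
    """One IV infusion within a cycle.

    ``start`` is days from the cycle origin (day 1 of the cycle = start 0),
    ``duration`` in days, ``dose`` in mg/m² (converted to mg/L internally when
    rates are formed).
    """

    drug_id: str
    start: float
    duration: float
    dose: float

    def __post_init__(self):
        if self.drug_id not in DRUG_ORDER:
            raise ValueError(f"unknown drug_id {self.drug_id!r}")
        if self.duration <= 0:
            raise ValueError("infusion duration must be > 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class Regimen:
    """An ordered infusion schedule: per-cycle events replicated over cycles."""

    name: str
    cycle_length: float
    n_cycles: int
    events: tuple[InfusionEvent, ...]
    treatment_start: float = DEFAULT_TREATMENT_START

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("a regimen needs at least one cycle")
        if self.treatment_start < 0:
            raise ValueError("treatment_start must be >= 0")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if ev.start + ev.duration > self.cycle_length + 1e-12:
                raise ValueError(
                    f"event {ev} does not fit within the {self.cycle_length}-day cycle"
                )

    # -- expanded (absolute-time) view -------------------------------------
    def expanded_events(self) -> list[tuple[str, float, float, float]]:
        """All events over all cycles as (drug_id, abs_start, abs_end, dose)."""
        out = []
        for c in range(self.n_cycles):
            origin = self.treatment_start + c * self.cycle_length
            for ev in self.events:
                s = origin + ev.start
                out.append((ev.drug_id, s, s + ev.duration, ev.dose))
        out.sort(key=lambda t: t[1])
        return out

    @property
    def end(self) -> float:
        return self.treatment_start + self.n_cycles * self.cycle_length

    def with_doses(self, doses: dict[str, float]) -> "Regimen":
        """Replace every event's per-infusion dose of each listed drug."""
        new = tuple(
            InfusionEvent(ev.drug_id, ev.start, ev.duration, doses.get(ev.drug_id, ev.dose))
            for ev in self.events
        )
        return Regimen(self.name, self.cycle_length, self.n_cycles, new, self.treatment_start)


def build_map(treatment_start: float = DEFAULT_TREATMENT_START, n_cycles: int = 2) -> Regimen:
    """Neoadjuvant MAP regimen (two 35-day cycles by default).

    Doxorubicin 37.5 and cisplatin 60 mg/m² on days 1 and 2, methotrexate
    12,000 mg/m² on days 22 and 29, each as a 4-h infusion per day.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    events = []
    for day in (0.0, 1.0):  # cycle days 1 and 2
        events.append(InfusionEvent("doxorubicin", day, FOUR_HOURS, 37.5))
        events.append(InfusionEvent("cisplatin", day, FOUR_HOURS, 60.0))
    for day in (21.0, 28.0):  # cycle days 22 and 29
        events.append(InfusionEvent("methotrexate", day, FOUR_HOURS, 12000.0))
    return Regimen("MAP", 35.0, n_cycles, tuple(events), treatment_start)


def build_ap(treatment_start: float = DEFAULT_TREATMENT_START, n_cycles: int = 3) -> Regimen:
    """AP regimen: doxorubicin bolus days 1-3 plus a 24-h cisplatin infusion."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    events = [InfusionEvent("doxorubicin", d, BOLUS_DURATION, 25.0) for d in (0.0, 1.0, 2.0)]
    events.append(InfusionEvent("cisplatin", 0.0, 1.0, 100.0))
    return Regimen("AP", 21.0, n_cycles, tuple(events), treatment_start)


def build_mtx_single(treatment_start: float = DEFAULT_TREATMENT_START,
                     n_courses: int = 4) -> Regimen:
    """Weekly single-agent methotrexate, 10 mg/m² over 4 h (see the dose
    caveat in the module docstring)."""
    if n_courses < 1:
        raise ValueError("n_courses must be >= 1")
    events = (InfusionEvent("methotrexate", 0.0, FOUR_HOURS, 10.0),)
    return Regimen("MTX", 7.0, n_courses, events, treatment_start)


def infusion_rate(regimen: Regimen, drug_id: str, t: float,
                  constants: UnitConstants | None = None) -> float:
    """Drug input v_A(t) in mg/L per day at absolute time t (days).

    Sum over active events of converted dose / duration; overlapping events
    superpose; zero outside all events.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rate = 0.0
    for d_id, s, e, dose in regimen.expanded_events():
        if d_id == drug_id and s <= t < e:
            rate += dose_bsa_to_concentration(dose, constants) / (e - s)
    return rate


def exposure_clock(regimen: Regimen, drug_id: str, t: float,
                   chemo: ChemoParameterSet) -> ExposureState:
    """Exposure clock of one drug at time t: T since its latest infusion start."""
    if t < 0:
        raise ValueError("t must be >= 0")
    starts = [s for d_id, s, _, _ in regimen.expanded_events() if d_id == drug_id and s <= t]
    T = (t - max(starts)) if starts else 0.0
    return ExposureState.from_times([T], chemo)


# ---------------------------------------------------------------------------
# Compiled schedule used by the integrator


class Schedule:
    """Regimen compiled to arrays for fast in-RHS evaluation.

    Precomputes per-event absolute windows and converted rates, per-drug
    first-injection-day totals v_A*, and the breakpoints where the RHS is
    non-smooth (event starts/ends and the τ-saturation kinks at
    start + f·a, where the methotrexate phase factor stops changing).
    """

    def __init__(self, regimen: Regimen | None, chemo: ChemoParameterSet,
                 constants: UnitConstants | None = None):
        self.regimen = regimen
        self.chemo = chemo
        events = regimen.expanded_events() if regimen is not None else []
        self._drug_idx = np.array([DRUG_ORDER.index(d) for d, *_ in events], dtype=int)
        self._starts = np.array([s for _, s, _, _ in events])
        self._ends = np.array([e for _, _, e, _ in events])
        self._rates = np.array(
            [dose_bsa_to_concentration(dose, constants) / (e - s)
             for _, s, e, dose in events]
        )
        bps = set()
        fa = chemo.f * chemo.a
        for _, s, e, _ in events:
            bps.update((s, e, s + fa))
        self.breakpoints = np.array(sorted(bps))

    def rates(self, t: float) -> np.ndarray:
        """Per-drug infusion rates (mg/L/day) at time t."""
        v = np.zeros(3)
        if self._starts.size:
            active = (self._starts <= t) & (t < self._ends)
            np.add.at(v, self._drug_idx[active], self._rates[active])
        return v

    def exposure_T(self, t: float) -> np.ndarray:
        """Raw per-drug exposure times T at time t (0 before any infusion)."""
        T = np.zeros(3)
        for j in range(3):
            mask = (self._drug_idx == j) & (self._starts <= t)
            if mask.any():
                T[j] = t - self._starts[mask].max()
        return T

    def exposure(self, t: float) -> ExposureState:
        """Per-drug exposure clocks at time t."""
        return ExposureState.from_times(self.exposure_T(t), self.chemo)

    def segment_info(self, a: float, b: float):
        """Infusion rates and methotrexate-clock form on a smooth segment.

        Between consecutive breakpoints the rates are constant and the capped
        clock τ is either constant or exactly t − (last MTX start). Returns
        ``(v, tau_const, tau_origin)`` where ``tau_origin`` is None for a
        constant clock.
        """
        mid = 0.5 * (a + b)
        v = self.rates(mid)
        fa = self.chemo.f * self.chemo.a
        mask = (self._drug_idx == 0) & (self._starts <= mid)
        if not mask.any():
            return v, 0.0, None
        last = float(self._starts[mask].max())
        if mid - last >= fa:
            return v, fa, None
        return v, 0.0, last

    def v_star(self, constants: UnitConstants | None = None) -> np.ndarray:
        """First-injection-day amount of each drug in mg/L (per day).

        Drugs absent from the regimen get their decay rate δ_A, which makes
        the non-dimensional scale v*/δ_A exactly 1.
        """
        out = np.array([float(d) for d in self.chemo.drug_decay])
        for j in range(3):
            mask = self._drug_idx == j
            if mask.any():
                first = self._starts[mask].min()
                day_mask = mask & (np.floor(self._starts - 1e-12) == np.floor(first - 1e-12))
                out[j] = float(
                    np.sum(self._rates[day_mask] * (self._ends[day_mask] - self._starts[day_mask]))
                )
        return out


# ---------------------------------------------------------------------------
# Serialization


def save_regimen(path, regimen: Regimen) -> None:
    doc = {
        "name": regimen.name,
        "cycle_length": regimen.cycle_length,
        "n_cycles": regimen.n_cycles,
        "treatment_start": regimen.treatment_start,
        "events": [asdict(ev) for ev in regimen.events],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_regimen(path) -> Regimen:
    doc = yaml.safe_load(Path(path).read_text())
    known = {"name", "cycle_length", "n_cycles", "treatment_start", "events"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown regimen keys: {sorted(unknown)}")
    events = tuple(InfusionEvent(**ev) for ev in doc["events"])
    return Regimen(doc["name"], doc["cycle_length"], doc["n_cycles"], events,
                   doc.get("treatment_start", DEFAULT_TREATMENT_START))
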