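"""Invariant-region bookkeeping and the energy diagnostic.

The continuous model keeps each component in a fixed box: endothelial
density ``C`` in ``[0, 1]`` (logistic growth), protease ``P`` in
``[0, P_max]`` with ``P_max = max{xi1, (k4 + k5)/k6}`` (decay dominates
production above that level), inhibitor ``I`` and matrix ``F`` below
their uniform initial values ``xi2`` and ``xi3`` (no positive sources),
and oxygen ``O`` in ``[0, max{O_0 + xi4, O_max}]`` (supply switches off at
the ceiling).  Under the explicit time-step restriction the RK4 scheme
preserves the same box; this module *verifies* that claim on computed
trajectories — it never clips or projects a state.

The energy functional

    E(t) = 1/2 ∫ ( C^2 + P^2 + I^2 + F^2 + O^2/(gamma2*beta) ) dx

is evaluated by trapezoidal quadrature as a dissipativity diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model import FIELD_NAMES, ModelParameters, SystemState

__all__ = [
    "InvariantRegion",
    "Violation",
    "BoundsReport",
    "EnergyTrace",
    "BoundsMonitor",
    "build_region",
    "check_state",
    "energy",
    "attach_monitor",
]

#: Default small positive offsets of the uniform initial data, matching the
#: baseline angiogenesis scenario (P=0.1, I=0.2, F=1, O-offset 0.1, O_0=0.5).
DEFAULT_IC_CONSTANTS = {"xi1": 0.1, "xi2": 0.2, "xi3": 1.0, "xi4": 0.1, "O_0": 0.5}


@dataclass(frozen=True)
class InvariantRegion:
    """Per-component closed intervals forming the invariant box."""

    intervals: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"invalid interval for {name}: [{lo}, {hi}]")

    @property
    def P_max(self) -> float:
        return self.intervals["P"][1]


def build_region(params: ModelParameters, ics=None) -> InvariantRegion:
    """Invariant box for the current parameters and initial-condition levels.

    ``ics`` is any object exposing ``xi1..xi4`` and ``O_0`` (the scenario
    module's ``InitialConditions`` fits); when omitted, the baseline
    scenario constants are used.  Bounds are recomputed on every call —
    never cached across configuration changes.
    """
    if ics is None:
        c = dict(DEFAULT_IC_CONSTANTS)
    else:
        c = {k: float(getattr(ics, k)) for k in ("xi1", "xi2", "xi3", "xi4", "O_0")}
    P_max = max(c["xi1"], (params.k4 + params.k5) / params.k6)
    O_upper = max(c["O_0"] + c["xi4"], params.O_max)
    return InvariantRegion(
        intervals={
            "C": (0.0, 1.0),
            "P": (0.0, P_max),
            "I": (0.0, c["xi2"]),
            "F": (0.0, c["xi3"]),
            "O": (0.0, O_upper),
        }
    )


@dataclass(frozen=True)
class Violation:
    """First recorded excursion of one component outside its interval."""

    time: float
    component: str
    node: int
    value: float
    tolerance: float


def check_state(
    state: SystemState, region: InvariantRegion, tol: float = 1e-10
) -> dict[str, Violation | None]:
    """Check every component against its interval with absolute slack ``tol``.

    Returns a per-component mapping to ``None`` (pass) or the worst
    offender.  Intervals are closed: values exactly at an endpoint pass.
    """
    if tol < 0:
        raise ValueError(f"tolerance must be nonnegative, got {tol}")
    result: dict[str, Violation | None] = {}
    for k, name in enumerate(FIELD_NAMES):
        lo, hi = region.intervals[name]
        u = state.data[k]
        excess = np.maximum(lo - tol - u, u - hi - tol)
        j = int(np.argmax(excess))
        if excess[j] > 0:
            result[name] = Violation(
                time=state.t, component=name, node=j, value=float(u[j]), tolerance=tol
            )
        else:
            result[name] = None
    return result


def energy(state: SystemState, params: ModelParameters, dx: float) -> float:
    """Quadratic energy ``E`` by trapezoidal quadrature (always >= 0)."""
    if params.gamma2 * params.beta <= 0:
        raise ValueError("gamma2 * beta must be positive")
    integrand = (
        state.C**2
        + state.P**2
        + state.I**2
        + state.F**2
        + state.O**2 / (params.gamma2 * params.beta)
    )
    return 0.5 * float(np.trapezoid(integrand, dx=dx))


@dataclass
class BoundsReport:
    """Per-component extrema: sampled series plus running global extrema."""

    times: list[float] = field(default_factory=list)
    minima: dict[str, list[float]] = field(default_factory=lambda: {n: [] for n in FIELD_NAMES})
    maxima: dict[str, list[float]] = field(default_factory=lambda: {n: [] for n in FIELD_NAMES})
    global_min: dict[str, float] = field(default_factory=lambda: {n: np.inf for n in FIELD_NAMES})
    global_max: dict[str, float] = field(default_factory=lambda: {n: -np.inf for n in FIELD_NAMES})
    violations: dict[str, Violation] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.times}
        for n in FIELD_NAMES:
            cols[f"min_{n}"] = self.minima[n]
            cols[f"max_{n}"] = self.maxima[n]
        return pd.DataFrame(cols)


@dataclass
class EnergyTrace:
    """Time series of the energy functional."""

    times: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "E": self.values})


class BoundsMonitor:
    """Simulation hook tracking extrema, violations, and the energy trace.

    Observes every accepted step: running global min/max are updated each
    step; the sampled series and the energy are recorded every
    ``cadence`` steps.  A violation is recorded once per component (first
    occurrence); policy ``"warn"`` continues, ``"abort"`` raises.
    Monitoring never mutates the observed state.
    """

    def __init__(
        self,
        region: InvariantRegion,
        params: ModelParameters,
        dx: float,
        cadence: int = 1,
        tol: float = 1e-10,
        policy: str = "warn",
        track_energy: bool = True,
    ) -> None:
        if cadence < 1:
            raise ValueError(f"monitoring cadence must be >= 1 step, got {cadence}")
        if policy not in ("warn", "abort"):
            raise ValueError(f"unknown violation policy {policy!r}")
        self.region = region
        self.params = params
        self.dx = dx
        self.cadence = cadence
        self.tol = tol
        self.policy = policy
        self.track_energy = track_energy
        self.report = BoundsReport()
        self.trace = EnergyTrace()
        self._bounds = np.array([region.intervals[n] for n in FIELD_NAMES])  # (5, 2)

    def __call__(self, step: int, t: float, U: np.ndarray) -> None:
        mins = U.min(axis=1)
        maxs = U.max(axis=1)
        rep = self.report
        lo, hi = self._bounds[:, 0], self._bounds[:, 1]
        if np.any(mins < lo - self.tol) or np.any(maxs > hi + self.tol):
            self._record_violations(t, U, mins, maxs)
        for k, n in enumerate(FIELD_NAMES):
            if mins[k] < rep.global_min[n]:
                rep.global_min[n] = float(mins[k])
            if maxs[k] > rep.global_max[n]:
                rep.global_max[n] = float(maxs[k])
        if step % self.cadence == 0:
            rep.times.append(t)
            for k, n in enumerate(FIELD_NAMES):
                rep.minima[n].append(float(mins[k]))
                rep.maxima[n].append(float(maxs[k]))
            if self.track_energy:
                self.trace.times.append(t)
                self.trace.values.append(energy(SystemState(U, t=t), self.params, self.dx))

    def _record_violations(self, t, U, mins, maxs) -> None:
        from .model import FIELD_NAMES as names

        for k, n in enumerate(names):
            if n in self.report.violations:
                continue
            lo, hi = self._bounds[k]
            if mins[k] < lo - self.tol or maxs[k] > hi + self.tol:
                below = lo - U[k]
                above = U[k] - hi
                excess = np.maximum(below, above)
                j = int(np.argmax(excess))
                v = Violation(time=t, component=n, node=j, value=float(U[k, j]), tolerance=self.tol)
                self.report.violations[n] = v
                if self.policy == "abort":
                    raise RuntimeError(
                        f"invariant-region violation: {n}={v.value} at node {j}, t={t}"
                    )

    def results(self) -> tuple[BoundsReport, EnergyTrace]:
        return self.report, self.trace


def attach_monitor(
    region: InvariantRegion,
    params: ModelParameters,
    dx: float,
    cadence: int = 1,
    tol: float = 1e-10,
    policy: str = "warn",
) -> BoundsMonitor:
    """Create a :class:`BoundsMonitor` ready to pass in a simulation's hooks."""
    return BoundsMonitor(region, params, dx, cadence=cadence, tol=tol, policy=policy)
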