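"""Explicit RK4 time stepping, stability bounds, and the simulation loop.

The semi-discrete system ``dU/dt = L(U) + N(U)`` is advanced with the
classical four-stage Runge–Kutta scheme, treating diffusion and
advection/reaction together (fully explicit, no splitting).  Because the
scheme is explicit, the time step is limited by

* the diffusion bound ``dt <= dx^2 / (2 d_max)`` (forward-Euler spectral
  bound on the Neumann Laplacian; conservative for RK4, whose real-axis
  stability interval extends to -2.785),
* an advective CFL bound ``dt <= C_CFL * dx``, and
* the invariant-region restriction
  ``dt <= min{dx^2/(2 d_max), 1/L_R, dx/alpha_max}`` where ``L_R`` is a
  Lipschitz constant of the reaction terms over the invariant region,
  estimated here numerically as the largest infinity-norm of a
  finite-difference reaction Jacobian over a coarse sample of the region.

The simulation loop is deterministic: fixed step size, no randomness, and
repeated runs on one platform are bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .model import FIELD_NAMES, ModelParameters, SystemState, TumorFactorProfile, make_rhs
from .monitor import build_region
from .operators import Grid1D, apply_gradient

__all__ = [
    "StabilityLimits",
    "RunResult",
    "rk4_step",
    "estimate_reaction_lipschitz",
    "compute_stability_limits",
    "simulate",
]

logger = logging.getLogger("angiosim")

#: Conservative default CFL constant when no state is available to measure
#: actual advective speeds.
DEFAULT_C_CFL = 1.0

#: Default safety factor applied to the recommended time step.
DEFAULT_SAFETY_FACTOR = 0.9


@dataclass(frozen=True)
class StabilityLimits:
    """Explicit time-step bounds for the current grid and parameters.

    ``dt_diffusion`` is the forward-Euler diffusion bound
    ``dx^2/(2 d_max)``; ``dt_cfl`` the advective bound ``C_CFL * dx``
    (``inf`` when advective speeds vanish); ``dt_region`` the
    invariant-region restriction; ``dt_recommended`` the safety-scaled
    minimum of the three.
    """

    dt_diffusion: float
    dt_cfl: float
    dt_region: float
    dt_recommended: float
    d_max: float
    alpha_max: float
    lipschitz_estimate: float
    c_cfl: float


@dataclass
class RunResult:
    """Trajectory summary produced by :func:`simulate`."""

    snapshots: list[tuple[float, SystemState]]
    step_count: int
    dt_used: float
    termination: str
    monitors: dict = field(default_factory=dict)


def _rk4_array(rhs, U: np.ndarray, t: float, dt: float) -> np.ndarray:
    s1 = rhs(U, t)
    s2 = rhs(U + (0.5 * dt) * s1, t + 0.5 * dt)
    s3 = rhs(U + (0.5 * dt) * s2, t + 0.5 * dt)
    s4 = rhs(U + dt * s3, t + dt)
    return U + (dt / 6.0) * (s1 + 2.0 * s2 + 2.0 * s3 + s4)


def rk4_step(
    rhs: Callable[[SystemState, float], np.ndarray],
    state: SystemState,
    t: float,
    dt: float,
) -> SystemState:
    """One classical RK4 step ``U + dt/6 (s1 + 2 s2 + 2 s3 + s4)``.

    Stage evaluations occur at ``t, t + dt/2, t + dt/2, t + dt`` so that
    non-autonomous forcing (manufactured-solution sources) retains the
    full fourth order; for an autonomous right-hand side this reduces to
    the plain four-stage scheme.  The input state is never mutated.
    Stage vectors are named ``stage_*`` (the model's kinetic rates already
    use the ``k`` names).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    U = state.data
    stages = []
    V = U
    for stage_no, (offset, prev_scale) in enumerate(
        [(0.0, 0.0), (0.5, 0.5), (0.5, 0.5), (1.0, 1.0)], start=1
    ):
        if stage_no > 1:
            V = U + (prev_scale * dt) * stages[-1]
        s = rhs(SystemState(V, t=t + offset * dt), t + offset * dt)
        s = np.asarray(s, dtype=float)
        if not np.all(np.isfinite(s)):
            bad = [n for k, n in enumerate(FIELD_NAMES) if not np.all(np.isfinite(s[k]))]
            raise FloatingPointError(
                f"non-finite RK4 stage {stage_no} at t={t} (components: {', '.join(bad)})"
            )
        stages.append(s)
    new = U + (dt / 6.0) * (stages[0] + 2.0 * stages[1] + 2.0 * stages[2] + stages[3])
    return SystemState(new, t=t + dt)


def _pointwise_reaction(u: np.ndarray, T: float, p: ModelParameters) -> np.ndarray:
    C, P, I, F, O = u
    H = O / (p.K_O + O)
    return np.array(
        [
            p.k1 * C * (1.0 - C) * H,
            -p.k3 * P * I + p.k4 * T * C + p.k5 * T - p.k6 * P,
            -p.k3 * P * I,
            -p.k2 * P * F,
            -p.gamma1 * C * H + p.gamma2 * (p.O_max - O) * p.beta * C,
        ]
    )


def estimate_reaction_lipschitz(
    params: ModelParameters,
    bounds: Sequence[tuple[float, float]] | None = None,
    n_levels: int = 3,
    fd_step: float = 1e-6,
) -> float:
    """Numerical Lipschitz constant of the reactions over the invariant box.

    Samples each component at ``n_levels`` equispaced levels of its
    invariant interval (Cartesian product, both tumor-factor extremes
    ``T = 0`` and ``T = 1``) and returns the largest infinity-norm of the
    forward-difference 5x5 reaction Jacobian over the sample.
    """
    if bounds is None:
        region = build_region(params)
        bounds = [region.intervals[name] for name in FIELD_NAMES]
    levels = [np.linspace(lo, hi, n_levels) for lo, hi in bounds]
    worst = 0.0
    for point in product(*levels):
        u0 = np.array(point)
        for T in (0.0, 1.0):
            f0 = _pointwise_reaction(u0, T, params)
            J = np.empty((5, 5))
            for j in range(5):
                u1 = u0.copy()
                u1[j] += fd_step
                J[:, j] = (_pointwise_reaction(u1, T, params) - f0) / fd_step
            worst = max(worst, float(np.max(np.sum(np.abs(J), axis=1))))
    return worst


def compute_stability_limits(
    params: ModelParameters,
    grid: Grid1D,
    current_state: SystemState | None = None,
    profile: TumorFactorProfile | None = None,
    c_cfl: float = DEFAULT_C_CFL,
    safety_factor: float = DEFAULT_SAFETY_FACTOR,
) -> StabilityLimits:
    """All explicit time-step bounds for this configuration.

    When ``current_state`` (and ``profile``) are given the CFL constant is
    replaced by ``1/a_max`` with the measured maximum advective speed
    ``a_max = max_j |alpha1 (D_x F)_j - alpha2 (D_x I)_j + alpha3 (D_x phi)_j|``;
    otherwise the configured conservative constant ``c_cfl`` is used.
    Vanishing advective speed yields ``dt_cfl = inf``.
    """
    dx = grid.dx
    dt_diffusion = dx**2 / (2.0 * params.d_max)
    if current_state is not None:
        speed = params.alpha1 * apply_gradient(current_state.F, dx)
        speed -= params.alpha2 * apply_gradient(current_state.I, dx)
        if profile is not None:
            speed += params.alpha3 * profile.dphi_dx
        a_max = float(np.max(np.abs(speed)))
        # speeds at round-off level (constant cue fields) count as zero
        scale = max(
            float(np.max(np.abs(current_state.F)))
            + float(np.max(np.abs(current_state.I)))
            + 1.0,
            1.0,
        )
        if a_max <= 1e-13 * scale / dx:
            a_max = 0.0
        dt_cfl = dx / a_max if a_max > 0 else math.inf
    else:
        dt_cfl = c_cfl * dx
    L_R = estimate_reaction_lipschitz(params)
    dt_region = min(dt_diffusion, 1.0 / L_R if L_R > 0 else math.inf, dx / params.alpha_max)
    dt_recommended = safety_factor * min(dt_diffusion, dt_cfl, dt_region)
    logger.debug(
        "stability limits: dt_diffusion=%.3e dt_cfl=%.3e dt_region=%.3e (L_R=%.3g)",
        dt_diffusion, dt_cfl, dt_region, L_R,
    )
    return StabilityLimits(
        dt_diffusion=dt_diffusion,
        dt_cfl=dt_cfl,
        dt_region=dt_region,
        dt_recommended=dt_recommended,
        d_max=params.d_max,
        alpha_max=params.alpha_max,
        lipschitz_estimate=L_R,
        c_cfl=c_cfl,
    )


def simulate(
    initial: SystemState,
    params: ModelParameters,
    profile: TumorFactorProfile,
    grid: Grid1D,
    dt: float,
    T_f: float,
    hooks: Sequence[Callable[[int, float, np.ndarray], None]] = (),
    snapshot_times: Sequence[float] | None = None,
    sources=None,
    allow_unstable_dt: bool = False,
    log_every: int = 0,
) -> RunResult:
    """March the semi-discrete system from ``t = 0`` to ``T_f``.

    Fixed step ``dt`` (a final shorter step closes any remainder); hooks
    are called as ``hook(step_index, t, U)`` after every accepted step
    (and once at step 0 with the initial data).  Snapshots are taken at
    the first accepted time >= each requested snapshot time.

    ``dt`` above the recommended stability bound is rejected unless
    ``allow_unstable_dt`` is set (then a warning is logged).  A non-finite
    state aborts with the failing time and component.
    """
    if T_f < 0:
        raise ValueError(f"final time must be nonnegative, got {T_f}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    limits = compute_stability_limits(params, grid, current_state=initial, profile=profile)
    if dt > limits.dt_recommended:
        if not allow_unstable_dt:
            raise ValueError(
                f"dt={dt:g} exceeds the recommended stability bound "
                f"{limits.dt_recommended:g}; pass allow_unstable_dt=True to override"
            )
        logger.warning(
            "dt=%g exceeds recommended stability bound %g (override active)",
            dt, limits.dt_recommended,
        )
    initial.check_finite("initial state")

    rhs = make_rhs(params, profile, grid, sources=sources)
    U = initial.data.copy()
    t = 0.0
    step = 0

    pending = sorted(float(s) for s in snapshot_times) if snapshot_times is not None else []
    snapshots: list[tuple[float, SystemState]] = []

    def maybe_snapshot() -> None:
        while pending and t >= pending[0] - 1e-12:
            pending.pop(0)
            snapshots.append((t, SystemState(U.copy(), t=t)))

    for hook in hooks:
        hook(0, 0.0, U)
    maybe_snapshot()

    # Fixed-step loop; a final partial step lands exactly on T_f.
    n_full = int(math.floor(T_f / dt + 1e-12))
    remainder = T_f - n_full * dt
    if remainder < 1e-12 * max(1.0, T_f):
        remainder = 0.0

    check_mask = 127  # finiteness check every 128 steps and at the end
    try:
        while step < n_full:
            U = _rk4_array(rhs, U, t, dt)
            step += 1
            t = step * dt
            if (step & check_mask) == 0 and not np.isfinite(np.sum(U)):
                SystemState(U, t=t).check_finite("time stepping")
            for hook in hooks:
                hook(step, t, U)
            maybe_snapshot()
            if log_every and step % log_every == 0:
                logger.info(
                    "step=%d t=%.6g dt=%.3g min=%s max=%s",
                    step, t, dt,
                    np.array2string(U.min(axis=1), precision=3),
                    np.array2string(U.max(axis=1), precision=3),
                )
        if remainder > 0.0:
            U = _rk4_array(rhs, U, t, remainder)
            step += 1
            t = T_f
            for hook in hooks:
                hook(step, t, U)
            maybe_snapshot()
    except FloatingPointError:
        SystemState(U, t=t).check_finite("time stepping")
        raise
    final = SystemState(U, t=t)
    final.check_finite("final state")
    if not snapshots or snapshots[-1][0] < t:
        snapshots.append((t, final.copy()))
    return RunResult(
        snapshots=snapshots,
        step_count=step,
        dt_used=dt,
        termination="completed",
    )
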