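"""Five-field continuum model of tumor-induced angiogenesis with oxygen.

State variables on the tissue strip between a parent vessel (x = 0) and a
tumor (x = L_f), all dimensionless:

* ``C`` — endothelial cell density,
* ``P`` — protease concentration,
* ``I`` — protease-inhibitor concentration,
* ``F`` — extracellular-matrix (ECM) density,
* ``O`` — oxygen concentration.

Endothelial cells diffuse, proliferate logistically at an oxygen-limited
rate (Michaelis–Menten factor ``H(O) = O/(K_O + O)``), and drift up ECM
gradients (haptotaxis, ``alpha1 > 0``), along inhibitor gradients
(``alpha2``, stored negative and used verbatim in the flux, so the
effective inhibitor-gradient coefficient is ``-alpha2 > 0``) and up the
gradient of the regularized tumor angiogenic factor ``phi`` (``alpha3``).
Protease is produced near the tumor (``k4*T*C + k5*T``), decays (``k6``)
and is neutralized by the inhibitor (``k3*P*I``); the ECM is degraded by
protease (``k2*P*F``) and does not move; oxygen diffuses, is consumed by
cells with saturating kinetics and is resupplied by the nascent
vasculature at rate ``gamma2*(O_max - O)*beta*C``.

The tumor angiogenic factor is the fixed spatial profile
``T(x) = exp(-(L_f - x)^2 / eps)`` peaking at the tumor edge, and
``phi(x) = log(1 + alpha4*T(x)) / alpha4`` its logarithmic regularization.

After spatial discretization (method of lines) the semi-discrete system is
``dU/dt = L(U) + N(U)`` where ``L`` stacks the linear diffusion terms
(the ECM row is zero — no spatial operator acts on F) and ``N`` the
advective flux divergence and reactions.  This module assembles that
right-hand side; time stepping lives in :mod:`angiosim.integrate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .operators import Grid1D, apply_gradient, apply_laplacian

__all__ = [
    "FIELD_NAMES",
    "ModelParameters",
    "SystemState",
    "TumorFactorProfile",
    "michaelis_menten",
    "tumor_factor",
    "reaction_terms",
    "advective_flux_divergence",
    "semi_discrete_rhs",
]

#: Order of the state components everywhere in the package.
FIELD_NAMES = ("C", "P", "I", "F", "O")

#: Parameters absent from the published baseline table; defaults are this
#: package's documented choices and are flagged as such in metadata output.
NON_TABLE_DEFAULTS = ("k4", "k5", "beta", "O_max", "eps", "alpha4")


@dataclass(frozen=True)
class ModelParameters:
    """Rate and transport coefficients of the angiogenesis system.

    Defaults are the baseline physiological set: diffusivities
    ``d_C=0.001, d_P=d_I=0.01, d_O=0.1``; taxis sensitivities
    ``alpha1=0.1, alpha2=-0.1, alpha3=0.01``; kinetics ``k1=0.1, k2=0.05,
    k3=0.5, k6=0.2``; oxygen exchange ``gamma1=0.1, gamma2=0.05,
    K_O=0.2``.  ``k4, k5, beta, O_max, eps, alpha4`` have no published
    baseline value; the defaults here are mid-range choices consistent
    with the magnitudes above (see the methods note).

    Sign conventions are enforced at construction: all diffusivities and
    kinetic rates positive, ``alpha1, alpha3 > 0`` and ``alpha2 < 0``.
    """

    d_C: float = 0.001
    d_P: float = 0.01
    d_I: float = 0.01
    d_O: float = 0.1
    alpha1: float = 0.1
    alpha2: float = -0.1
    alpha3: float = 0.01
    alpha4: float = 1.0
    k1: float = 0.1
    k2: float = 0.05
    k3: float = 0.5
    k4: float = 0.1
    k5: float = 0.05
    k6: float = 0.2
    gamma1: float = 0.1
    gamma2: float = 0.05
    K_O: float = 0.2
    O_max: float = 1.0
    beta: float = 1.0
    eps: float = 0.01
    L_f: float = 1.0

    def __post_init__(self) -> None:
        positive = (
            "d_C", "d_P", "d_I", "d_O", "alpha1", "alpha3", "alpha4",
            "k1", "k2", "k3", "k4", "k5", "k6",
            "gamma1", "gamma2", "K_O", "O_max", "beta", "eps", "L_f",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive, got {getattr(self, name)}")
        if self.alpha2 >= 0:
            raise ValueError(f"alpha2 must be negative (sign convention), got {self.alpha2}")

    @property
    def d_max(self) -> float:
        """Largest diffusivity; controls the explicit diffusion time-step bound."""
        return max(self.d_C, self.d_P, self.d_I, self.d_O)

    @property
    def alpha_max(self) -> float:
        """Largest taxis-sensitivity magnitude."""
        return max(abs(self.alpha1), abs(self.alpha2), abs(self.alpha3))

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SystemState:
    """The five grid functions plus the current time.

    Internally stored as one contiguous ``(5, M+1)`` array so the
    integrator can operate on the whole state at once; the per-field
    attributes are views into that array.
    """

    data: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 5:
            raise ValueError(f"state array must have shape (5, M+1), got {self.data.shape}")

    @classmethod
    def from_fields(
        cls,
        C: np.ndarray,
        P: np.ndarray,
        I: np.ndarray,
        F: np.ndarray,
        O: np.ndarray,
        t: float = 0.0,
    ) -> "SystemState":
        return cls(np.stack([C, P, I, F, O]).astype(float), t=t)

    @classmethod
    def zeros(cls, n_nodes: int, t: float = 0.0) -> "SystemState":
        return cls(np.zeros((5, n_nodes)), t=t)

    @property
    def C(self) -> np.ndarray:
        return self.data[0]

    @property
    def P(self) -> np.ndarray:
        return self.data[1]

    @property
    def I(self) -> np.ndarray:
        return self.data[2]

    @property
    def F(self) -> np.ndarray:
        return self.data[3]

    @property
    def O(self) -> np.ndarray:
        return self.data[4]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "SystemState":
        return SystemState(self.data.copy(), t=self.t)

    def check_finite(self, context: str = "state") -> None:
        """Raise with the first offending component if any entry is NaN/Inf."""
        for k, name in enumerate(FIELD_NAMES):
            if not np.all(np.isfinite(self.data[k])):
                j = int(np.argmin(np.isfinite(self.data[k])))
                raise FloatingPointError(
                    f"non-finite value in component {name} at node {j} ({context}, t={self.t})"
                )


@dataclass(frozen=True)
class TumorFactorProfile:
    """Sampled tumor-factor field T, its regularization phi, and D_x phi.

    ``T`` rises monotonically from ~0 at the parent vessel to exactly 1 at
    the tumor edge ``x = L_f``; ``phi <= T`` pointwise.  ``dphi_dx`` is
    precomputed with the package's discrete gradient (not the analytic
    derivative) so the advective flux matches the discrete scheme exactly.
    """

    grid: Grid1D
    T: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    dphi_dx: np.ndarray = field(repr=False)


def michaelis_menten(O_value: np.ndarray | float, K_O: float) -> np.ndarray | float:
    """Saturating oxygen factor ``H(O) = O / (K_O + O)``.

    Zero at ``O = 0``, one half at ``O = K_O``, monotone and bounded
    below 1 for nonnegative oxygen.  Negative inputs are evaluated as-is
    (the invariant monitor, not this function, reports them).
    """
    if K_O <= 0:
        raise ValueError(f"K_O must be positive, got {K_O}")
    return O_value / (K_O + O_value)


def tumor_factor(grid: Grid1D, eps: float, alpha4: float) -> TumorFactorProfile:
    """Build the static tumor-angiogenic-factor profile on a grid."""
    if eps <= 0:
        raise ValueError(f"transition width eps must be positive, got {eps}")
    if alpha4 <= 0:
        raise ValueError(f"regularization strength alpha4 must be positive, got {alpha4}")
    x = grid.nodes
    T = np.exp(-((grid.L_f - x) ** 2) / eps)
    phi = np.log1p(alpha4 * T) / alpha4
    dphi_dx = apply_gradient(phi, grid.dx)
    return TumorFactorProfile(grid=grid, T=T, phi=phi, dphi_dx=dphi_dx)


def _reaction_terms_arrays(
    U: np.ndarray, params: ModelParameters, T: np.ndarray, out: np.ndarray
) -> np.ndarray:
    """Reaction part of N(U) on the raw (5, n) array; hot path."""
    C, P, I, F, O = U
    p = params
    H = O / (p.K_O + O)
    out[0] = p.k1 * C * (1.0 - C) * H
    out[1] = -p.k3 * P * I + p.k4 * T * C + p.k5 * T - p.k6 * P
    out[2] = -p.k3 * P * I
    out[3] = -p.k2 * P * F
    out[4] = -p.gamma1 * C * H + p.gamma2 * (p.O_max - O) * p.beta * C
    return out


def reaction_terms(
    state: SystemState, params: ModelParameters, profile: TumorFactorProfile
) -> np.ndarray:
    """Pointwise reaction terms for all five fields, shape ``(5, M+1)``.

    Rows: logistic oxygen-limited proliferation of C; protease balance
    ``-k3*P*I + k4*T*C + k5*T - k6*P``; inhibitor loss ``-k3*P*I``; ECM
    degradation ``-k2*P*F``; oxygen consumption/supply
    ``-gamma1*C*O/(K_O+O) + gamma2*(O_max-O)*beta*C``.
    """
    if state.n_nodes != profile.T.shape[0]:
        raise ValueError("state and tumor-factor profile live on different grids")
    state.check_finite("reaction_terms input")
    out = np.empty_like(state.data)
    return _reaction_terms_arrays(state.data, params, profile.T, out)


def _advective_flux_divergence_arrays(
    C: np.ndarray,
    I: np.ndarray,
    F: np.ndarray,
    dphi_dx: np.ndarray,
    params: ModelParameters,
    dx: float,
) -> np.ndarray:
    """``D_x( C * (alpha1*D_x F - alpha2*D_x I + alpha3*dphi_dx) )``."""
    flux = params.alpha1 * apply_gradient(F, dx)
    flux -= params.alpha2 * apply_gradient(I, dx)
    flux += params.alpha3 * dphi_dx
    flux *= C
    return apply_gradient(flux, dx)


def advective_flux_divergence(
    state: SystemState, profile: TumorFactorProfile, grid: Grid1D, params: ModelParameters
) -> np.ndarray:
    """Divergence of the taxis flux of endothelial cells.

    Returns ``D_x(C ⊙ (alpha1·D_x F − alpha2·D_x I + alpha3·D_x phi))``;
    this quantity enters the C-equation with a leading minus sign.
    ``alpha2`` is used verbatim (stored negative), so the inhibitor term
    contributes ``+|alpha2|·D_x I`` to the flux.
    """
    if state.n_nodes != grid.n_nodes or profile.T.shape[0] != grid.n_nodes:
        raise ValueError("state, profile and grid sizes disagree")
    return _advective_flux_divergence_arrays(
        state.C, state.I, state.F, profile.dphi_dx, params, grid.dx
    )


def make_rhs(
    params: ModelParameters,
    profile: TumorFactorProfile,
    grid: Grid1D,
    sources=None,
):
    """Build the semi-discrete right-hand side as a fast array callable.

    Returns ``rhs(U, t) -> dU/dt`` on raw ``(5, M+1)`` arrays implementing
    ``L(U) + N(U)``:

    * ``L(U) = (d_C·D_xx C, d_P·D_xx P, d_I·D_xx I, 0, d_O·D_xx O)``,
    * ``N(U)`` = minus the advective flux divergence plus reactions.

    ``sources``, when given, is a sequence of five callables
    ``S_k(x, t) -> array`` (used by manufactured-solution forcing); the
    physical model is autonomous and ignores ``t``.
    """
    dx = grid.dx
    T = profile.T
    dphi_dx = profile.dphi_dx
    x = grid.nodes

    def rhs(U: np.ndarray, t: float) -> np.ndarray:
        out = np.empty_like(U)
        _reaction_terms_arrays(U, params, T, out)
        out[0] -= _advective_flux_divergence_arrays(U[0], U[2], U[3], dphi_dx, params, dx)
        out[0] += params.d_C * apply_laplacian(U[0], dx)
        out[1] += params.d_P * apply_laplacian(U[1], dx)
        out[2] += params.d_I * apply_laplacian(U[2], dx)
        out[4] += params.d_O * apply_laplacian(U[4], dx)
        if sources is not None:
            for k in range(5):
                out[k] += sources[k](x, t)
        return out

    return rhs


def semi_discrete_rhs(
    state: SystemState,
    t: float,
    params: ModelParameters,
    profile: TumorFactorProfile,
    grid: Grid1D,
    sources=None,
) -> np.ndarray:
    """Full method-of-lines right-hand side ``L(U) + N(U)`` (+ sources).

    Convenience wrapper over :func:`make_rhs` for a single evaluation;
    returns a ``(5, M+1)`` array.  Raises :class:`FloatingPointError`
    naming the first non-finite component of the input.
    """
    state.check_finite("semi_discrete_rhs input")
    return make_rhs(params, profile, grid, sources=sources)(state.data, t)
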