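"""The self-guiding machinery.

Self-guided dynamics extracts the low-frequency part of the recent trajectory
with an exponential local average of time constant ``t_L`` (a first-order
low-pass filter) and feeds two guiding terms back into the equation of motion:

* a momentum guiding force ``lambda * xi * p_lf`` built from the local-average
  momentum, which promotes diffusion-controlled search, and
* a force guiding force ``mu * (F_lf - F_lf2)`` built from the local-average
  force deviation, which effectively lowers energy barriers when ``mu < 0``.

``xi`` is the apparent friction constant that converts local-average momentum
into force units; it is estimated on the fly from long-time averages (time
constant ``t_avg``) of ``(F_lf - F_lf2).p_lf`` and ``p_lf.p_lf``.

The two guiding factors are linked by a balance relation: with ``u = 1 + mu``
the balanced pair satisfies the cubic ``u**3 - lambda*u - 1 = 0``
(equivalently ``lambda = (1+mu)**2 - 1/(1+mu)``).  At the balanced pair the
biases of the two guiding terms on the conformational distribution cancel and
the simulation samples the canonical ensemble.

All quantities here live in internal units (amu, A, ps); see ``constants``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import ConfigurationError, DomainError, InvalidInputError

__all__ = [
    "Mode",
    "GuidingParams",
    "LocalAverageState",
    "FrictionAccumulators",
    "local_average_update",
    "update_position_and_energy_averages",
    "derive_low_frequency_state",
    "update_friction_estimate",
    "guiding_force",
    "conservation_scaling_eta",
    "balanced_momentum_factor",
    "balanced_force_factor",
    "equivalent_force_factor",
    "gle_nu",
]

#: PP below this (internal units) leaves xi at zero (cold-start guard).
PP_GUARD = 1e-12
#: |denominator| below this (internal units) leaves eta at zero.
ETA_GUARD = 1e-12


class Mode(str, Enum):
    MD = "MD"
    LD = "LD"
    SGMD = "SGMD"
    SGLD = "SGLD"
    SGLD_GLE = "SGLD_GLE"


@dataclass(frozen=True)
class GuidingParams:
    """Self-guiding knobs.

    t_L : local average time (ps); motions faster than 1/t_L are filtered out
        of the guiding signals.  0.2 ps is the conventional choice.
    t_avg : long averaging time for the apparent-friction estimate (ps);
        defaults to 10*t_L.
    lambda_ : momentum guiding factor (dimensionless).
    mu : force guiding factor (dimensionless).
    gamma : Langevin collision frequency (1/ps); exactly 0 for MD/SGMD.
    """

    t_L: float = 0.2
    t_avg: float | None = None
    lambda_: float = 0.0
    mu: float = 0.0
    gamma: float = 0.0
    mode: Mode = Mode.MD

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        t_avg = self.t_avg if self.t_avg is not None else 10.0 * self.t_L
        object.__setattr__(self, "t_avg", float(t_avg))
        if self.t_L <= 0:
            raise ConfigurationError("t_L must be > 0")
        if self.t_avg < self.t_L:
            raise ConfigurationError("t_avg must be >= t_L")
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")
        if self.mode in (Mode.MD, Mode.SGMD):
            if self.gamma != 0:
                raise ConfigurationError(f"{self.mode.value} requires gamma = 0")
        elif self.gamma <= 0:
            raise ConfigurationError(f"{self.mode.value} requires gamma > 0")
        if self.mode is Mode.SGLD_GLE:
            if self.lambda_ > 1:
                raise DomainError("SGLD_GLE requires lambda <= 1")
            if self.mu != 0:
                raise ConfigurationError("SGLD_GLE requires mu = 0")


@dataclass
class LocalAverageState:
    """Running local averages: positions (once and twice filtered), previous
    filtered momentum, and potential energy (once and twice filtered)."""

    r_avg: np.ndarray        # A, (n, 3)
    r_avg2: np.ndarray       # A, (n, 3)
    p_avg_prev: np.ndarray   # amu*A/ps, (n, 3)
    E_avg: float             # kcal/mol
    E_avg2: float            # kcal/mol

    @classmethod
    def cold_start(cls, positions: np.ndarray, E_p: float) -> "LocalAverageState":
        """Averages seeded with the current configuration so guiding forces
        vanish smoothly at t = 0."""
        r = np.array(positions, dtype=float)
        return cls(r.copy(), r.copy(), np.zeros_like(r), float(E_p), float(E_p))

    def copy(self) -> "LocalAverageState":
        return LocalAverageState(
            self.r_avg.copy(), self.r_avg2.copy(), self.p_avg_prev.copy(),
            self.E_avg, self.E_avg2,
        )


@dataclass
class FrictionAccumulators:
    """Long-time averages FP = <(F_lf - F_lf2).p_lf> and PP = <p_lf.p_lf>
    (per atom) and the apparent friction xi = -FP/PP (1/ps)."""

    FP: np.ndarray
    PP: np.ndarray
    xi: np.ndarray

    @classmethod
    def cold_start(cls, n_atoms: int) -> "FrictionAccumulators":
        z = np.zeros(n_atoms)
        return cls(z.copy(), z.copy(), z.copy())

    def copy(self) -> "FrictionAccumulators":
        return FrictionAccumulators(self.FP.copy(), self.PP.copy(), self.xi.copy())


def local_average_update(prev_avg, current_value, dt: float, t_L: float):
    """One step of the exponential local average:
    ``(1 - dt/t_L)*prev + (dt/t_L)*current``.

    Equivalent to the discrete convolution with weights
    ``(dt/t_L)*(1 - dt/t_L)**k`` over past samples.
    """
    if not 0 < dt <= t_L:
        raise ConfigurationError(f"need 0 < dt <= t_L, got dt={dt}, t_L={t_L}")
    w = dt / t_L
    return (1.0 - w) * prev_avg + w * current_value


def update_position_and_energy_averages(
    state: LocalAverageState,
    positions: np.ndarray,
    E_p: float,
    dt: float,
    t_L: float,
) -> LocalAverageState:
    """Advance r_avg, r_avg2, E_avg, E_avg2 one step.  The doubly filtered
    quantities average the *just-updated* singly filtered ones."""
    r = np.asarray(positions, dtype=float)
    if r.shape != state.r_avg.shape:
        raise InvalidInputError(
            f"positions shape {r.shape} != averages shape {state.r_avg.shape}"
        )
    E_avg = local_average_update(state.E_avg, float(E_p), dt, t_L)
    E_avg2 = local_average_update(state.E_avg2, E_avg, dt, t_L)
    r_avg = local_average_update(state.r_avg, r, dt, t_L)
    r_avg2 = local_average_update(state.r_avg2, r_avg, dt, t_L)
    return LocalAverageState(r_avg, r_avg2, state.p_avg_prev, E_avg, E_avg2)


def derive_low_frequency_state(
    positions: np.ndarray,
    r_avg: np.ndarray,
    r_avg2: np.ndarray,
    p_avg_prev: np.ndarray,
    masses: np.ndarray,
    dt: float,
    t_L: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Low-frequency momentum, full-step momentum, and filtered forces from
    the (already updated) local-average positions.

    p_lf  = (m/t_L) (r - r_avg)
    p     = p_avg_prev + (t_L/dt) (p_lf - p_avg_prev)
    F_lf  = p/t_L - (m/t_L^2)(r - r_avg)  ==  (p - p_lf)/t_L
    F_lf2 = (m/t_L^2)(r - 2 r_avg + r_avg2)
    """
    if dt == 0:
        raise InvalidInputError("dt must be nonzero")
    r = np.asarray(positions, dtype=float)
    m = np.asarray(masses, dtype=float)[:, None]
    p_lf = (m / t_L) * (r - r_avg)
    p_full = p_avg_prev + (t_L / dt) * (p_lf - p_avg_prev)
    F_lf = (p_full - p_lf) / t_L
    F_lf2 = (m / t_L**2) * (r - 2.0 * r_avg + r_avg2)
    return p_lf, p_full, F_lf, F_lf2


def update_friction_estimate(
    acc: FrictionAccumulators,
    F_lf: np.ndarray,
    F_lf2: np.ndarray,
    p_lf: np.ndarray,
    dt: float,
    t_avg: float,
) -> FrictionAccumulators:
    """Advance FP and PP with the t_avg filter and refresh xi = -FP/PP.

    xi stays 0 while PP is below the cold-start guard so that early frames,
    where the filters are not yet representative, produce no momentum guiding.
    """
    fp_inst = np.einsum("ij,ij->i", F_lf - F_lf2, p_lf)
    pp_inst = np.einsum("ij,ij->i", p_lf, p_lf)
    FP = local_average_update(acc.FP, fp_inst, dt, t_avg)
    PP = local_average_update(acc.PP, pp_inst, dt, t_avg)
    xi = np.where(PP > PP_GUARD, -FP / np.where(PP > PP_GUARD, PP, 1.0), 0.0)
    return FrictionAccumulators(FP, PP, xi)


def guiding_force(
    lambda_: float,
    mu: float,
    xi: np.ndarray,
    p_lf: np.ndarray,
    F_lf: np.ndarray,
    F_lf2: np.ndarray,
) -> np.ndarray:
    """g = mu*(F_lf - F_lf2) + lambda*xi*p_lf (internal force units)."""
    return mu * (F_lf - F_lf2) + lambda_ * np.asarray(xi)[:, None] * p_lf


def conservation_scaling_eta(
    g: np.ndarray,
    v_half_prev: np.ndarray,
    f: np.ndarray,
    gamma: float,
    masses: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Per-atom energy-conservation scaling factor (1/ps).

    p0 is the free-move momentum at t,
    ``p0 = m v(t-dt/2) + (f + g - gamma m v(t-dt/2)) dt/2``, and
    ``eta = (2 + gamma dt)(g.p0) / (2 p0.p0 - (g.p0) dt)``.
    eta is exactly 0 when g.p0 = 0 and when the denominator degenerates
    (p0 ~ 0), in which case a warning is emitted.
    """
    m = np.asarray(masses, dtype=float)[:, None]
    mv = m * v_half_prev
    p0 = mv + (f + g - gamma * mv) * (dt / 2.0)
    gp0 = np.einsum("ij,ij->i", g, p0)
    p0sq = np.einsum("ij,ij->i", p0, p0)
    denom = 2.0 * p0sq - gp0 * dt
    ok = np.abs(denom) > ETA_GUARD
    degenerate = (~ok) & (np.einsum("ij,ij->i", g, g) > 0)
    if np.any(degenerate):
        warnings.warn(
            "eta denominator degenerate (p0 ~ 0) for "
            f"{int(degenerate.sum())} atoms; eta set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    eta = np.zeros_like(gp0)
    np.divide((2.0 + gamma * dt) * gp0, denom, out=eta, where=ok & (gp0 != 0))
    return eta


def _real_cbrt(x: float) -> float:
    return float(np.copysign(np.abs(x) ** (1.0 / 3.0), x))


#: Largest lambda with a real balanced factor: radicand 1/4 - lambda^3/27 >= 0.
LAMBDA_MAX = (27.0 / 4.0) ** (1.0 / 3.0)


def balanced_force_factor(lambda_: float) -> float:
    """Force guiding factor mu_lambda whose bias cancels that of ``lambda_``.

    Computed as the real Cardano root of ``u^3 - lambda*u - 1 = 0`` with
    ``u = 1 + mu`` (the closed form of inverting the balance relation),
    handling negative cube-root arguments explicitly.  mu_lambda(0) = 0 and
    the function is continuous on the real-root regime lambda <= (27/4)^(1/3).
    """
    lam = float(lambda_)
    radicand = 0.25 - lam**3 / 27.0
    if radicand < 0:
        raise DomainError(
            f"lambda={lam} outside the real-root regime (lambda <= {LAMBDA_MAX:.6f})"
        )
    s = np.sqrt(radicand)
    u = _real_cbrt(0.5 + s) + _real_cbrt(0.5 - s)
    # polish: the radicand cancels catastrophically for |lambda| << 1
    for _ in range(3):
        u -= (u**3 - lam * u - 1.0) / (3.0 * u * u - lam)
    return u - 1.0


def balanced_momentum_factor(mu: float) -> float:
    """Momentum guiding factor lambda_mu that balances ``mu``:
    ``lambda = (1+mu)^2 - 1/(1+mu)``.  Inverse of
    :func:`balanced_force_factor`."""
    if mu <= -1:
        raise DomainError("balanced momentum factor requires 1 + mu > 0")
    u = 1.0 + float(mu)
    return u * u - 1.0 / u


def equivalent_force_factor(lambda_: float) -> float:
    """The force guiding factor producing an enhancement equivalent to
    ``lambda_`` (the conventional printed lambda-to-mu correspondence,
    e.g. lambda = 1 <-> mu = -0.3247).  Equal to ``-mu_lambda``: the
    balancing factor with its sign flipped from canceling to reinforcing."""
    return -balanced_force_factor(lambda_)


def gle_nu(lambda_: float) -> float:
    """Colored-noise parameter nu of the GLE variant: the
    ``nu = 1 - sqrt(1 - lambda)`` branch of ``lambda = nu (2 - nu)``."""
    lam = float(lambda_)
    if lam > 1:
        raise DomainError("gle_nu requires lambda <= 1")
    return 1.0 - np.sqrt(1.0 - lam)
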