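"""Leapfrog steppers: MD/LD baselines, self-guided SGMD/SGLD, and the
colored-noise SGLD-GLE variant.

One eight-step procedure is shared by every mode:

1. energy and forces at ``r(t)`` (plus the Langevin random force when noisy);
2. local averages of energy and position, and the derived low-frequency
   momentum and filtered forces;
3. apparent-friction accumulators;
4. guiding force ``g = mu (F_lf - F_lf2) + lambda xi p_lf`` (SGMD/SGLD) or
   ``g = lambda gamma p_lf`` (SGLD-GLE);
5. per-atom energy-conservation scaling ``eta`` (SGMD/SGLD only — SGLD-GLE
   preserves the canonical ensemble by construction and applies none);
6. velocity half-step update with combined damping ``gamma + eta``;
7. position update;
8. repeat.

With ``lambda = mu = 0`` the guiding force and eta vanish identically, so
SGLD reduces bitwise to LD and SGMD to MD under a shared noise stream.

Two backends exist: this module's readable numpy stepper (the reference) and
the numba kernel in ``_kernels`` (the fast path); they implement identical
arithmetic.  Kinetic energy is reported with the standard leapfrog estimator,
the mean of squared velocities at the two adjacent half-steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .constants import KB, KCAL_TO_INTERNAL
from .errors import ConfigurationError, InvalidInputError
from .guiding import (
    FrictionAccumulators,
    GuidingParams,
    LocalAverageState,
    Mode,
    balanced_force_factor,
    conservation_scaling_eta,
    derive_low_frequency_state,
    gle_nu,
    guiding_force,
    local_average_update,
    update_friction_estimate,
    update_position_and_energy_averages,
)
from .systems import (
    HarmonicParams,
    LJParams,
    SDWParams,
    SystemSpec,
    maxwell_boltzmann_velocities,
)

__all__ = [
    "IntegratorConfig",
    "DynamicsState",
    "NoiseStream",
    "RunResult",
    "Simulation",
    "langevin_random_force",
    "sg_leapfrog_step",
    "sgld_gle_step",
    "run_simulation",
]

_MODE_CODE = {
    Mode.MD: _kernels.MODE_MD,
    Mode.LD: _kernels.MODE_LD,
    Mode.SGMD: _kernels.MODE_SGMD,
    Mode.SGLD: _kernels.MODE_SGLD,
    Mode.SGLD_GLE: _kernels.MODE_GLE,
}

FRAME_COLUMNS = [
    "t", "E_p", "E_avg", "E_avg2", "KE", "T_lf",
    "lam_lf", "lam_hf", "chi_lf", "chi_hf",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration settings.  dt and t_L in ps; temperature in K."""

    dt: float = 0.001
    n_steps: int = 1000
    temperature: float = 300.0
    guiding: GuidingParams = field(default_factory=GuidingParams)
    seed: int = 0
    record_every: int = 10
    traj_every: int = 0
    eta_enabled: bool = True  # disable only to demonstrate guiding-work drift

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.dt > self.guiding.t_L:
            raise ConfigurationError("dt must not exceed t_L")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be >= 0")


@dataclass
class NoiseStream:
    """Colored-noise state for SGLD-GLE: the local average of past white
    random forces and the kernel parameter nu."""

    R_avg: np.ndarray
    nu: float


@dataclass
class DynamicsState:
    """Everything the stepper reads and writes."""

    t: float
    positions: np.ndarray     # A, (n, 3)
    v_half: np.ndarray        # A/ps at t - dt/2, (n, 3)
    local: LocalAverageState
    friction: FrictionAccumulators
    noise: NoiseStream
    E_p: float = 0.0

    @classmethod
    def initialize(
        cls, system: SystemSpec, positions: np.ndarray, velocities: np.ndarray,
        nu: float = 0.0,
    ) -> "DynamicsState":
        r = np.array(positions, dtype=float).reshape(system.n_atoms, 3)
        v = np.array(velocities, dtype=float).reshape(system.n_atoms, 3)
        E_p, _ = system.energy_forces(r)
        return cls(
            t=0.0,
            positions=r,
            v_half=v,
            local=LocalAverageState.cold_start(r, E_p),
            friction=FrictionAccumulators.cold_start(system.n_atoms),
            noise=NoiseStream(np.zeros_like(r), nu),
            E_p=E_p,
        )


def langevin_random_force(
    gamma: float,
    masses: np.ndarray,
    temperature: float,
    dt: float,
    rng: np.random.Generator | np.random.RandomState,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Langevin random force (internal units), i.i.d. Gaussian per component
    with variance 2*gamma*m*kB*T/dt.  ``z`` overrides the standard-normal
    draws (used to share one stream across backends)."""
    masses = np.asarray(masses, dtype=float)
    if gamma == 0:
        return np.zeros((masses.size, 3))
    if z is None:
        z = rng.standard_normal((masses.size, 3))
    sig = np.sqrt(2.0 * gamma * masses * KB * temperature * KCAL_TO_INTERNAL / dt)
    return sig[:, None] * z


def _step(
    state: DynamicsState,
    system: SystemSpec,
    cfg: IntegratorConfig,
    rng,
    z: np.ndarray | None,
) -> tuple[DynamicsState, dict]:
    """Shared eight-step leapfrog body (all modes)."""
    gp = cfg.guiding
    mode = gp.mode
    dt, t_L = cfg.dt, gp.t_L
    m = system.masses
    r = state.positions

    # (1) forces; random force for noisy modes
    E_p, f_kcal = system.energy_forces(r)
    if not np.isfinite(E_p):
        raise InvalidInputError(
            f"non-finite potential energy at t={state.t:.6f} ps; "
            f"positions:\n{r}"
        )
    f_tot = f_kcal * KCAL_TO_INTERNAL
    noise_eff = None
    noisy = mode in (Mode.LD, Mode.SGLD, Mode.SGLD_GLE) and gp.gamma > 0
    if noisy:
        R = langevin_random_force(gp.gamma, m, cfg.temperature, dt, rng, z)
        if mode is Mode.SGLD_GLE:
            # colored noise R - nu*R_avg; R_avg averages strictly past draws
            # (updating it before use would leave an O(dt/t_L) cold bias)
            noise_eff = R - state.noise.nu * state.noise.R_avg
            f_tot = f_tot + noise_eff
            state.noise.R_avg = local_average_update(state.noise.R_avg, R, dt, t_L)
        else:
            f_tot = f_tot + R

    # (2) local averages and derived low-frequency state
    local = update_position_and_energy_averages(state.local, r, E_p, dt, t_L)
    p_lf, p_full, F_lf, F_lf2 = derive_low_frequency_state(
        r, local.r_avg, local.r_avg2, local.p_avg_prev, m, dt, t_L
    )
    local.p_avg_prev = p_lf

    # (3) apparent friction
    friction = update_friction_estimate(
        state.friction, F_lf, F_lf2, p_lf, dt, gp.t_avg
    )

    # (4) guiding force
    if mode in (Mode.SGMD, Mode.SGLD):
        g = guiding_force(gp.lambda_, gp.mu, friction.xi, p_lf, F_lf, F_lf2)
    elif mode is Mode.SGLD_GLE:
        g = gp.lambda_ * gp.gamma * p_lf
    else:
        g = np.zeros_like(r)

    # (5) conservation scaling (SGMD/SGLD only)
    if cfg.eta_enabled and mode in (Mode.SGMD, Mode.SGLD):
        eta = conservation_scaling_eta(g, state.v_half, f_tot, gp.gamma, m, dt)
    else:
        eta = np.zeros(system.n_atoms)

    # (6)-(7) velocity and position updates
    aa = ((gp.gamma + eta) * dt / 2.0)[:, None]
    v_new = ((1.0 - aa) / (1.0 + aa)) * state.v_half \
        + (f_tot + g) * dt / (m[:, None] * (1.0 + aa))
    ke_int = float(np.sum(0.25 * m[:, None] * (state.v_half**2 + v_new**2)))
    r_new = r + v_new * dt

    state.positions = r_new
    state.v_half = v_new
    state.local = local
    state.friction = friction
    state.E_p = E_p
    state.t += dt

    diag = {
        "E_p": E_p,
        "E_avg": local.E_avg,
        "E_avg2": local.E_avg2,
        "KE": ke_int / KCAL_TO_INTERNAL,
        "T_lf": float(np.sum(np.einsum("ij,ij->i", p_lf, p_lf) / m))
        / (system.ndf * KB * KCAL_TO_INTERNAL),
        "g": g,
        "eta": eta,
        "noise_eff": noise_eff,
    }
    return state, diag


def sg_leapfrog_step(
    state: DynamicsState,
    system: SystemSpec,
    cfg: IntegratorConfig,
    rng=None,
    z: np.ndarray | None = None,
) -> tuple[DynamicsState, dict]:
    """One MD/LD/SGMD/SGLD leapfrog step (reference numpy path)."""
    if cfg.guiding.mode not in (Mode.MD, Mode.LD, Mode.SGMD, Mode.SGLD):
        raise ConfigurationError(f"sg_leapfrog_step does not handle {cfg.guiding.mode}")
    return _step(state, system, cfg, rng, z)


def sgld_gle_step(
    state: DynamicsState,
    system: SystemSpec,
    cfg: IntegratorConfig,
    rng=None,
    z: np.ndarray | None = None,
) -> tuple[DynamicsState, dict]:
    """One SGLD-GLE step: guiding ``lambda*gamma*p_lf``, noise
    ``R - nu*R_avg``, no eta."""
    if cfg.guiding.mode is not Mode.SGLD_GLE:
        raise ConfigurationError("sgld_gle_step requires mode SGLD_GLE")
    return _step(state, system, cfg, rng, z)


@dataclass
class RunResult:
    """Frames table plus optional trajectory arrays from one run segment."""

    frames: pd.DataFrame
    positions: np.ndarray | None = None   # (n_frames, n_atoms, 3), unwrapped
    velocities: np.ndarray | None = None
    traj_dt: float = 0.0


class Simulation:
    """A continuable simulation: holds full dynamics state and advances it in
    segments (replica exchange relies on this).

    Per-segment RNG seeds are spawned deterministically from the master seed,
    so a run is reproducible regardless of how it is segmented... provided the
    same backend is used throughout.
    """

    def __init__(
        self,
        system: SystemSpec,
        cfg: IntegratorConfig,
        positions: np.ndarray,
        velocities: np.ndarray | None = None,
        backend: str = "numba",
        xi_init: np.ndarray | None = None,
    ) -> None:
        """``xi_init`` pre-seeds the per-atom apparent friction constants
        (1/ps), e.g. values saved from a previous run of the same system and
        guiding parameters (plain one-column text via ``numpy.loadtxt``);
        the on-the-fly estimate then evolves from there."""
        if backend not in ("numba", "python"):
            raise ConfigurationError(f"unknown backend {backend!r}")
        self.system = system
        self.cfg = cfg
        self.backend = backend
        self._seedseq = np.random.SeedSequence(cfg.seed)
        if velocities is None:
            rng = np.random.default_rng(self._next_seed())
            velocities = maxwell_boltzmann_velocities(
                system.masses, cfg.temperature, rng
            )
        nu = gle_nu(cfg.guiding.lambda_) if cfg.guiding.mode is Mode.SGLD_GLE else 0.0
        self.state = DynamicsState.initialize(system, positions, velocities, nu=nu)
        if xi_init is not None:
            xi = np.asarray(xi_init, dtype=float).reshape(system.n_atoms)
            self.state.friction.PP = np.full(system.n_atoms, 1.0)
            self.state.friction.FP = -xi.copy()
            self.state.friction.xi = xi.copy()
        # kernel-side factor/average arrays
        n = system.n_atoms
        self._f_avg = np.zeros((n, 3))
        self._g_avg = np.zeros((n, 3))
        self._acc8 = np.zeros(8)
        self._pot_id, self._pot_params, self._box = _potential_code(system)

    def _next_seed(self) -> int:
        return int(self._seedseq.spawn(1)[0].generate_state(1)[0] >> 1)

    def set_guiding(self, guiding: GuidingParams, temperature: float | None = None):
        """Swap guiding parameters (and optionally temperature) mid-run, as a
        replica does when it changes stage."""
        cfg = replace(self.cfg, guiding=guiding)
        if temperature is not None:
            cfg = replace(cfg, temperature=temperature)
        self.cfg = cfg
        if guiding.mode is Mode.SGLD_GLE:
            self.state.noise.nu = gle_nu(guiding.lambda_)

    def advance(
        self,
        n_steps: int,
        record_every: int | None = None,
        traj_every: int | None = None,
        noise: np.ndarray | None = None,
    ) -> RunResult:
        record_every = record_every or self.cfg.record_every
        traj_every = self.cfg.traj_every if traj_every is None else traj_every
        if self.backend == "numba":
            return self._advance_numba(n_steps, record_every, traj_every, noise)
        return self._advance_python(n_steps, record_every, traj_every, noise)

    def _advance_numba(self, n_steps, record_every, traj_every, noise):
        st = self.state
        gp = self.cfg.guiding
        scalars = np.array([st.t, st.local.E_avg, st.local.E_avg2, st.E_p])
        noise_arr = noise if noise is not None else np.zeros((0, 0, 0))
        seed = -1 if noise is not None else self._next_seed()
        rec, traj_r, traj_v, status = _kernels.run_kernel(
            self._pot_id, self._pot_params, self._box, self.system.masses,
            _MODE_CODE[gp.mode], self.cfg.dt, gp.t_L, gp.t_avg,
            gp.lambda_, gp.mu, gp.gamma, st.noise.nu, self.cfg.temperature,
            n_steps, record_every, traj_every, seed, noise_arr,
            self.cfg.eta_enabled,
            st.positions, st.v_half,
            st.local.r_avg, st.local.r_avg2, st.local.p_avg_prev,
            self._f_avg, self._g_avg,
            st.friction.FP, st.friction.PP, st.noise.R_avg,
            self._acc8, scalars,
        )
        st.t, st.local.E_avg, st.local.E_avg2, st.E_p = scalars
        st.friction.xi = np.where(
            st.friction.PP > 1e-12, -st.friction.FP / np.maximum(st.friction.PP, 1e-12), 0.0
        )
        if status != 0:
            raise InvalidInputError(
                f"non-finite energy during kernel run at t~{st.t:.4f} ps; "
                f"state dumped on Simulation.state"
            )
        frames = pd.DataFrame(rec, columns=FRAME_COLUMNS)
        return RunResult(frames, traj_r if traj_every else None,
                         traj_v if traj_every else None,
                         self.cfg.dt * (traj_every or 0))

    def _advance_python(self, n_steps, record_every, traj_every, noise):
        rng = None
        if noise is None:
            rng = np.random.RandomState(self._next_seed())
        rows, traj_r, traj_v = [], [], []
        stepper = (
            sgld_gle_step if self.cfg.guiding.mode is Mode.SGLD_GLE else sg_leapfrog_step
        )
        for k in range(n_steps):
            z = noise[k] if noise is not None else None
            self.state, diag = stepper(self.state, self.system, self.cfg, rng, z)
            if (k + 1) % record_every == 0:
                rows.append(
                    [self.state.t, diag["E_p"], diag["E_avg"], diag["E_avg2"],
                     diag["KE"], diag["T_lf"], np.nan, np.nan, np.nan, np.nan]
                )
            if traj_every and (k + 1) % traj_every == 0:
                traj_r.append(self.state.positions.copy())
                traj_v.append(self.state.v_half.copy())
        frames = pd.DataFrame(rows, columns=FRAME_COLUMNS)
        return RunResult(
            frames,
            np.array(traj_r) if traj_every else None,
            np.array(traj_v) if traj_every else None,
            self.cfg.dt * (traj_every or 0),
        )


def _potential_code(system: SystemSpec) -> tuple[int, np.ndarray, float]:
    pot = system.potential
    if isinstance(pot, HarmonicParams):
        return _kernels.POT_HARMONIC, np.array([pot.k_spring]), 0.0
    if isinstance(pot, SDWParams):
        return _kernels.POT_SDW, np.array([pot.a, pot.b, pot.c, pot.y0]), 0.0
    if isinstance(pot, LJParams):
        return _kernels.POT_LJ, np.array([pot.epsilon, pot.sigma, pot.cutoff]), \
            float(system.box)
    raise ConfigurationError(f"unknown potential {pot!r}")


def _initial_frame(sim: Simulation, system: SystemSpec) -> list:
    st = sim.state
    ke = float(np.sum(0.5 * system.masses[:, None] * st.v_half**2)) / KCAL_TO_INTERNAL
    return [st.t, st.E_p, st.local.E_avg, st.local.E_avg2, ke, 0.0,
            np.nan, np.nan, np.nan, np.nan]


def run_simulation(
    system: SystemSpec,
    cfg: IntegratorConfig,
    positions: np.ndarray,
    velocities: np.ndarray | None = None,
    backend: str = "numba",
) -> tuple[RunResult, Simulation]:
    """Run ``cfg.n_steps`` steps and return (result, simulation).

    The frames table always starts with an initial-state row at the starting
    time (so ``n_steps = 0`` yields exactly that one frame) and carries the
    reweighting factor ``w`` of every frame.  Fully deterministic under
    ``cfg.seed``.
    """
    sim = Simulation(system, cfg, positions, velocities, backend=backend)
    first = _initial_frame(sim, system)
    res = sim.advance(cfg.n_steps)
    frames = pd.concat(
        [pd.DataFrame([first], columns=FRAME_COLUMNS), res.frames],
        ignore_index=True,
    )
    frames["T_kin"] = 2.0 * frames["KE"] / (system.ndf * KB)
    gp = cfg.guiding
    if gp.mode in (Mode.SGMD, Mode.SGLD):
        from .reweighting import conformation_weight

        frames["w"] = conformation_weight(
            frames["E_avg"].to_numpy(), frames["E_avg2"].to_numpy(),
            gp.lambda_, gp.mu, 1.0 / (KB * cfg.temperature),
        )
    else:
        frames["w"] = 1.0
    return RunResult(frames, res.positions, res.velocities, res.traj_dt), sim
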