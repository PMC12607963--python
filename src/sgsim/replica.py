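"""Replica exchange over self-guiding stages (RXSGLD) and temperature
ladders (TRXLD).

A *stage* is a simulation condition (temperature, lambda, mu); replicas run
dynamics segments under their current stage and periodically attempt to swap
stages with a Metropolis criterion.  Two acceptance criteria are provided:

* ``generalized`` (default): built from the self-guided ensemble weight —
  needs only per-frame E_p and the filtered energies, and supports mixed
  temperature/guiding ladders;
* ``legacy``: built from the frequency-separated energy and collision factors
  (lambda_lf, lambda_hf, chi_lf, chi_hf) measured during the runs; its
  energy-splitting approximation is exact only for equal-temperature ladders,
  so a warning is emitted otherwise.

Replicas swap stage labels only, keeping their momenta (ladders at a single
temperature, the recommended usage, need no velocity rescaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB
from .errors import ConfigurationError, InvalidInputError
from .guiding import GuidingParams, Mode, balanced_force_factor
from .integrators import IntegratorConfig, Simulation
from .systems import SystemSpec

__all__ = [
    "StageSpec",
    "FrequencyFactors",
    "ReplicaState",
    "RXResult",
    "frequency_factors",
    "exchange_coefficients",
    "exchange_probability_legacy",
    "exchange_probability_generalized",
    "attempt_exchange",
    "run_rxsgld",
]


@dataclass(frozen=True)
class StageSpec:
    """One rung of the ladder: temperature and guiding factors."""

    index: int
    T: float
    lambda_: float = 0.0
    mu: float = 0.0

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.T)

    @property
    def mu_hat(self) -> float:
        """Balanced force factor of this stage's lambda."""
        return balanced_force_factor(self.lambda_)


@dataclass(frozen=True)
class FrequencyFactors:
    """Frequency-separated diagnostic factors of one stage.  With zero
    guiding all collision factors are 1."""

    lambda_lf: float = 1.0
    lambda_hf: float = 1.0
    chi_lf: float = 1.0
    chi_hf: float = 1.0


def frequency_factors(
    f: np.ndarray,
    f_avg: np.ndarray,
    g: np.ndarray,
    g_avg: np.ndarray,
    p: np.ndarray,
    p_lf: np.ndarray,
    gamma: float | np.ndarray,
) -> FrequencyFactors:
    """Instantaneous frequency-separated factors from per-atom arrays.

    lambda_lf projects the total low-frequency force on the low-frequency
    interaction force; lambda_hf is the high-frequency analogue; chi_lf and
    chi_hf project the guiding forces on the friction forces.  Degenerate
    denominators (cold start, zero friction) leave the factor at 1 with a
    warning.  In production the kernel filters numerators and denominators
    over t_avg before taking these ratios.
    """
    gam = np.broadcast_to(np.asarray(gamma, dtype=float), (f.shape[0],))[:, None]

    def _ratio(num: float, den: float, name: str) -> float:
        if abs(den) < 1e-12:
            warnings.warn(
                f"{name} denominator ~ 0; factor defaults to 1", RuntimeWarning,
                stacklevel=3,
            )
            return 1.0
        return num / den

    lam_lf = _ratio(
        float(np.sum((f_avg + g_avg - gam * p_lf) * f_avg)),
        float(np.sum(f_avg * f_avg)),
        "lambda_lf",
    )
    fh, gh, ph = f - f_avg, g - g_avg, p - p_lf
    lam_hf = _ratio(
        float(np.sum((fh + gh - gam * ph) * fh)),
        float(np.sum(fh * fh)),
        "lambda_hf",
    )
    chi_lf = 1.0 - _ratio(
        float(np.sum(g_avg * gam * p_lf)),
        float(np.sum(gam**2 * p_lf * p_lf)),
        "chi_lf",
    ) if np.any(gam != 0) else 1.0
    chi_hf = 1.0 - _ratio(
        float(np.sum(gam * gh * ph)),
        float(np.sum(gam**2 * ph * ph)),
        "chi_hf",
    ) if np.any(gam != 0) else 1.0
    if not np.any(gam != 0):
        # no friction: collision factors are defined as 1
        return FrequencyFactors(lam_lf, lam_hf, 1.0, 1.0)
    return FrequencyFactors(lam_lf, lam_hf, chi_lf, chi_hf)


def exchange_coefficients(
    stage: StageSpec, factors: FrequencyFactors
) -> tuple[float, float]:
    """Low- and high-frequency exchange coefficients (mol/kcal):
    l = (lam_lf chi_lf - lam_hf chi_hf)/(kB T), h = lam_hf chi_hf/(kB T)."""
    if stage.T <= 0:
        raise InvalidInputError("stage temperature must be > 0")
    lc = factors.lambda_lf * factors.chi_lf
    hc = factors.lambda_hf * factors.chi_hf
    kT = KB * stage.T
    return (lc - hc) / kT, hc / kT


def legacy_log_ratio(
    E_p_i: float, E_avg_i: float, E_p_j: float, E_avg_j: float,
    l_m: float, h_m: float, l_n: float, h_n: float,
) -> float:
    """Log of the raw legacy exchange ratio for replica i at stage m and
    replica j at stage n (before the Metropolis min)."""
    return -(l_m - l_n) * (E_avg_j - E_avg_i) - (h_m - h_n) * (E_p_j - E_p_i)


def exchange_probability_legacy(
    E_p_i: float, E_avg_i: float, E_p_j: float, E_avg_j: float,
    l_m: float, h_m: float, l_n: float, h_n: float,
) -> float:
    """Metropolis probability from the frequency-factor (legacy) criterion."""
    return min(
        1.0, float(np.exp(legacy_log_ratio(
            E_p_i, E_avg_i, E_p_j, E_avg_j, l_m, h_m, l_n, h_n)))
    )


def generalized_log_ratio(
    E_p_i: float, dE_i: float, E_p_j: float, dE_j: float,
    stage_m: StageSpec, stage_n: StageSpec,
) -> float:
    """Log of the raw generalized exchange ratio; ``dE`` is the filtered
    energy deviation E_avg - E_avg2 of the replica.

    Derived from the sampled self-guided density
    rho ~ exp(-beta [E_p + (mu - mu_hat) dE]) for replica i at stage m and
    replica j at stage n swapping stages.
    """
    bm, bn = stage_m.beta, stage_n.beta
    cm = bm * (stage_m.mu - stage_m.mu_hat)
    cn = bn * (stage_n.mu - stage_n.mu_hat)
    return (bm - bn) * (E_p_i - E_p_j) - (cm - cn) * (dE_i - dE_j)


def exchange_probability_generalized(
    E_p_i: float, dE_i: float, E_p_j: float, dE_j: float,
    stage_m: StageSpec, stage_n: StageSpec,
) -> float:
    """Metropolis probability from the self-guided-ensemble criterion."""
    return min(
        1.0,
        float(np.exp(generalized_log_ratio(E_p_i, dE_i, E_p_j, dE_j,
                                           stage_m, stage_n))),
    )


@dataclass
class ReplicaState:
    """A replica: its simulation, current stage, and stage history."""

    replica_id: int
    current_stage: int
    sim: Simulation
    stage_history: list = field(default_factory=list)

    def snapshot(self) -> tuple[float, float, float]:
        st = self.sim.state
        return st.E_p, st.local.E_avg, st.local.E_avg2


def _stage_guiding(stage: StageSpec, template: GuidingParams) -> GuidingParams:
    return GuidingParams(
        t_L=template.t_L, t_avg=template.t_avg,
        lambda_=stage.lambda_, mu=stage.mu,
        gamma=template.gamma, mode=template.mode,
    )


def attempt_exchange(
    rep_a: ReplicaState,
    rep_b: ReplicaState,
    stages: list[StageSpec],
    template: GuidingParams,
    rng: np.random.Generator,
    counters: dict,
    mode: str = "generalized",
    factors: dict[int, FrequencyFactors] | None = None,
) -> bool:
    """Metropolis-attempt a stage swap between two replicas.

    On acceptance the replicas exchange stage labels and adopt the new
    stage's guiding parameters for their subsequent dynamics.  Counters are
    updated either way.  Same-stage pairs are rejected with a warning.
    """
    sa, sb = rep_a.current_stage, rep_b.current_stage
    if sa == sb:
        warnings.warn("exchange attempted between replicas on the same stage",
                      RuntimeWarning, stacklevel=2)
        return False
    key = (min(sa, sb), max(sa, sb))
    counters.setdefault(key, [0, 0])
    counters[key][0] += 1
    E_a, Eav_a, Eav2_a = rep_a.snapshot()
    E_b, Eav_b, Eav2_b = rep_b.snapshot()
    if mode == "generalized":
        pi = exchange_probability_generalized(
            E_a, Eav_a - Eav2_a, E_b, Eav_b - Eav2_b,
            stages[sa], stages[sb],
        )
    elif mode == "legacy":
        fa = (factors or {}).get(sa, FrequencyFactors())
        fb = (factors or {}).get(sb, FrequencyFactors())
        l_m, h_m = exchange_coefficients(stages[sa], fa)
        l_n, h_n = exchange_coefficients(stages[sb], fb)
        pi = exchange_probability_legacy(
            E_a, Eav_a, E_b, Eav_b, l_m, h_m, l_n, h_n
        )
    else:
        raise ConfigurationError(f"unknown exchange mode {mode!r}")
    accepted = bool(rng.random() < pi)
    if accepted:
        rep_a.current_stage, rep_b.current_stage = sb, sa
        rep_a.sim.set_guiding(_stage_guiding(stages[sb], template),
                              temperature=stages[sb].T)
        rep_b.sim.set_guiding(_stage_guiding(stages[sa], template),
                              temperature=stages[sa].T)
        counters[key][1] += 1
    return accepted


@dataclass
class RXResult:
    """Outputs of a replica-exchange run."""

    acceptance: pd.DataFrame          # stage_a, stage_b, attempts, accepted, ratio
    stage_traces: pd.DataFrame        # replica, t, stage
    frames_by_stage: dict[int, pd.DataFrame]
    replicas: list[ReplicaState]


def run_rxsgld(
    system: SystemSpec,
    stages: list[StageSpec],
    cfg: IntegratorConfig,
    positions: np.ndarray,
    velocities: np.ndarray | None = None,
    exchange_interval: int = 1000,
    n_cycles: int = 100,
    replicas_per_stage: int = 1,
    mode: str = "generalized",
    pairing: str = "deterministic",
    backend: str = "numba",
) -> RXResult:
    """Interleave dynamics segments with exchange attempts.

    ``pairing='deterministic'`` alternates even/odd adjacent stage pairs on a
    fixed schedule; ``'random'`` picks one random adjacent pair per cycle.
    Returns per-stage-pair acceptance statistics, per-replica stage traces,
    and per-stage frame records.
    """
    if len(stages) < 2:
        raise ConfigurationError("need at least 2 stages")
    if exchange_interval < 1:
        raise ConfigurationError("exchange_interval must be >= 1")
    base = stages[0]
    if base.lambda_ != 0 or base.mu != 0:
        warnings.warn("stage 0 is conventionally the unguided base stage",
                      RuntimeWarning, stacklevel=2)
    temps = {s.T for s in stages}
    if len(temps) > 1 and mode == "legacy":
        warnings.warn(
            "legacy exchange criterion is approximate for unequal-temperature "
            "ladders", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xE5]))
    template = cfg.guiding

    replicas: list[ReplicaState] = []
    rid = 0
    from dataclasses import replace as _replace

    for _ in range(replicas_per_stage):
        for stage in stages:
            rcfg = _replace(
                cfg,
                seed=int(np.random.SeedSequence([cfg.seed, rid]).generate_state(1)[0] >> 1),
                temperature=stage.T,
                guiding=_stage_guiding(stage, template),
            )
            sim = Simulation(system, rcfg, positions, velocities, backend=backend)
            rep = ReplicaState(rid, stage.index, sim)
            rep.stage_history.append((sim.state.t, stage.index))
            replicas.append(rep)
            rid += 1

    counters: dict = {}
    frames_by_stage: dict[int, list] = {s.index: [] for s in stages}
    factors: dict[int, FrequencyFactors] = {}

    for cycle in range(n_cycles):
        for rep in replicas:
            res = rep.sim.advance(exchange_interval)
            frames = res.frames.assign(
                stage=rep.current_stage, replica=rep.replica_id
            )
            frames_by_stage[rep.current_stage].append(frames)
            if mode == "legacy" and len(res.frames):
                last = res.frames.iloc[-1]
                if np.isfinite(last["lam_lf"]):
                    factors[rep.current_stage] = FrequencyFactors(
                        last["lam_lf"], last["lam_hf"],
                        last["chi_lf"], last["chi_hf"],
                    )
        # pick exchange partners
        by_stage: dict[int, list[ReplicaState]] = {}
        for rep in replicas:
            by_stage.setdefault(rep.current_stage, []).append(rep)
        if pairing == "deterministic":
            if len(stages) == 2:
                pairs = [(0, 1)]
            else:
                start = cycle % 2
                pairs = [
                    (s, s + 1)
                    for s in range(start, len(stages) - 1, 2)
                ]
        elif pairing == "random":
            s = int(rng.integers(0, len(stages) - 1))
            pairs = [(s, s + 1)]
        else:
            raise ConfigurationError(f"unknown pairing {pairing!r}")
        for sa, sb in pairs:
            if by_stage.get(sa) and by_stage.get(sb):
                ra = by_stage[sa][int(rng.integers(0, len(by_stage[sa])))]
                rb = by_stage[sb][int(rng.integers(0, len(by_stage[sb])))]
                attempt_exchange(ra, rb, stages, template, rng, counters,
                                 mode=mode, factors=factors)
        for rep in replicas:
            rep.stage_history.append((rep.sim.state.t, rep.current_stage))

    acc_rows = [
        {"stage_a": a, "stage_b": b, "attempts": c[0], "accepted": c[1],
         "ratio": c[1] / c[0] if c[0] else np.nan}
        for (a, b), c in sorted(counters.items())
    ]
    trace_rows = [
        {"replica": rep.replica_id, "t": t, "stage": s}
        for rep in replicas
        for t, s in rep.stage_history
    ]
    frames = {
        s: (pd.concat(fr, ignore_index=True) if fr else pd.DataFrame())
        for s, fr in frames_by_stage.items()
    }
    return RXResult(
        pd.DataFrame(acc_rows), pd.DataFrame(trace_rows), frames, replicas
    )
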