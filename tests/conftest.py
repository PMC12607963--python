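"""Shared fixtures: cached simulation runs on the toy systems.

Heavy trajectories are produced once per session and shared across tests;
everything is seeded and deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import replace

import numpy as np
import pytest

from sgsim.guiding import GuidingParams, Mode, gle_nu
from sgsim.integrators import IntegratorConfig, Simulation
from sgsim.systems import build_argon_system, build_sdw_system


@pytest.fixture(scope="session")
def sdw_runner():
    """Run the one-particle skewed-double-well system; results cached."""
    system, r0 = build_sdw_system()
    cache: dict = {}

    def run(mode=Mode.SGLD, lambda_=0.0, mu=0.0, n_steps=1_000_000, seed=100,
            temperature=300.0, record_every=20, traj_every=0, gamma=10.0):
        key = (mode, lambda_, mu, n_steps, seed, temperature, record_every,
               traj_every, gamma)
        if key not in cache:
            from sgsim.integrators import run_simulation

            cfg = IntegratorConfig(
                dt=0.001, n_steps=n_steps, temperature=temperature, seed=seed,
                record_every=record_every, traj_every=traj_every,
                guiding=GuidingParams(mode=mode, gamma=gamma,
                                      lambda_=lambda_, mu=mu),
            )
            cache[key] = run_simulation(system, cfg, r0)
        return cache[key]

    run.system = system
    run.r0 = r0
    return run


@pytest.fixture(scope="session")
def argon_runner():
    """Equilibrated argon production runs, cached; LD-equilibrates each
    (n_atoms, T, seed) state once and reuses it."""
    eq_cache: dict = {}
    run_cache: dict = {}

    def equilibrated(n_atoms, temperature, seed, n_equil):
        key = (n_atoms, temperature, seed, n_equil)
        if key not in eq_cache:
            spec, r0, v0 = build_argon_system(
                n_atoms, temperature=temperature, seed=seed
            )
            cfg = IntegratorConfig(
                dt=0.001, n_steps=0, temperature=temperature, seed=seed,
                record_every=100,
                guiding=GuidingParams(mode=Mode.LD, gamma=10.0),
            )
            sim = Simulation(spec, cfg, r0, v0)
            sim.advance(n_equil)
            eq_cache[key] = (spec, sim)
        spec, sim = eq_cache[key]
        return spec, copy.deepcopy(sim)

    def run(mode=Mode.LD, lambda_=0.0, mu=0.0, n_atoms=64, temperature=100.0,
            n_equil=20_000, n_prod=50_000, seed=7, record_every=100,
            traj_every=0, eta_enabled=True, gamma=10.0):
        key = (mode, lambda_, mu, n_atoms, temperature, n_equil, n_prod, seed,
               record_every, traj_every, eta_enabled, gamma)
        if key not in run_cache:
            spec, sim = equilibrated(n_atoms, temperature, seed, n_equil)
            sim.cfg = replace(
                sim.cfg,
                guiding=GuidingParams(mode=mode, gamma=gamma, lambda_=lambda_,
                                      mu=mu),
                eta_enabled=eta_enabled,
            )
            if mode is Mode.SGLD_GLE:
                sim.state.noise.nu = gle_nu(lambda_)
            res = sim.advance(n_prod, record_every=record_every,
                              traj_every=traj_every)
            run_cache[key] = (spec, res, sim)
        return run_cache[key]

    return run


@pytest.fixture(scope="session")
def sdw_rx_runner(sdw_runner):
    """Replica-exchange ladders on the skewed double well."""
    from sgsim.replica import run_rxsgld

    def run(stages, seed=1, n_cycles=40, exchange_interval=1000, **kw):
        cfg = IntegratorConfig(
            dt=0.001, n_steps=0, temperature=300.0, seed=seed,
            record_every=100,
            guiding=GuidingParams(mode=Mode.SGLD, gamma=10.0),
        )
        return run_rxsgld(sdw_runner.system, stages, cfg, sdw_runner.r0,
                          n_cycles=n_cycles,
                          exchange_interval=exchange_interval, **kw)

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
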