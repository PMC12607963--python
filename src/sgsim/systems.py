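"""Toy model systems: skewed double well, Lennard-Jones argon, harmonic wells.

All potentials return energies in kcal/mol and forces in kcal/mol/A as exact
negative gradients.  Positions are (n_atoms, 3) arrays in Angstrom; a single
3-vector is accepted for one-particle systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ARGON_EPSILON_K, ARGON_MASS, ARGON_SIGMA, KB
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "SDWParams",
    "LJParams",
    "HarmonicParams",
    "SystemSpec",
    "sdw_energy_forces",
    "lj_energy_forces",
    "lj_pair_energy",
    "harmonic_energy_forces",
    "build_sdw_system",
    "build_argon_system",
    "build_harmonic_system",
    "argon_box_edge",
]

#: Number density of the reference argon fluid (500 atoms / 28.53^3 A^3).
ARGON_DENSITY = 500.0 / 28.53**3


@dataclass(frozen=True)
class SDWParams:
    """Skewed double well: e(x,y,z) = a*y^2*(y^2 - 2*y0^2) + b*(y+y0)^2 + c*(x^2+z^2).

    Two wells sit near y = -y0 and y = +y0; ``a`` sets the well depth, ``b``
    skews the two wells apart in energy, and a large ``c`` confines x and z so
    that motion in those directions is high-frequency.
    """

    a: float = 1.0       # kcal/mol
    b: float = 0.25      # kcal/mol
    c: float = 1000.0    # kcal/mol/A^2
    y0: float = 1.0      # A

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.y0 > 0 and self.b >= 0):
            raise ConfigurationError(
                "SDW parameters require a > 0, c > 0, y0 > 0, b >= 0"
            )

    def profile(self, y: np.ndarray) -> np.ndarray:
        """Potential along the y axis at x = z = 0."""
        y = np.asarray(y, dtype=float)
        return self.a * y**2 * (y**2 - 2 * self.y0**2) + self.b * (y + self.y0) ** 2

    def barrier_top(self) -> float:
        """y position of the interior maximum, found by scan between the wells."""
        y = np.arange(-self.y0, self.y0, 1e-3)
        return float(y[np.argmax(self.profile(y))])


@dataclass(frozen=True)
class LJParams:
    """Truncated, energy-shifted Lennard-Jones 6-12 pair potential."""

    epsilon: float = ARGON_EPSILON_K * KB   # kcal/mol
    sigma: float = ARGON_SIGMA              # A
    cutoff: float = 8.5                     # A

    def __post_init__(self) -> None:
        if not (self.epsilon > 0 and self.sigma > 0 and self.cutoff > self.sigma):
            raise ConfigurationError(
                "LJ parameters require epsilon > 0, sigma > 0, cutoff > sigma"
            )


@dataclass(frozen=True)
class HarmonicParams:
    """Isotropic harmonic well centred at the origin, one per atom."""

    k_spring: float = 1.0  # kcal/mol/A^2

    def __post_init__(self) -> None:
        if not self.k_spring > 0:
            raise ConfigurationError("harmonic k_spring must be > 0")


Potential = SDWParams | LJParams | HarmonicParams


@dataclass(frozen=True)
class SystemSpec:
    """A simulation system: atom masses, a potential, and an optional box."""

    n_atoms: int
    masses: np.ndarray               # amu, shape (n_atoms,)
    potential: Potential
    box: float | None = None         # cubic edge, A; None = non-periodic

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        if masses.shape != (self.n_atoms,) or not np.all(masses > 0):
            raise ConfigurationError("masses must be positive, one per atom")
        if isinstance(self.potential, LJParams):
            if self.box is None:
                raise ConfigurationError("LJ systems require a periodic box")
            if self.box < 2 * self.potential.cutoff:
                raise ConfigurationError(
                    f"box edge {self.box:.3f} A must exceed twice the "
                    f"cutoff {self.potential.cutoff:.3f} A"
                )

    @property
    def ndf(self) -> int:
        return 3 * self.n_atoms

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        """Dispatch to the potential's energy/force routine."""
        if isinstance(self.potential, SDWParams):
            return sdw_energy_forces(positions, self.potential)
        if isinstance(self.potential, LJParams):
            return lj_energy_forces(positions, self.box, self.potential)
        return harmonic_energy_forces(positions, self.potential.k_spring)


def _check_positions(positions: np.ndarray) -> np.ndarray:
    r = np.atleast_2d(np.asarray(positions, dtype=float))
    if r.ndim != 2 or r.shape[1] != 3:
        raise InvalidInputError(f"positions must be (n, 3), got {r.shape}")
    if not np.all(np.isfinite(r)):
        raise InvalidInputError("positions contain non-finite values")
    return r


def sdw_energy_forces(
    positions: np.ndarray, params: SDWParams
) -> tuple[float, np.ndarray]:
    """Energy and forces of the skewed double well."""
    r = _check_positions(positions)
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    a, b, c, y0 = params.a, params.b, params.c, params.y0
    energy = float(np.sum(a * y**2 * (y**2 - 2 * y0**2) + b * (y + y0) ** 2
                          + c * (x**2 + z**2)))
    forces = np.empty_like(r)
    forces[:, 0] = -2 * c * x
    forces[:, 1] = -(4 * a * y**3 - 4 * a * y0**2 * y + 2 * b * (y + y0))
    forces[:, 2] = -2 * c * z
    return energy, forces


def lj_pair_energy(r: float, params: LJParams, shifted: bool = True) -> float:
    """Pair energy at separation ``r``; optionally without the cutoff shift."""
    sr6 = (params.sigma / r) ** 6
    u = 4 * params.epsilon * (sr6 * sr6 - sr6)
    if shifted:
        sr6c = (params.sigma / params.cutoff) ** 6
        u -= 4 * params.epsilon * (sr6c * sr6c - sr6c)
    return u


def lj_energy_forces(
    positions: np.ndarray, box: float, params: LJParams, overlap_r: float = 0.1
) -> tuple[float, np.ndarray]:
    """Total truncated-shifted LJ energy and per-atom forces (minimum image).

    Raises :class:`ConfigurationError` if the box cannot hold the cutoff
    sphere and :class:`InvalidInputError` on atom overlaps closer than
    ``overlap_r`` (never silently continued).
    """
    r = _check_positions(positions)
    if box is None or box < 2 * params.cutoff:
        raise ConfigurationError("periodic box edge must be at least 2*cutoff")
    n = r.shape[0]
    # O(n^2) minimum-image pair loop, vectorized over pairs
    dr = r[:, None, :] - r[None, :, :]
    dr -= box * np.round(dr / box)
    iu = np.triu_indices(n, k=1)
    d = dr[iu]
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < overlap_r**2):
        raise InvalidInputError(
            f"{int(np.sum(r2 < overlap_r ** 2))} atom pairs closer than "
            f"{overlap_r} A: overlapping configuration"
        )
    rc2 = params.cutoff**2
    mask = r2 < rc2
    sr6 = np.zeros_like(r2)
    sr6[mask] = (params.sigma**2 / r2[mask]) ** 3
    sr6c = (params.sigma / params.cutoff) ** 6
    ushift = 4 * params.epsilon * (sr6c * sr6c - sr6c)
    energy = float(np.sum(4 * params.epsilon * (sr6**2 - sr6) - ushift * mask))
    w = np.zeros_like(r2)
    w[mask] = 24 * params.epsilon * (2 * sr6[mask] ** 2 - sr6[mask]) / r2[mask]
    fpair = w[:, None] * d
    forces = np.zeros_like(r)
    np.add.at(forces, iu[0], fpair)
    np.add.at(forces, iu[1], -fpair)
    return energy, forces


def harmonic_energy_forces(
    positions: np.ndarray, k_spring: float
) -> tuple[float, np.ndarray]:
    """Energy 1/2*k*|r|^2 per atom, force -k*r."""
    if k_spring <= 0:
        raise ConfigurationError("k_spring must be > 0")
    r = _check_positions(positions)
    energy = float(0.5 * k_spring * np.sum(r * r))
    return energy, -k_spring * r


def build_sdw_system(
    params: SDWParams | None = None, mass: float = ARGON_MASS
) -> tuple[SystemSpec, np.ndarray]:
    """One argon-mass particle on the skewed double well, starting in the
    deeper well at (0, -y0, 0)."""
    params = params or SDWParams()
    spec = SystemSpec(1, np.array([mass]), params)
    r0 = np.array([[0.0, -params.y0, 0.0]])
    return spec, r0


def build_harmonic_system(
    k_spring: float = 1.0, n_atoms: int = 1, mass: float = ARGON_MASS
) -> tuple[SystemSpec, np.ndarray]:
    spec = SystemSpec(n_atoms, np.full(n_atoms, mass), HarmonicParams(k_spring))
    return spec, np.zeros((n_atoms, 3))


def argon_box_edge(n_atoms: int) -> float:
    """Cubic edge that keeps the reference argon fluid number density."""
    return float((n_atoms / ARGON_DENSITY) ** (1.0 / 3.0))


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocities (A/ps) with centre-of-mass momentum removed."""
    from .constants import KCAL_TO_INTERNAL

    masses = np.asarray(masses, dtype=float)
    std = np.sqrt(KB * temperature * KCAL_TO_INTERNAL / masses)
    v = rng.standard_normal((masses.size, 3)) * std[:, None]
    p = masses[:, None] * v
    v -= p.sum(axis=0) / masses.sum()
    return v


def build_argon_system(
    n_atoms: int = 125,
    box_edge: float | None = None,
    temperature: float = 100.0,
    seed: int = 0,
    cutoff: float | None = None,
) -> tuple[SystemSpec, np.ndarray, np.ndarray]:
    """Argon atoms on a simple-cubic lattice with Maxwell-Boltzmann velocities.

    ``box_edge`` defaults to the edge that keeps the reference fluid density;
    ``cutoff`` defaults to 10 A, reduced to just under half the box edge for
    small scaled-down boxes.
    Returns (spec, positions, velocities); deterministic under ``seed``.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be > 0")
    if box_edge is None:
        box_edge = argon_box_edge(n_atoms)
    if cutoff is None:
        cutoff = min(10.0, 0.497 * box_edge)
    n_side = int(np.ceil(n_atoms ** (1.0 / 3.0)))
    if n_side**3 < n_atoms:
        n_side += 1
    spacing = box_edge / n_side
    sigma = ARGON_SIGMA
    if spacing < 0.9 * sigma:
        raise ConfigurationError(
            f"lattice spacing {spacing:.2f} A too small for {n_atoms} atoms "
            f"in a {box_edge:.2f} A box"
        )
    sites = np.array(
        [(i, j, k) for i in range(n_side) for j in range(n_side) for k in range(n_side)],
        dtype=float,
    )[:n_atoms]
    positions = (sites + 0.5) * spacing
    masses = np.full(n_atoms, ARGON_MASS)
    spec = SystemSpec(n_atoms, masses, LJParams(cutoff=cutoff), box=box_edge)
    rng = np.random.default_rng(seed)
    velocities = maxwell_boltzmann_velocities(masses, temperature, rng)
    return spec, positions, velocities
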