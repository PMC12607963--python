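"""Trajectory observables: velocity autocorrelation and its power spectrum,
diffusion constants, barrier-crossing counts, and energy histograms."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "SpectrumResult",
    "CrossingResult",
    "vacf",
    "power_spectrum",
    "diffusion_constant",
    "count_barrier_crossings",
    "energy_histogram",
    "histogram_overlap",
]


def _strip_com(x: np.ndarray) -> np.ndarray:
    """Subtract the per-frame mean over atoms (equal masses assumed)."""
    return x - x.mean(axis=1, keepdims=True)


def vacf(
    velocities: np.ndarray, max_lag: int, remove_com: bool = False
) -> np.ndarray:
    """Velocity autocorrelation averaged over atoms and time origins.

    ``velocities`` is (n_frames, n_atoms, 3) on a uniform time grid;
    returns C of length ``max_lag + 1`` with
    C(l) = < v(t0) . v(t0 + l) >_{t0, atoms}.  Computed via FFT.

    ``remove_com`` subtracts the centre-of-mass velocity per frame first;
    use it for fluids where an undamped drift would otherwise contribute a
    constant plateau (e.g. NVE or zero-frequency-frictionless runs).
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim == 2:
        v = v[:, None, :]
    if remove_com and v.shape[1] > 1:
        v = _strip_com(v)
    n = v.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 frames for a VACF")
    if not 0 < max_lag < n:
        raise InvalidInputError(f"max_lag must be in [1, {n - 1}]")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fv = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft((fv * fv.conj()).real.sum(axis=(1, 2)), n=nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return acf / (counts * v.shape[1])


@dataclass
class SpectrumResult:
    """Power spectrum of a velocity autocorrelation function.

    ``density[0]`` equals the numerical two-sided integral of the windowed
    C(t); for diffusive motion it is proportional to the diffusion constant
    (rho(0) = 6 D in three dimensions).
    """

    frequencies: np.ndarray   # angular frequency omega, 1/ps
    density: np.ndarray
    vacf: np.ndarray          # windowed C(t) actually transformed
    dt: float
    metadata: dict = field(default_factory=dict)

    def density_at(self, omega: float) -> float:
        return float(np.interp(omega, self.frequencies, self.density))


def power_spectrum(
    c: np.ndarray, dt: float, window: str = "hann", pad_factor: int = 4
) -> SpectrumResult:
    """Discrete transform of a symmetrized, windowed VACF.

    C is given for lags 0..L; it is extended symmetrically (C(-t) = C(t)),
    tapered with a cosine half-window, zero-padded ``pad_factor``-fold and
    transformed, so rho(omega) = dt * sum_t C(t) w(|t|) exp(-i omega t) on
    the FFT frequency grid.  The transform of the even sequence is real.
    """
    c = np.asarray(c, dtype=float)
    L = c.size - 1
    if window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * np.arange(L + 1) / max(L, 1)))
    elif window in (None, "none", "boxcar"):
        w = np.ones(L + 1)
    else:
        raise InvalidInputError(f"unknown window {window!r}")
    cw = c * w
    m = pad_factor * (2 * L + 2)
    # circularly symmetric layout: [C0, C1..CL, zeros, CL..C1]
    x = np.zeros(m)
    x[0] = cw[0]
    if L > 0:
        x[1 : L + 1] = cw[1:]
        x[-L:] = cw[1:][::-1]
    rho = dt * np.fft.rfft(x).real
    freq = 2.0 * np.pi * np.fft.rfftfreq(m, d=dt)
    return SpectrumResult(
        freq, rho, cw, dt,
        metadata={"window": window, "pad_factor": pad_factor, "max_lag": L},
    )


def diffusion_constant(
    positions: np.ndarray,
    dt: float,
    fit_window: tuple[float, float] = (0.2, 0.8),
    box: float | None = None,
    remove_com: bool = False,
) -> tuple[float, dict]:
    """Diffusion constant (A^2/ps) from the slope of the mean-squared
    displacement, MSD(t) ~ 6 D t.

    ``positions`` is (n_frames, n_atoms, 3) of *unwrapped* coordinates with
    frame spacing ``dt``.  The linear fit uses the relative lag range
    ``fit_window`` of the computed MSD curve; slope, intercept and R^2 are
    reported.  If a box edge is given, a plateau near the box scale triggers
    a wrapped-coordinate warning.  ``remove_com`` measures displacements in
    the centre-of-mass frame (recommended for fluids: a residual drift grows
    quadratically and would swamp the diffusive slope).
    """
    r = np.asarray(positions, dtype=float)
    if r.ndim == 2:
        r = r[:, None, :]
    if remove_com and r.shape[1] > 1:
        r = _strip_com(r)
    n = r.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 frames for an MSD")
    max_lag = n // 2
    lags = np.arange(1, max_lag + 1)
    # FFT-based MSD over all time origins
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    s2 = (r**2).sum(axis=2)                      # (n, atoms)
    fv = np.fft.rfft(r, n=nfft, axis=0)
    acf = np.fft.irfft((fv * fv.conj()).real.sum(axis=2), n=nfft, axis=0)[:n]
    counts = (n - np.arange(n))[:, None]
    acf = acf / counts
    css = np.cumsum(s2, axis=0)
    css_rev = np.cumsum(s2[::-1], axis=0)
    msd = np.empty((max_lag, r.shape[1]))
    for i, lag in enumerate(lags):
        sa = (css[-1] - (css[lag - 1] if lag > 0 else 0)) / (n - lag)
        sb = (css_rev[-1] - (css_rev[lag - 1] if lag > 0 else 0)) / (n - lag)
        msd[i] = sa + sb - 2 * acf[lag]
    msd_mean = msd.mean(axis=1)
    lo = max(0, int(fit_window[0] * max_lag) - 1)
    hi = max(lo + 2, int(fit_window[1] * max_lag))
    tfit = lags[lo:hi] * dt
    yfit = msd_mean[lo:hi]
    slope, intercept = np.polyfit(tfit, yfit, 1)
    pred = slope * tfit + intercept
    ss_res = float(np.sum((yfit - pred) ** 2))
    ss_tot = float(np.sum((yfit - yfit.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if box is not None and msd_mean[-1] > 0:
        if abs(slope) * tfit[-1] < 0.05 * box**2 and msd_mean[-1] > 0.1 * box**2:
            warnings.warn(
                "MSD plateaus near the box scale; coordinates look wrapped",
                RuntimeWarning, stacklevel=2,
            )
    D = max(slope / 6.0, 0.0)
    info = {"slope": float(slope), "intercept": float(intercept), "r2": r2,
            "fit_window_ps": (float(tfit[0]), float(tfit[-1]))}
    return D, info


@dataclass
class CrossingResult:
    """Barrier-crossing count with the dwell (well-label) sequence."""

    n_crossings: int
    barrier_y: float
    hysteresis: float
    dwell_wells: list   # sequence of visited well labels (-1 / +1)


def count_barrier_crossings(
    y: np.ndarray, barrier_y: float, hysteresis: float
) -> CrossingResult:
    """Count transitions between the two wells of a double-well coordinate.

    A crossing is registered each time the trajectory, last committed to one
    well (beyond ``barrier_y -/+ hysteresis``), first reaches beyond the
    hysteresis band on the other side; recrossings inside the band are not
    counted.  The count is invariant to time-reversal of the series.
    """
    if hysteresis <= 0:
        raise InvalidInputError("hysteresis must be > 0")
    y = np.asarray(y, dtype=float)
    labels = np.zeros(y.size, dtype=int)
    labels[y <= barrier_y - hysteresis] = -1
    labels[y >= barrier_y + hysteresis] = +1
    committed = labels[labels != 0]
    if committed.size == 0:
        return CrossingResult(0, barrier_y, hysteresis, [])
    wells = [int(committed[0])]
    for lab in committed[1:]:
        if lab != wells[-1]:
            wells.append(int(lab))
    return CrossingResult(len(wells) - 1, barrier_y, hysteresis, wells)


def energy_histogram(
    energies: np.ndarray, bins: int | np.ndarray = 50,
    range_: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram (density, bin_edges)."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise InvalidInputError("no frames to histogram")
    density, edges = np.histogram(e, bins=bins, range=range_, density=True)
    return density, edges


def histogram_overlap(
    a: np.ndarray, b: np.ndarray, bins: int = 50
) -> float:
    """Overlap coefficient of two samples: integral of the bin-wise minimum
    of their densities on a common grid (1 for identical distributions)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    da, edges = energy_histogram(a, bins, (lo, hi))
    db, _ = energy_histogram(b, bins, (lo, hi))
    width = np.diff(edges)
    return float(np.sum(np.minimum(da, db) * width))
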