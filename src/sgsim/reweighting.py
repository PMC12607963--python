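"""Canonical-ensemble recovery from self-guided runs, and temperature
diagnostics.

A self-guided simulation with guiding factors (lambda, mu) samples a biased
ensemble: the force guiding term corresponds to an added energy surface
``mu (E_avg - E_avg2)`` and the momentum guiding term to ``-mu_lambda
(E_avg - E_avg2)``, where mu_lambda is the balanced force factor of lambda
and E_avg, E_avg2 are the singly and doubly filtered local-average potential
energies.  The sampled density is thus

    rho_SG  propto  exp(-beta [E_p + (mu - mu_lambda)(E_avg - E_avg2)])

and the canonical-recovery frame weight is its inverse bias factor,

    w = exp(+beta (mu - mu_lambda) (E_avg - E_avg2)).

(The overall exponent sign is fixed empirically by the balance property:
at mu = mu_lambda the weights are 1 and the run is canonical as sampled,
and with this sign reweighted biased-run averages match unguided Langevin
averages; the opposite sign moves them away.)  Canonical averages follow by
weighted averaging over frames.

beta uses the thermostat target temperature.  Standard errors of means over
correlated frames come from block averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB
from .errors import InvalidInputError
from .guiding import balanced_force_factor

__all__ = [
    "WeightedEstimate",
    "conformation_weight",
    "reweighted_average",
    "block_mean_se",
    "weighted_block_mean_se",
    "low_frequency_temperature",
    "self_guiding_temperature",
    "DEFAULT_WARMUP_TL",
]

#: Frames earlier than this many t_L are excluded from ensemble estimates.
DEFAULT_WARMUP_TL = 5.0

_EXP_CLIP = 700.0


@dataclass(frozen=True)
class WeightedEstimate:
    """A reweighted mean with its bookkeeping."""

    mean: float
    weights_sum: float
    effective_sample_size: float
    se: float = float("nan")


def conformation_weight(
    E_avg: np.ndarray | float,
    E_avg2: np.ndarray | float,
    lambda_: float,
    mu: float,
    beta: float,
) -> np.ndarray | float:
    """Frame weight w = exp(+beta (mu - mu_lambda) (E_avg - E_avg2)),
    the inverse of the sampled ensemble's bias factor."""
    mu_l = balanced_force_factor(lambda_)
    expo = beta * (mu - mu_l) * (np.asarray(E_avg, dtype=float) - E_avg2)
    if np.any(np.abs(expo) > _EXP_CLIP):
        warnings.warn(
            "reweighting exponent clipped at +-700; weights are saturated",
            RuntimeWarning,
            stacklevel=2,
        )
        expo = np.clip(expo, -_EXP_CLIP, _EXP_CLIP)
    w = np.exp(expo)
    return float(w) if np.isscalar(E_avg) else w


def reweighted_average(values: np.ndarray, weights: np.ndarray) -> WeightedEstimate:
    """Weighted mean sum(w P)/sum(w) with effective sample size
    (sum w)^2 / sum(w^2)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise InvalidInputError("values and weights must have equal length")
    if np.any(w < 0):
        raise InvalidInputError("weights must be non-negative")
    sw = float(w.sum())
    if sw == 0:
        raise InvalidInputError("all weights vanished; cannot reweight")
    mean = float(np.dot(w, v) / sw)
    ess = sw**2 / float(np.dot(w, w))
    return WeightedEstimate(mean, sw, ess)


def block_mean_se(x: np.ndarray, n_blocks: int = 20) -> tuple[float, float]:
    """Mean and standard error of a correlated series via block averaging."""
    x = np.asarray(x, dtype=float)
    n_blocks = min(n_blocks, max(2, x.size))
    blocks = np.array_split(x, n_blocks)
    bm = np.array([b.mean() for b in blocks])
    return float(x.mean()), float(bm.std(ddof=1) / np.sqrt(len(bm)))


def weighted_block_mean_se(
    values: np.ndarray, weights: np.ndarray, n_blocks: int = 20
) -> WeightedEstimate:
    """Reweighted mean with a block-averaged standard error (blocks of the
    weighted-mean estimator, weighted by their weight mass)."""
    est = reweighted_average(values, weights)
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    vb = np.array_split(v, n_blocks)
    wb = np.array_split(w, n_blocks)
    bm = np.array([np.dot(wi, vi) / wi.sum() for vi, wi in zip(vb, wb) if wi.sum() > 0])
    se = float(bm.std(ddof=1) / np.sqrt(len(bm)))
    return WeightedEstimate(est.mean, est.weights_sum, est.effective_sample_size, se)


def low_frequency_temperature(
    p_lf: np.ndarray, masses: np.ndarray, ndf: int
) -> float:
    """Low-frequency kinetic temperature (K) from the filtered momenta:
    T_lf = (1/(ndf kB)) sum p_lf^2/m, with p_lf in amu*A/ps."""
    from .constants import KCAL_TO_INTERNAL

    if ndf <= 0:
        raise InvalidInputError("ndf must be > 0")
    p = np.atleast_2d(np.asarray(p_lf, dtype=float))
    m = np.asarray(masses, dtype=float)
    s = float(np.sum(np.einsum("ij,ij->i", p, p) / m))
    return s / (ndf * KB * KCAL_TO_INTERNAL)


def self_guiding_temperature(T: float, T_lf: float, T_lf0: float) -> float:
    """Self-guiding temperature quantifying conformational search power:
    T_SG = T_lf (T - T_lf0) / (T_lf0 (T - T_lf)) * T.

    T_lf0 is the low-frequency temperature of a guiding-free run of the same
    system, thermostat and filter; with no guiding T_SG = T.
    """
    if not (0 < T_lf < T) or not (0 < T_lf0 < T):
        raise InvalidInputError(
            f"need 0 < T_lf, T_lf0 < T; got T={T}, T_lf={T_lf}, T_lf0={T_lf0} "
            "(T_lf >= T usually indicates a mis-set t_L or dt)"
        )
    return T_lf * (T - T_lf0) / (T_lf0 * (T - T_lf)) * T
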