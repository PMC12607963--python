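# Methods

## The self-guided equation of motion

Self-guided molecular dynamics (SGMD) and self-guided Langevin dynamics
(SGLD) enhance conformational search by feeding the low-frequency content of
the recent trajectory back into the equation of motion:

    dp/dt = F + lambda * xi * p_lf + mu * (F_lf - F_lf2)

`p_lf` is the local average of the momentum, `F_lf` and `F_lf2` the singly
and doubly filtered forces.  A *local average* is the exponential moving
average with time constant `t_L`,

    A_lf(t) <- (1 - dt/t_L) A_lf(t - dt) + (dt/t_L) A(t),

a first-order low-pass filter with threshold frequency `1/t_L`.  The
momentum guiding force `lambda*xi*p_lf` pushes along the low-frequency drift
(diffusion-controlled search); the force guiding force `mu*(F_lf - F_lf2)`
amplifies (`mu > 0`) or counteracts (`mu < 0`) the band-passed force, which
for `mu < 0` effectively lowers energy barriers (barrier-controlled search).

Everything is stored as two local-average position arrays (`r_lf`,
`r_lf2`): the filtered momentum is `p_lf = (m/t_L)(r - r_lf)`, the full-step
momentum is reconstructed from the change of `p_lf`, and
`F_lf = (p - p_lf)/t_L`, `F_lf2 = (m/t_L^2)(r - 2 r_lf + r_lf2)`.  Note that
`F_lf` is identically `d p_lf/dt`; consequences of this identity are
discussed under "The apparent friction constant" below.

## Leapfrog discretization

One step at time `t` (shared by every mode):

1. energy `E_p` and interaction forces at `r(t)`; the Langevin random force
   (variance `2 gamma m kB T/dt` per component) is added in the noisy modes;
2. local averages of `E_p` and `r` advance, then `p_lf`, `p`, `F_lf`,
   `F_lf2` are derived;
3. the apparent-friction accumulators `FP <- <(F_lf - F_lf2).p_lf>` and
   `PP <- <p_lf.p_lf>` advance with time constant `t_avg` (default
   `10 t_L`), and `xi = -FP/PP`;
4. the guiding force `g` is assembled;
5. a per-atom energy-conservation scaling factor
   `eta = (2 + gamma dt)(g.p0)/(2 p0^2 - (g.p0) dt)`, with `p0` the
   free-move momentum at `t`, cancels the work done by the guiding force by
   scaling the whole velocity — the guiding pumps low frequencies while
   `eta` drains all frequencies, which is exactly how the low-frequency
   modes heat up at constant total energy;
6. `v(t+dt/2) = [(1-(gamma+eta)dt/2)/(1+(gamma+eta)dt/2)] v(t-dt/2)
   + (f+g) dt / m / (1+(gamma+eta)dt/2)`;
7. `r(t+dt) = r(t) + v(t+dt/2) dt`.

With `lambda = mu = 0` the guiding force and `eta` vanish identically, so
SGLD reduces bitwise to LD and SGMD to MD under a shared noise stream; this
reduction is asserted in the tests.  Kinetic energy is reported with the
standard leapfrog estimator (mean of squared velocities at the two adjacent
half-steps).  `p0` includes the random force, consistent with the force
defined in the velocity update.

Cold start: `r_lf = r_lf2 = r(0)`, filtered energies equal `E_p(0)`,
`p_lf_prev = FP = PP = 0`, so guiding grows in smoothly.  `xi` stays 0 until
`PP > 1e-12` (internal units).  Frames earlier than `5 t_L` are excluded
from ensemble statistics by default.

Units: A, ps, amu, kcal/mol, with `kB = 0.0019872041 kcal/mol/K` and
`1 kcal/mol = 418.4 amu A^2/ps^2`; the conversion chain is validated by the
equipartition tests rather than asserted.

## Balanced guiding factors and reweighting

The two guiding terms bias the conformational distribution in opposite
directions.  With `u = 1 + mu`, the balanced pair satisfies the cubic
`u^3 - lambda u - 1 = 0` (equivalently `lambda = (1+mu)^2 - 1/(1+mu)`);
`balanced_force_factor` evaluates the real Cardano root with a Newton
polish (the radicand cancels catastrophically near `lambda = 0`).  Two sign
conventions coexist and are both exposed:

* `mu_lambda = balanced_force_factor(lambda)` — the *canceling* factor:
  running at `(lambda, mu_lambda)` samples the canonical ensemble
  (`mu_lambda(1) = +0.3247`);
* `equivalent_force_factor(lambda) = -mu_lambda` — the *equal-enhancement*
  correspondent conventionally quoted for the method
  (`lambda = -1..1` corresponds to `mu = 0.3177..-0.3247`).

The sampled self-guided ensemble is
`rho_SG ~ exp(-beta [E_p + (mu - mu_lambda)(E_lf - E_lf2)])`, where
`E_lf - E_lf2` is the band-passed potential energy (positively correlated
with `E_p`).  Canonical averages are recovered with the inverse bias weight

    w = exp(+beta (mu - mu_lambda)(E_lf - E_lf2)),

so `w = 1` at the balanced pair.  The overall exponent sign is pinned
empirically by two measurements on the skewed double well: the balanced run
matches the unguided mean, and reweighting a `(lambda=1, mu=0)` run with
this sign moves its mean onto the unguided one (the opposite sign moves it
away).  `beta` uses the thermostat target temperature.  Every reweighted
estimate carries an effective sample size `(sum w)^2 / sum w^2`; standard
errors of correlated series come from 20-block averaging.

## The apparent friction constant

Because `F_lf = d p_lf/dt` exactly, stationarity gives

    xi = (1 - <p_lf . p_lf2> / <p_lf . p_lf>) / t_L  in (0, 1/t_L),

i.e. the on-the-fly estimator is intrinsically confined below the filter
frequency; for strongly damped systems it saturates near `1/(2 t_L)`
(measured ~2.3/ps on both liquid argon and the double well at
`t_L = 0.2 ps`).  This bound matters when comparing SGLD with SGLD-GLE (see
"Known limitations").

## SGLD-GLE: colored noise with canonical sampling

Choosing a generalized-Langevin memory kernel
`K(t) = 2 delta(t) - (lambda/t_L) exp(-t/t_L)` yields the equation of motion

    dp/dt = f - gamma p + lambda gamma p_lf + R - nu R_lf,

with white `R` and `nu = 1 - sqrt(1 - lambda)` (the chosen branch of
`lambda = nu(2 - nu)`; both roots are statistically equivalent).  The
fluctuation-dissipation theorem holds at every frequency, so the canonical
ensemble is preserved while zero-frequency drag is reduced by the factor
`1 - lambda`.  No `eta` is applied — adding it would double-correct.
`p_lf` reuses the position-difference route of SGMD/SGLD for a single code
path.

Discretization of `R_lf`: the local average is taken over *strictly past*
draws (`noise = R(t) - nu R_lf(t-dt)`, then the filter advances).  Updating
the filter before use leaves a measurable O(dt/t_L) cold bias (about -1% in
`<x^2>` at `dt = 1 fs`, `t_L = 0.2 ps`, `lambda = 1` on a harmonic well);
the strictly-past convention is unbiased within tight statistics
(+0.08% +- 0.27% over 9M steps).  Both conventions are consistent
discretizations of the continuous filter integral.

## Replica exchange (RXSGLD / TRXLD)

A stage is a condition `(T, lambda, mu)`; replicas run dynamics segments and
attempt stage swaps.  The default (generalized) Metropolis criterion follows
from `rho_SG` above:

    ln ratio = (beta_m - beta_n)(E_i - E_j)
             - [beta_m(mu_m - mu_hat_m) - beta_n(mu_n - mu_hat_n)]
               (dE_i - dE_j),

with `dE = E_lf - E_lf2` and `mu_hat` the stage's balanced factor.  The
legacy criterion built from frequency-separated energy/collision factors
(tracked during the run with `t_avg` filtering of each numerator and
denominator) is retained for diagnostics; it relies on an equal-temperature
approximation and warns otherwise.  Swapping exchanges stage labels only —
momenta are kept, which is exact for the recommended equal-temperature
ladders.  Partner selection alternates even/odd adjacent pairs on a fixed
schedule (a two-stage ladder attempts its only pair every cycle); fully
random adjacent pairing is available.  A stage's search power is summarized
by the self-guiding temperature
`T_SG = T_lf (T - T_lf0) / (T_lf0 (T - T_lf)) T`, with `T_lf0` calibrated
from a zero-guiding companion run of the same system, thermostat and filter
(degrees of freedom counted as `3N` throughout).

## Toy systems and study conditions

* **Skewed double well (SDW)**: one argon-mass particle (39.948 amu; the
  mass is not printed with the potential and is taken from the stated
  particle) on `a y^2(y^2 - 2 y0^2) + b(y + y0)^2 + c(x^2 + z^2)` with
  `a = 1`, `b = 0.25`, `c = 1000 kcal/mol`, `y0 = 1 A`; `T = 300 K`,
  `gamma = 10/ps`, `dt = 1 fs`, `t_L = 0.2 ps`; runs of 1 ns (the reference
  experiments use 100 ns; 1 ns keeps every comparison inside its quoted
  uncertainty at desk scale).  Barrier crossings are counted with a
  hysteresis band of `0.5 y0` around the scanned barrier top (y ~ 0.146 A):
  a crossing requires committing beyond the band on the other side, which
  suppresses recrossing noise; the count is time-reversal invariant.
* **Lennard-Jones argon**: `epsilon = 119.8 K`, `sigma = 3.405 A`,
  truncated-and-shifted at the cutoff (the reference long-range method is a
  different published scheme; shifted truncation preserves the energy
  conservation that the `eta` tests require).  Scaled-down systems keep the
  reference density (500 atoms / 28.53 A box): 125 atoms in a 17.97 A box
  (cutoff capped just under half the box, 8.93 A) and 64 atoms in a 14.38 A
  box.  Simple-cubic lattice start, Maxwell-Boltzmann velocities with the
  COM momentum removed, 20-30 ps LD equilibration, 50-100 ps production.
  O(N^2) minimum-image pair loop (no cell lists — performance is not a
  surface here); the numba kernel integrates ~10^6 one-particle or ~10^3
  125-atom steps per second.
* **Harmonic wells** provide the analytic oracles (equipartition, OU
  autocorrelation, Einstein relation with a vanishing spring).

The generator emulates equilibrium fluids and barrier crossing only; it has
no bonded terms, electrostatics, solvent, or NPT barostat, so passing tests
demonstrate the guiding/reweighting/exchange machinery, not force-field
realism.

## Analysis choices

VACF is computed by FFT over atoms and time origins; fluid analyses remove
the per-frame COM motion (an undamped drift — inevitable after a Langevin
segment in NVE or zero-DC-friction runs — otherwise adds a ballistic term
that swamps both the MSD slope and the zero-frequency spectral density).
The power spectrum transforms the symmetrized VACF with a Hann taper and
4x zero padding (window and padding recorded in the result metadata);
`rho(0)` equals the two-sided integral of the windowed VACF and is `6 D`
for diffusive motion.  Diffusion constants come from a linear fit of
`MSD = 6 D t` over a stated relative lag window, with slope, intercept and
R^2 reported.  Histograms are density-normalized; distribution overlap uses
the integrated bin-wise minimum.

## Known limitations

* At constant volume the SGLD diffusion gain at `lambda = 1` is *smaller*
  than SGLD-GLE's: SGLD's zero-frequency drag reduction is bounded by
  `lambda * xi < 1/t_L` (see the `xi` bound above), while SGLD-GLE cancels
  the full thermostat drag `gamma = 10/ps`.  The reference NPT comparison,
  where the guided run's energy/volume elevation opens a density channel,
  is outside this package's scope (no barostat), and the corresponding
  spectral-ordering assertion in the acceptance tests fails by design of
  the scaled-down conditions.  Measured at 125 atoms / 100 ps NVT:
  `D` gains +0.010 (SGLD) vs +0.083 (SGLD-GLE) A^2/ps over LD's 0.031.
* The discrete integrators carry O(dt) ensemble bias; at the standard
  `dt = 1 fs`, `t_L = 0.2 ps` settings it is below the statistical
  resolution of every test here.
* Replica-exchange runs are sequential in-process; no distributed
  execution.
* `Omega`-style partition normalizers are never computed — only weight
  ratios are used.
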