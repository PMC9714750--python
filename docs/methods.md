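# Methods

## The measurement being modelled

A phosphorescent Zn-protoporphyrin probe embedded in hemoglobin decays on
the millisecond scale. In an oxygen-saturated, cryosolvent-free sample the
decay is unquenched as long as the protein matrix is frozen; once matrix
dynamics are thermally activated, dissolved O₂ diffuses and quenches the
triplet state, shortening the lifetime. A stepwise-warming protocol
(thermal equilibration at each temperature, 10 K increments on the frozen
plateau, 5 K through the transition) yields one summed photon-counting
decay trace per temperature. The analysis chain is: deconvolve each trace
into discrete exponential components; reduce it to the ensemble-average
lifetime; normalise the temperature series by the frozen-plateau mean τ₀;
fit the protein-specific activation step with a two-state thermodynamic
model.

## Decay model and fitting

A heterogeneous emitter population gives

    I(t) = Σᵢ Aᵢ e^(−t/τᵢ),  1 ≤ n ≤ 5,  Aᵢ ≥ 0, τᵢ > 0,

plus an optional flat background per bin. Binned expectations use the
exact integral of each exponential over the bin, not the midpoint value,
removing discretisation bias from lifetime recovery.

**Objective.** The default objective is the Poisson maximum likelihood,
minimised as least squares on signed square-root deviance residuals
d_j = sign(c_j − m_j) √(2(m_j − c_j + c_j ln(c_j/m_j))). This matters: with
~10⁵ photons spread over thousands of 80 µs bins, most tail bins hold only
a few counts, and the familiar "observed-count" weighting 1/max(c_j, 1)
(Neyman χ²) over-weights downward-fluctuating bins. In our simulations
that weighting biased the recovered ensemble average by 5–8% low; the
maximum-likelihood objective reduced the bias to ~0.2%. An unweighted
least-squares option remains available. The reported reduced χ² is the
reduced deviance in the Poisson case (both ≈ 1 for a correct model).

**Parsimony rule for n.** Components are added one at a time. The
(n+1)-component candidate is warm-started from the accepted n-component
solution plus one lifetime in the largest logarithmic gap of the current
lifetime grid, amplitudes re-seeded by nonnegative linear least squares at
fixed lifetimes (a separable / variable-projection warm start), then all
2n+1 parameters are refined by bounded trust-region least squares with
lifetimes in log space. Growth stops when the reduced χ² improves by less
than 5% relative, when the newest component holds less than 0.1% of total
amplitude, or at n = 5. Fitted lifetimes closer than relative 10⁻³ are
merged (amplitude sum, amplitude-weighted lifetime) and the reduced model
refitted. Warm starting makes the accepted path's reduced χ²
non-increasing in n.

**Excitation pulse.** The ~2 µs flash is 1/40 of the 80 µs bin, so the
default treats excitation as a delta function. A Gaussian-IRF option
(`irf_fwhm`) exists for completeness: it evaluates the
exponentially-modified-Gaussian closed form on a 16× sub-grid per bin. At
the default bin width its effect is far below counting noise.

**Ensemble average.** ⟨τ⟩ = ΣAᵢτᵢ²/ΣAᵢτᵢ is the first moment of the
multi-exponential; it is invariant to amplitude rescaling and homogeneous
of degree one in the lifetimes. An independent cross-check,
`moment_average_oracle`, computes the background-subtracted discrete
moment ratio Σt_c c / Σc at bin centres; it is biased low when the tail is
truncated (the error is of order the truncated intensity fraction, e^(−20)
≈ 2×10⁻⁹ for a 20-lifetime trace), and tests require fit-based and
moment-based ⟨τ⟩ to agree within 1% on long noiseless traces.

## Two-state activation model

Let the matrix switch between a frozen state (decay rate 1/τ₀) and a
molten, dynamically active state (rate K_d/τ₀), with molar energy and
entropy differences ΔE > 0 and ΔS > 0. With the Boltzmann factor
x(T) = e^(−(ΔE−TΔS)/RT), the molten occupancy is f = x/(1+x) and the
observed normalized lifetime is the reciprocal of the population-weighted
mean rate:

    ⟨τ⟩/τ₀ = [ (1−f)/τ₀ + f·K_d/τ₀ ]⁻¹ / τ₀ = (1 + x) / (1 + K_d x).

The curve falls monotonically from 1 to 1/K_d with midpoint
T_MP = ΔE/(ΔS + R ln K_d) (at T_MP, x = 1/K_d and the ratio is exactly
halfway between the asymptotes). R = 8.314 J/(mol·K); ΔE is carried in
kJ/mol and converted internally; ΔS is in J/(mol·K).

**Numerics.** The exponent is clamped to [−700, 700] and the ratio is
evaluated in log space as exp(log1p-sum differences), so the model is
finite for any admissible parameters at any T > 0.

**Windows.** Defaults: baseline 10–180 K (the plateau over which τ₀ is the
mean and sample SD of ⟨τ⟩), fit window 180–245 K. The upper limit stops
short of the second, solvent-related transition, which this package
deliberately does not model. Both windows are configurable. τ₀ is fixed
from the baseline, not co-fitted — the fit operates on the normalized
ratio in (ΔE, ΔS, K_d) only.

**Fitting.** Bounded trust-region least squares, uniform weights by
default (per-point 1/sd² optional). The deterministic default start is
ΔE⁰ = 100 kJ/mol, ΔS⁰ = ΔE⁰/T_steep with T_steep the steepest observed
drop, K_d⁰ = 1/min(ratio). A window whose minimum ratio stays above 0.95
is rejected as non-identifiable rather than fitted. Parameter SDs come
from the residual-variance-scaled covariance (Jᵀ J)⁻¹ by default, or from
a seeded residual bootstrap (resampled residuals added back to the fitted
curve, ≥ 500 refits); the SD of T_MP is propagated by the delta method.

**Identifiability limit.** K_d is determined by the lower asymptote. When
a transition is broad enough that the curve does not approach 1/K_d inside
the fit window (for the BZF-like parameter set, ΔE ≈ 42 kJ/mol, the ratio
is still ≈ 0.20 at 245 K against a floor of 0.056), K_d becomes weakly
identified: at ratio noise of sd 0.02 its sampling distribution is
strongly right-skewed and even the median over 100 replicates sits ~20%
high, although the estimator is exact on noiseless data and the bias
vanishes as the noise shrinks. ΔE and ΔS remain well recovered (within
~2%) in the same regime. Users fitting broad transitions should either
extend the window (if no second process intrudes) or report K_d with its
bootstrap interval rather than as a point estimate.

## Synthetic data: what it emulates and what it does not

The generator has two fidelity levels.

*Trace level* (`simulate_decay`): Poisson counts per 80 µs bin whose means
are the exact bin integrals of the mixture, scaled by 14 000 flashes ×
`counts_per_flash_scale` (default 0.1, chosen once to give ~200 peak
counts per bin and ~8×10⁴ photons per trace — a realistic weak
single-photon-counting signal; the actually achieved count scale of such
experiments is not published). The default frozen-state mixture has three
components at base lifetimes (12, 25, 45) ms, amplitudes (0.5, 1.0, 0.6),
rescaled so ⟨τ⟩ hits a requested target (28.7 ms by default); real samples
are heterogeneous but their component structure is unknown, so only ⟨τ⟩ is
treated as meaningful.

*Series level* (`simulate_series`): the two-state ratio evaluated directly
with Gaussian noise of chosen sd on the ratio (default study condition
0.02), for fast parameter-recovery work. A full experiment
(`simulate_experiment`) scales every lifetime of the plateau mixture by
r(T) — uniform scaling, so ⟨τ⟩ scales by exactly r(T) — and draws one
Poisson trace per temperature with per-temperature seeds spawned from one
master seed.

Not emulated: instrument response beyond the optional Gaussian IRF,
detector dead time and afterpulsing, drift between temperature steps, the
solvent-related second transition, and any temperature dependence of the
intrinsic (unquenched) lifetime. Passing recovery tests therefore shows
that the analysis chain is unbiased for data generated by its own model
class at realistic counting statistics — not that real traces obey a
5-component discrete mixture.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); no global state. Identical inputs and seed
reproduce outputs bitwise.

## Problem sizes used in tests and the acceptance script

Parameter-recovery studies use 13 temperatures (185–245 K, 5 K), ratio
noise sd 0.02, and 100 replicates per parameter set. Trace-level recovery
uses 20 traces of ~4900 bins (10× the longest lifetime at 80 µs bins);
unit tests that only exercise mechanics use shorter traces or coarser
bins. These sizes make the median estimators stable at the few-permille
level while keeping a full run in minutes on one core.

## Design choices made where the field leaves them open

- Background handling in decay fits is a free nonnegative flat parameter
  by default (published analyses of this experiment do not state their
  background treatment).
- Component-count selection uses the 5%-improvement/0.1%-amplitude rule
  above; "an acceptable least-squares fit with at most five exponentials"
  is the only constraint the experimental literature states, and the rule
  makes that reproducible. With the maximum-likelihood objective the rule
  tends to parsimony (often n = 2 for the default 3-component truth),
  which leaves ⟨τ⟩ essentially unbiased — the best two-component
  approximation of the default mixture has ⟨τ⟩ within 0.6% of truth.
- Transition-fit uncertainties default to covariance-based SDs (how the
  published SDs were obtained is not stated); the bootstrap alternative is
  provided and both record their method in the result metadata.
- The interchange formats are headered CSV plus JSON sidecars; no binary
  spectrometer formats are involved.

## Known limitations

- Lifetime distributions (maximum-entropy or regularised) are out of
  scope; only discrete mixtures are fitted.
- No global simultaneous fit across temperatures; each trace is fitted
  independently.
- The two-state model is a coarse reduction of a conformational ensemble;
  three-state or multi-transition fits are not provided.
- K_d for broad, window-truncated transitions is weakly identified (see
  above).
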