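# Methods

This note documents the models and procedures implemented in
`protospike`, the conventions and defaults they use, and what the
synthetic data generator does and does not emulate.

## Data model and units

A recording is a uniformly sampled potential time series (`VoltageTrace`;
step uniform to 1e-9 relative). All potentials are held internally in mV;
volt-denominated CSV inputs (header `time_s,potential_V`) are converted on
read. Spike trains carry strictly increasing spike times (s) and positive
amplitudes (mV) over a known duration. Statistics conventions throughout:
sample SD with the n−1 denominator; quartiles by linear interpolation
(numpy's inclusive scheme); skewness and kurtosis as population-moment
plugin estimators `m₃/m₂^{3/2}` and `m₄/m₂²` (non-excess: a normal sample
gives ≈ 3). The plugin convention was chosen because the reference
analyses of this system report values consistent with it (e.g. an
amplitude kurtosis of 2.9488 described as near-normal).

## Gamma amplitude model: scale, not rate

The amplitude density is the gamma `f(x; α, b) = x^{α−1} e^{−x/b}/(Γ(α) b^α)`.
The reference analysis of the 1.1 mg/ml condition names its second
parameter b = 0.01904 a "rate", but its own printed mean amplitude
(0.61 mV) equals α·b = 32.27402 × 0.01904, which is only consistent if b
is a **scale**. `GammaFit.scale` therefore stores b as a scale parameter
(mean = shape × scale, SD = √shape × scale: 0.6145 and 0.1082, matching
the printed 0.61 and 0.11 after rounding). This is deliberate and is the
package's single most load-bearing convention.

Fitting is exact maximum likelihood: Newton iteration on the profile
score `log α − ψ(α) = log x̄ − mean(log x)` (ψ the digamma), initialized
at the method-of-moments estimate, converging at |Δα|/α < 1e−10 (typically
3–5 iterations); the scale follows from the first-moment identity
b̂ = x̄/α̂. The fit is cross-checked in the test suite against scipy's
independent gamma MLE with the location pinned at zero.

## Spike detection

The reference analyses report spike statistics but not their detection
procedure, so the detector here is the package's own: baseline = centered
rolling median over a 600 s window; noise scale = 1.4826 × MAD of the
residual (robust, so spikes do not inflate it); a spike is a local maximum
of the residual exceeding max(k·σ̂, A_min) with k = 5 and
A_min = 0.3 mV (just below the smallest amplitude reported for these
systems, 0.38 mV), separated from the previous accepted spike by a 60 s
refractory interval; on a refractory conflict the larger peak wins, which
makes detection deterministic. Printed amplitude statistics are treated as
detector-independent reference values, never as detector acceptance tests.

## Fano-factor machinery

`fano_factor` tiles the recording with consecutive non-overlapping windows
starting at t = 0, discards the final partial window, and returns
Var(N)/E[N] with the n−1 variance; a zero mean count is reported as
undefined rather than zero. Curves FF(w) use 30 log-spaced windows by
default, expressed in units of the mean ISI — the published absolute
0.1–100 s grid is incompatible with ISIs of ~200 s, where small windows
necessarily push FF toward the Bernoulli limit of 1. (How a train with
mean ISI 203 s yielded a printed FF of 0.05 on 0.1–100 s windows is not
explained in the source analysis; the value is carried as a reference
only, and is reproduced here through the renewal identity FF(∞) = CV²:
0.22² = 0.0484 ≈ 0.05.)

A closed-form renewal FF(w) expression sometimes quoted alongside this
analysis is dimensionally inconsistent as printed and fails the Poisson
self-check FF ≡ 1, so it is deliberately **not** implemented. Theoretical
model curves are instead Monte-Carlo estimates (independent long
realizations, empirical FF per window averaged across them), validated in
the tests against the exact large-window asymptote CV² for every renewal
family and against FF → 1 as w → 0⁺.

## Reference point processes

Six families parameterize the reference curves: gamma renewal (shape k,
rate λ; CV² = 1/k), inverse-Gaussian renewal (mean μ, shape λ_IG;
CV² = μ/λ_IG), shifted exponential with refractory dead time, periodic
firing (CV² = 0), and two rate-switching processes whose published
parameter names (p, F) come without definitions. The adopted semantics
are: MPP — a two-state Markov-modulated Poisson process whose hidden state
switches with probability p after each interval, each state having its
own rate; APP — deterministic alternation between rates r and r·F on
successive intervals. Both degenerate to a homogeneous Poisson process
when the two rates coincide (verified by the FF ≈ 1 property test).

## Synthetic data: what it emulates

The multi-day recordings behind the published statistics are not
deposited, so the generator reproduces their *statistical fingerprint*,
not their physics:

- **Condition presets** carry the published per-concentration raw-potential
  mean/SD/range (in volts) for 1.10, 1.86, 4.00, 10.20 mg/ml and the water
  control, the published gamma amplitude fit for 1.1 mg/ml, a
  moment-matched amplitude gamma (mean 5.07, SD 3.38 mV) for 1.8 mg/ml,
  and gamma-renewal ISI models (1.8 mg/ml: mean 203.39 s, SD 52.22 s; the
  keys "1.80"/"1.8" alias the 1.86 mg/ml preset, following the labelling
  of the spiking analyses). One published range (1.86 mg/ml) is printed in
  mV inside an otherwise V-denominated list; the preset stores the V
  reading and flags the ambiguity in its notes.
- **Low-dose heavy tail**: the 1.1 mg/ml ISI distribution combines a bulk
  gamma renewal (mean 200 s, SD 55 s, approximating the printed quartiles
  175/193/249 s) with rare exponential "silent gaps" (probability 0.0046
  per interval, mean 20,000 s), reproducing the extreme right tail
  (printed max ~1.05×10⁵ s, skewness 41) without claiming the unknown
  mechanism. Whether those gaps are biological or instrumental is not
  stated in the source; the mixture is a modelling choice.
- **Traces** are baseline + spikes + noise: a random-walk drift rescaled to
  a target SD, triangular spike templates (3 samples wide at 1 Hz — the
  narrowest representable pulse, since no waveform shape is published)
  with gamma amplitudes at model-generated times, and i.i.d. Gaussian
  sensor noise. The generator returns the injected ground truth alongside.
  Note an inherited scale mismatch: raw-potential statistics are V-scale
  while spikes are mV-scale, so with drift at the preset's raw SD the
  spikes are unrecoverable from the trace. Detector validation therefore
  uses a low-drift configuration (drift SD ~1 mV), where recall and
  precision ≥ 0.95 hold at SNR ≥ 5. Passing these tests shows the
  detector recovers spikes of the published scale over slow drift and
  Gaussian noise; it says nothing about electrode chemistry, temperature
  coupling or solvent effects, which are not modelled.
- **Signal pairs**: the input is a tonically driven regular-spiking
  Izhikevich neuron (a=0.02, b=0.2, c=−65, d=8, dt=1 ms, drive
  10 ± 2 noise), 100 s → 100,000 samples — the unique equal-n consistent
  with the published t = −599.4801 given the published means/SDs. The
  output is the input through the transduction stand-in below.

All generators take explicit seeds; there is no global random state.

## Izhikevich simulation and the transduction stand-in

Integration is forward Euler at dt = 1 ms (the model's canonical published
scheme). When v reaches 30 mV the pre-reset sample is stored as 30 mV and
the reset state (v = c, u = u + d) is stored at the next sample before
integration resumes; this makes the reset semantics exactly observable in
the stored trace. Subthreshold Euler convergence (halving dt changes the
trajectory by < 1% of its range) is verified at dt = 0.1 ms.

The proteinoid–CS network's transformation of the signal is *modelled, not
claimed*: `TransductionModel` is an explicit stand-in — gain on the
deviation from the neuron's resting potential, first-order low-pass
(τ = 5 ms), soft tanh saturation at 5 mV, offset, Gaussian noise, and an
optional anticipatory delay. Defaults (gain 0.04, offset 1.49 mV, delay
122 ms) reproduce the *scale* of the published comparison — output
≈ 1.55 ± 0.34 mV from an input SD ≈ 20 mV, lag ≈ −122 ms — not its exact
values, which depend on unavailable recordings. The published analysis
does not state whether its "output" was a second simulated population or
a physical electrode recording; the stand-in makes no claim either way.
The cross-correlation lag convention is: negative lag ⇔ the output's
pattern precedes the input's.

## Mechanism models

**Electrostatics.** The Poisson–Boltzmann equation is reduced to spherical
symmetry around a charged microsphere: ∇·(ε₀ε_r∇ψ) = −ρ_f − Σ z_i e c_i N_A
exp(−z_i eψ/k_BT) on [a, R], with a Neumann surface-charge condition at a
and ψ(R) = 0. The source framework supplies no geometry, boundary
conditions or parameters, so the defaults (a = 1 µm, 0.1 M 1:1
electrolyte, 298.15 K, ε_r = 78.5) are configuration, not claims.
Discretization is conservative finite differences (flux form, half-cell
balance at the inner boundary); the nonlinear system is solved by damped
Newton iteration (step halving on non-decreasing residual, convergence at
residual max-norm < 1e−10 relative to the ψ = 0 residual; Boltzmann
exponents clipped at ±50 to keep intermediate iterates finite). The solver
is validated against the Debye–Hückel closed form
ψ(r) = σa²/(ε₀ε_r(1+κa)) · e^{−κ(r−a)}/r to < 1% at eψ/k_BT ≤ 0.1, and
against outer-boundary insensitivity when κR ≫ 1. The electrostatic
potential is *not* coupled into the gating energy: the source framework
never quantifies how ψ shifts ΔG, so ΔG is an input.

**Gating and membrane.** Channel open probability is the two-state
Boltzmann P = 1/(1 + e^{ΔG/k_BT}). The membrane ODE
C_m dV/dt = −Σ g_i(V − E_i) + I_ext uses effective conductances
g_i = ḡ_i·P_open(ΔG_i, T); with constant conductances the equation is
linear, so stepping uses the exact exponential-Euler update (and an exact
linear ramp when all ḡ = 0), which conserves the algebraic steady state
(Σ g_iE_i + I_ext)/Σ g_i to machine precision.

**Plasticity.** The CS-dependent Hebbian rule dw_ij/dt = η(CS_ij)·x_i·y_j
is stepped by forward Euler with optional weight clipping. The source
leaves η(CS) abstract (and the units of the activities unspecified; they
are treated as dimensionless); the default is a saturating Michaelis form
η₀·CS/(K + CS), bounded above by η₀, consistent with the observed
stabilisation of electrical activity at high CS concentrations.

## Energetics

`complexation_deltas` computes per-property component sums and
complex-minus-sum deltas over records of final energy, solvation energy
(kJ/mol) and dipole moment (Debye). The published values for chondroitin
sulfate, the L-Glu:L-Asp:L-Phe proteinoid and their complex ship as a
packaged record set (they are printed data, not computed here). Deltas are
reported signed and uninterpreted; note the published prose describes the
complex's solvation energy (−326.25) as more negative than the component
sum (−346.87) although the arithmetic shows the opposite — the module
reports the numbers and leaves the reading to the user.

## Problem sizes and tolerances

Default problem sizes were chosen as the smallest that make the
statistical assertions sharp: 10⁵ draws for moment-convergence and MLE
recovery (recovery within 2% relative), 2×10⁴–4×10⁴ ISIs per Monte-Carlo
realization with 4–8 realizations for FF curves (agreement with the CV²
asymptote within 5–10% or 0.01–0.02 absolute), 3000-point grids over
~12 Debye lengths for the PB solver. File round-trips are lossless to
1e−12 relative (17-significant-digit CSV, full-precision JSON). KDE
normalization holds to ±1% on grids spanning the data ± 4 bandwidths.

## Known limitations

- The generator reproduces summary statistics, not waveform morphology,
  drift chemistry or any deterministic structure the true recordings may
  contain; conclusions about real data from these tests are limited
  accordingly.
- The 4.00 and 10.20 mg/ml presets carry raw-potential statistics only (no
  published spike models at those doses), so their surrogate traces are
  spike-free.
- MPP/APP semantics are an interpretation of undefined published labels.
- The transduction model is a stand-in; its parameters are not fitted to
  recordings and should not be read as physical constants of the mixture.
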