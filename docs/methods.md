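# Methods

This note documents the models and estimators implemented in `aadkit`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Event extraction and avalanche definition

Signals are z-normalized per channel with the population-SD convention over
the full record, so thresholds are in units of each channel's overall
standard deviation. An *excursion* is a maximal run of samples strictly
beyond ±h; one event is placed at the excursion's extreme sample (first
occurrence on exact ties — the tie rule is arbitrary but deterministic).
Excursions truncated by the record boundary are kept by default (dropping
them biases rates at segment edges) and can be excluded with
`drop_boundary_excursions`.

Binning uses an integer number of samples per bin so bin edges are exact;
the trailing partial bin is kept. An avalanche is a maximal run of non-empty
bins. Both size measures are always computed: `size_count` (events) and
`size_amp` (summed |amplitude| of suprathreshold samples' events, SD units);
count-based sizes suit dense arrays (wake MEG-style analyses), amplitude
sums suit sparse montages (sleep EEG-style). Avalanches touching the record
boundary are flagged as size-censored and excluded from increment pairing.

The quiet time between consecutive avalanches is the **empty-gap duration**,
(start(i+1) − end(i) − 1)·ε — the period containing no events — not the
start-to-start distance. The convention is isolated in `quiet_times` so the
alternative can be audited.

Note one subtlety found by property testing: the event *count* is not
monotone in the threshold. Raising h can split a single excursion into two
(when an interior dip falls below the higher threshold), each contributing
an event. What does hold is nesting: every event found at a higher
threshold is suprathreshold at any lower one.

## Scaling statistics

Truncated power-law exponents are estimated by maximum likelihood. On an
unbounded support the closed form α = 1 + n/Σln(x/xmin) applies; with a
finite upper bound the likelihood is maximized numerically over α ∈ (0, 50],
which admits α ≤ 1 (needed for the short-gap quiet-time regime, α ≈ 0.8).
Standard errors come from the observed Fisher information.

The power-law/exponential decision uses the normalized log-likelihood
ratio R = Σ ln[p_pl(x)/p_exp(x)] with both families MLE-fitted above xmin
and p = erfc(|R| / √(2nσ²)), σ² the variance of the per-point log ratios.
The source literature typesets this formula ambiguously ("erfc(R/2nσ)" with
σ² described as the variance of the data); the Vuong-style normalization
implemented here is the form the cited methodology defines, and the only
one that makes the statistic scale-free.

For the double power law the crossover, when not supplied, is selected on a
log-spaced grid (5th–95th percentile, 30 points) minimizing the summed KS
distances of the two truncated fits; the upper cutoff defaults to the 99th
percentile so the exponential tail region does not contaminate the fit. The
selection rule is this package's construction — the regime boundaries are
not defined operationally in the source analyses — and a crossover can
always be pinned manually.

The stretched exponential N(t) ∝ exp(−(t/τ)^β) is fitted by weighted least
squares of ln N against the model (Nelder–Mead over (ln A, β, ln τ) with
three β starts to avoid the shallow-valley local optima), weights
proportional to per-bin counts since Var[ln N̂] ≈ 1/count for Poisson bins.
Windows with very low counts carry a negative bias in ln N̂ and should be
filtered (the acceptance pipeline requires ≥ 10 counts per window).

Autocorrelation removes one global mean, divides by the global variance and
normalizes each lag by its pair count (so a perfectly periodic series has
C(period) = 1); the maximum lag defaults to n/4. Spectra are Welch-averaged
periodograms, averaged over channels; the alpha peak f(αmax) is the argmax
over a configurable 8–13 Hz band.

## The δP statistic

P(Δs<s0 | Δt<t0) uses strict inequalities on both sides, as the definition
is written; on integer sizes the s0 = 0 cell therefore measures P(Δs ≤ −1),
i.e. the probability of a strict decrease. Surrogates permute the size
sequence while keeping all start/end times (hence all quiet times) fixed;
P* and σ* are the surrogate mean and SD per cell. The default surrogate
count is 10⁴ as in the source methodology; 10³ is ample for the synthetic
calibrations and is what the tests use. Cells whose conditioning set is
empty are NaN-masked, never zero-filled, and propagate as masked.

Regime classification per t0 column: attenuation if the δP maximum over s0
is significant (> 2σ*) and sits at s0 < 0, amplification if at s0 > 0,
indeterminate otherwise. No multiple-testing correction is applied across
grid cells (the source analyses apply none); note the column maximum is an
implicit multiple comparison, so under a memoryless null a few spurious
column labels are expected even though the per-cell false-positive rate is
calibrated (≤ 5–7%).

The transition objective is the **mean** |δP| over the s0 band (default
−30…30), not the sum: masked cells are skipped and columns with different
defined-cell counts stay comparable. Ties break toward the smaller t0. A
`low_contrast` flag marks surfaces whose objective spread is within the
surrogate noise floor (e.g. the Poisson null), where t0_min is meaningless.

## Omori sequences

Elapsed time is measured from the main avalanche's **end**, and each epoch
truncates at the next main avalanche's start (the alternative — no
truncation — is a flag). Counts are pooled on logarithmic windows
w(k+1) = w(k)·10^c with w1 = 10 ms; a window contributes only for epochs
long enough to cover it fully, and the rate divides the pooled count by
window width × covering-epoch count. The decay exponent is fitted by
count-weighted least squares on the log-binned curve because the source
analyses fit N(t) directly; `omori_rate_from_times` provides the same
estimate for a raw event-time train (single epoch). Default window
fractions: c = 0.1 (wake), 0.11 (sleep).

The data collapse divides each curve's time axis by s*^q (default q = 0.5)
and scores the RMS log-distance of the curves to their pointwise mean over
the common rescaled range; lower is better, 0 is a perfect collapse.

## Phase-randomization surrogates

Per channel, the rFFT phases of all interior bins are replaced by i.i.d.
uniform draws (independent across channels, which destroys cross-channel
synchronization; a shared-phase variant preserving cross-spectra is
available for robustness checks); DC and Nyquist bins are untouched so the
inverse transform is real. No iterative amplitude adjustment is applied —
the null is plain phase randomization.

## Synthetic data: what is emulated, and what is not

The generators are **statistical stand-ins**, not biophysical models: they
reproduce the observable signatures the pipeline is designed to detect, so
that passing tests certify the estimators, not any claim about cortical
mechanism.

**Quiet times** follow a piecewise power law, density ∝ Δt^−0.79 below and
∝ Δt^−1.97 above a 100 ms crossover (continuous at the crossover, exact
inverse-CDF sampling), on [10 ms, 1 s]. The exponents are the wake-MEG
values used throughout as generating truth; the support compresses the
extreme short-gap tail and the exponential cutoff region, neither of which
carries information for the transition statistic.

**Avalanche sizes** couple to the preceding quiet time through a switched
rule motivated by the pulsed-inhibition picture:

* *Short gaps (Δt < t_switch, within an oscillation cycle).* With
  probability `q_collapse` = 0.30, and only when the source avalanche is
  large (s ≥ s_big = 70), the next size collapses multiplicatively,
  ln s → ln s − 1.1 (± 0.15 jitter): a large cascade depletes the excitable
  pool for the remainder of the cycle. Otherwise the next size is an
  independent refresh — within-cycle memory is destroyed.
* *Long gaps (Δt ≥ t_switch, across cycles).* Sizes are persistent,
  ln s(i+1) = ln s(i) + 0.12 + N(0, 0.1²): the slow amplitude envelope
  ("waxing and waning") keeps nearby-in-time avalanches at similar sizes
  with a mild upward drift — the amplification signature.

Sizes live on [10, 800], clipped at the walls and rounded to integers.
Refresh draws must match the realized size marginal, otherwise the
mismatch itself shows up in δP as a spurious signal; the construction is
therefore iterated three times, with refreshes bootstrap-resampled from the
previous pass, which makes refreshed pairs statistically indistinguishable
from size-shuffled surrogate pairs. An earlier design following a plain
sign-switched drift random walk was abandoned: on a heavy-tailed size
marginal the multiplicative drift mostly suppresses the right tail of the
increments, which moves the attenuation maximum of δP to positive s0, and
reflecting boundaries convert collapse steps near the floor into spurious
rises. The collapse/persistence/refresh rule is the simplest one found that
reproduces all of: a significant attenuation maximum at s0 < 0 for
t0 < 100 ms, a significant amplification maximum at s0 > 0 beyond the
transition, and a summed-|δP| minimum inside the reported 70–130 ms band
(it lands on the 130 ms grid point at the default parameters).

These parameters are the study conditions for the end-to-end checks and are
not tuned per test; with 5000 avalanches and 1000 surrogates the full
pattern (attenuation below 100 ms, amplification above 130 ms, t0_min ≤
130 ms) holds in ≥ 90% of seeded replicates.

**Decaying-rate processes** are exact: time rescaling with the analytically
inverted integrated rate for the Omori process (including the logarithmic
p = 1 case), thinning against the t = 0 envelope for the stretched
exponential. The stretched-exponential recovery uses a 300 s horizon at
~10⁴ events; at 30 s the (t/τ)^β lever arm is too short and the per-seed
scatter of β̂ exceeds ±0.05.

**Multichannel signals** are 1/f^0.5 Gaussian noise plus an alpha
oscillation whose amplitude follows a mean-reverting (clipped
Ornstein–Uhlenbeck) envelope shared across channels. The envelope model is
the simplest process producing seconds-scale waxing and waning; nothing
about sensor geometry, cross-channel covariance structure or non-Gaussian
artifacts is emulated. The noise background is deliberately whiter than
cortical 1/f: with strongly autocorrelated noise the *phase-randomized
surrogate* still produces bursty threshold crossings (the Gaussian process
keeps a slowly varying Rayleigh envelope), and its quiet times are then not
exponential — an instructive caveat for interpreting surrogate comparisons
on narrowband data generally.

## Problem sizes

The test suite and acceptance pipeline use: 5×10⁴ samples for exponent
recoveries, ~10⁴ events for the rate-decay recoveries, 5×10³ avalanches ×
10³ surrogates × 20 seeds for the end-to-end transition check, and 100
seeds × 10³ avalanches for the null calibration. These sizes put every
recovery comfortably inside its stated tolerance while keeping the whole
suite under a minute of compute.

## Known limitations

* The δP machinery assumes exchangeability of sizes under the null; rate
  nonstationarity (drowsiness, artifacts) violates it and inflates σ*.
* The empty-gap quiet-time convention and the end-anchored Omori epochs are
  documented choices; alternatives (start-to-start gaps, start-anchored
  epochs, non-truncated epochs) are one flag away but change exponents
  slightly.
* Channel selection is left to the caller; no sensor-geometry handling, no
  preprocessing (filtering, ICA, artifact rejection) is provided.
* The AAD generator's coupling is a stand-in; whether real Δs–Δt coupling
  is multiplicative or additive, graded or switched, cannot be decided from
  the summary statistics it emulates.
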