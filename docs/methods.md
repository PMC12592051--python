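# Methods

This note documents the models, numerical choices and known limitations of
somnoscale, in the order data flows through the package.

## Data model

An epoch is one fixed-length multichannel segment (default 60 s at
fs = 200 Hz, N = 12,000 samples per channel) labelled with one of four
vigilance states {W, N2, N3, R}; other labels are rejected rather than
coerced. Samples are stored channel-major. Channels carry an optional
anatomical assignment into a packaged taxonomy of 38 brain regions grouped
into six lobes (occipital, parietal, insular, medial frontal, lateral
frontal, temporal); the taxonomy validates region/lobe pairs at load time
and is the join key for all regional aggregation. Longer records are sliced
into non-overlapping epochs aligned to record start, which keeps
segmentation deterministic; trailing partial epochs are dropped with a
warning.

EDF files are read through mne; because EDF labels cannot carry the
region taxonomy, the channel → (patient, region) mapping travels in a plain
key:value sidecar file. EDFs with heterogeneous per-channel sampling rates
are refused outright (mne would silently resample them). The columnar TSV
format plus the same sidecar is the round-trippable interchange format used
by the synthetic generators.

## Spectral stage

`periodogram` is a single-segment, demeaned, unwindowed one-sided estimate
scaled so the power bins sum to the signal variance (discrete Parseval),
which makes it self-checking. `welch_psd` uses Hann-tapered, segment-wise
demeaned, 50 %-overlapping segments (defaults 600 samples → 0.333 Hz
resolution, 39 segments per 60 s epoch) with one-sided density
normalization. The taper choice is conventional; only "a non-rectangular
window" is required by the procedure the package implements, and Hann is the
default a practitioner would pick.

`normalize_by_mean` divides each PSD by the pooled across-epoch mean at each
frequency, so the pooled mean of the outputs is exactly 1 everywhere; this
emphasizes relative shifts and crossover points between conditions and is
scale-free by construction.

The five-Gaussian band decomposition fits log10 power against linear
frequency on the 0.7–75 Hz grid. The log domain balances the
order-of-magnitude dominance of delta over gamma so a single R² threshold is
meaningful; whether a reference implementation fits linear or log power is
not fixed by the procedure, so the log-domain choice is recorded here as
this package's decision. No additive aperiodic baseline term is included:
the model presumes spectra expressed relative to a reference level (e.g.
after `normalize_by_mean`), and the acceptance flag (R² ≥ 0.95) reports when
that presumption fails — a flat spectrum yields a degenerate R² and is
flagged rather than accepted. Constraints: amplitudes ≥ 0, each center
box-constrained to its band, σ ∈ [0.2 Hz, band width]. Fitting is
trust-region nonlinear least squares with multi-start initialization
(centers at band midpoints with amplitudes read off the smoothed spectrum,
plus four seeded jittered restarts); the best R² wins, ties broken by the
smallest total σ. Savitzky–Golay smoothing defaults to an 11-bin window of
order 3, exposed in config.

## Avalanche stage

Event semantics: one event per negative-going crossing of the −2.0 SD
threshold (sample i with z[i] < θ and z[i−1] ≥ θ; a sub-threshold start
counts once at index 0) — not one event per sub-threshold sample. This keeps
the mean activity per active bin in the ~1.3–1.6 range typical of sparse
crossing events on 16-channel rasters. Inputs must already be z-scored;
channels off by more than 1e-3 in mean or SD are rejected with the channel
named.

Binning pools events over channels into consecutive non-overlapping windows
(default 10 ms = 2 samples at 200 Hz; the bin must be an integer number of
samples). Avalanches are maximal runs of active bins bounded by empty bins;
runs touching the record edges are retained but flagged, since 60 s epochs
make boundary effects negligible. Sizes conserve events exactly
(Σ sizes = Σ counts), which the tests exploit as an invariant.

The discrete power law P(x) = x^−τ / ζ(τ, x_min) is fitted by numerical
likelihood maximization (bounded scalar minimization of the per-observation
negative log-likelihood; the Hurwitz zeta comes from scipy). The
exponentially truncated variant P(x) ∝ x^−τ e^−λx is fitted jointly over
(τ, λ ≥ 0) with the normalizing sum evaluated by blockwise summation with an
overflow guard; the pure power law is the default model and the truncated
one is opt-in. The exponent's standard error is the observed Fisher
information (numerical second derivative of the total negative
log-likelihood); a seeded bootstrap is unnecessary at the tail sizes the
pipeline produces and was left out. The KS distance is the sup-distance
between the empirical and fitted CDFs over the observed tail, checked at
each observed value and just below it; for the pure model the fitted CDF is
computed from zeta ratios so no support array is materialized (observed
tails can span many decades). x_min defaults to 3 for both sizes and
durations; whether the duration distribution should share the size cutoff is
genuinely open, so both are exposed in config.

Size–duration scaling regresses log10⟨s⟩ on log10 T by OLS over distinct
durations (default: every duration with at least one avalanche enters; a
`min_per_duration` filter is available). The crackling check reports
γ_pred = (α − 1)/(τ − 1), the discrepancy from the directly fitted γ, and
whether γ_pred lies in the 1.10–1.40 reference band spanned by deep sleep
(N3) and wakefulness.

Channel subsetting for cross-patient comparability draws a uniform random
subset of exactly k = 16 channels per patient (deterministic given the seed;
patients with fewer channels are excluded), with the per-patient seed
derived from the global run seed by a CRC of the patient id so reruns are
byte-identical.

The sensitivity sweep reruns detect → bin → extract → fit over the full
factorial grid of bin widths {10, 15, 20} ms × thresholds
{−2.2, −2.0, −1.8} SD, tabulating τ, α, mean activity and avalanche counts;
failed cells are flagged and the sweep continues.

## DFA stage

The profile is the cumulative sum of the demeaned signal. Window sizes are
30 log-spaced integers from 4 samples to the signal length (the grid density
is this package's default; 30 gives ~15 scales inside the fit range at the
default epoch geometry). At each size, consecutive windows with 50 % overlap
(hop = ⌊w/2⌋, trailing partial window dropped, no reverse pass) are linearly
detrended by closed-form least squares; F is the RMS of the squared
residuals pooled across all windows and points. Pooling is equivalent to the
per-window average of variances when windows share a length and is
numerically simpler; that interpretation of the fluctuation average is
recorded here as a design decision. α is the OLS slope of log10 F versus
log10 window size restricted to 0.04–2.5 s (8–500 samples at 200 Hz,
endpoints inclusive after conversion to samples), with the slope's standard
error reported. Scales with F = 0 are dropped with a warning (they arise
only for exactly linear profiles).

Regime labels: |α − 0.5| ≤ 0.02 is called uncorrelated; below that band
anticorrelated; (0.5, 1] correlated (stationary long-range temporal
correlations); above 1 non-stationary. The 0.02 half-width is a pragmatic
convention — the underlying classification names only the exact point
α = 0.5 and open intervals.

Detrending is strictly linear (first order); higher-order DFA and crossover
estimation are out of scope.

## Synthetic data

The generators produce the statistical structure each stage assumes, with
seeds fully determining output:

* white noise, random walks (cumulative white noise; differencing recovers
  the white sequence), and fractional Gaussian noise by exact circulant
  embedding (Davies–Harte): the fGn autocovariance
  γ(k) = ½(|k+1|^2H − 2|k|^2H + |k−1|^2H) is embedded in a circulant of
  order 2(N−1) whose FFT eigenvalues are non-negative for H ∈ (0, 1) up to
  rounding (tiny negatives are clipped; a genuinely indefinite embedding
  raises). Exact synthesis was chosen over spectral approximations because
  the DFA calibration (α̂ ≈ H within 0.1) demands unbiased covariance.
* spectral mixtures: a target one-sided log10 PSD (1/f^β background plus
  Gaussian bumps in log power) is inverse-transformed with seeded uniform
  random phases, so the periodogram of the output matches the target shape
  and the band-fit stage has exact ground truth.
* branching rasters: repeated Galton–Watson cascades (each event spawns
  Poisson(m_b) offspring in the next bin on uniformly random channels),
  separated by a configurable number of empty bins so ground-truth avalanche
  boundaries are exact. At m_b = 1 the size distribution approaches the
  mean-field s^−3/2 law and durations T^−2. A size cap (default 10⁴ events)
  guards against runaway supercritical cascades; capped cascades are counted
  and warned about. Cascade-separated generation (rather than a continuously
  driven process) was chosen precisely so that extraction can be verified
  exactly; the binned counts are the ground truth, and the binary raster
  placement onto (channel, sample-in-bin) slots can saturate at high
  densities (warned, counts unaffected).
* discrete power-law samples by exact inverse CDF: a tabulated CDF over the
  first 10⁵ support points plus zeta-ratio bisection for the rare draws
  beyond the table, so the sampler is exact over the whole support and
  serves as independent ground truth for the MLE.
* raster embedding: each channel is unit-variance Gaussian noise low-pass
  smoothed with a 50-sample (0.25 s) Gaussian kernel — mimicking the
  slow-wave-dominated background of sleep iEEG, in which spontaneous −2 SD
  down-crossings are rare — with a one-sample deflection to −3.5 noise-SD at
  each event. Single-sample pulses avoid multiplying crossings. After
  z-scoring, pulse depth shrinks with planted-event density (the events
  contribute variance), so very dense rasters push pulses back above the
  threshold; the `spacing_bins` knob of the branching generator exists to
  keep embedded densities in the regime the detector assumes (a few percent
  of samples).

What the generators deliberately do not emulate: volume conduction,
electrode geometry, non-Gaussian artifacts, sleep-stage transitions within
an epoch, or biophysically realistic oscillations. Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not performance on clinical recordings.

## Statistics

Mann–Whitney U tests are two-sided and unpaired everywhere: channel sets
differ across vigilance states, so pairing is not generally well defined.
Exact enumeration is used when both groups have n ≤ 8 without ties,
otherwise the tie-corrected normal approximation. BH-FDR is the step-up
procedure (via statsmodels), applied within each comparison family — the
band × lobe grid for spectral amplitudes, the lobe set for DFA exponents —
rather than across all tests at once. One-way ANOVA attaches per-group
Shapiro–Wilk p-values and a Levene (center = median) p-value, flagging
violations at p ≤ 0.05. −log10(p) values are capped at 320 to keep tabular
output finite. Channels are the unit of analysis for lobe-level tests,
matching the per-channel granularity of the metrics tables.

The a(b) notation rounds the standard error to one significant digit and
prints it in units of the value's last digit (0.84 ± 0.02 → "0.84(2)");
`parse_ab` inverts it at printed precision.

## Pipeline and problem sizes

`run_pipeline` executes the requested stages per epoch/channel, pools
avalanche statistics per (patient, state) with the ≥ 16-channel rule, and
emits one long/tidy metrics table (one metric per row) plus contrast and
sweep tables. All randomness derives from the single run seed; identical
config and inputs give byte-identical outputs, which the tests check
directly. Default contrast families are W vs R and N2 vs N3; other pairs are
configurable.

The test suite and acceptance script run entirely on synthetic inputs at
desk scale: 20 epochs of 12,000 samples per DFA calibration class, 100
replicates of n = 10⁴ per power-law recovery setting, and 10⁵ cascades for
the critical-branching recovery — sizes chosen so each check has clear
statistical resolution while the whole suite completes in well under a
minute per stage on one CPU. Cohort-level empirical exponents from clinical
recordings are outside what synthetic calibration can certify.

## Known limitations

* The five-Gaussian model has no aperiodic (1/f-exponent) term; strongly
  sloped raw spectra will be rejected by the R² rule unless normalized
  first. Aperiodic/periodic decomposition is deliberately out of scope.
* The duration-exponent MLE at x_min = 3 is sensitive to the strong
  small-T curvature of near-critical cascade distributions; it recovers the
  asymptotic slope only as x_min grows. The crackling check reports the
  discrepancy rather than hiding it.
* DFA is first-order only; no multifractal extension, no crossover
  estimation.
* Amplitude-weighted avalanche sizes, likelihood-ratio comparisons against
  lognormal alternatives, and avalanche shape collapse are not implemented.
* EDF writing is not supported (read-only); columnar TSV is the write path.
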