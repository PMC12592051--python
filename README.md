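# somnoscale

Multiscale analysis of intracranial EEG (iEEG) across sleep–wake states.

Sleep reorganizes brain dynamics on every timescale: slow delta oscillations
and 12–15 Hz spindles appear in NREM sleep, cascades of population activity
("neuronal avalanches") grow larger and longer, and the temporal memory of
the signal — its long-range temporal correlations — strengthens. This
package implements the three complementary measurements that capture those
changes in 60-second iEEG epochs labelled with a vigilance state
(wakefulness W, NREM stages N2/N3, REM R), together with the statistics
needed to compare states and a synthetic-signal module that makes every
stage testable without clinical data. It is aimed at computational
neuroscientists and sleep researchers working with multichannel
electrophysiology.

## What it computes

**Spectral band structure.** Welch power spectral densities (600-sample Hann
windows, 50 % overlap at fs = 200 Hz), optionally normalized by the
across-epoch mean at each frequency, are smoothed with a Savitzky–Golay
filter and decomposed over 0.7–75 Hz as a sum of five Gaussians in log10
power — one per canonical band: delta (0.7–4 Hz), theta (4–8), alpha (8–12),
beta (12–30), gamma (30–75). Each component has free amplitude A, center c
and width σ:

    log10 P(f) ≈ Σᵢ Aᵢ exp(−(f − cᵢ)² / (2σᵢ²)),   i ∈ {δ, θ, α, β, γ}

and a fit is accepted only when R² ≥ 0.95.

**Neuronal avalanches.** Each channel is z-scored; a discrete event is a
negative-going crossing of −2.0 SD; events are pooled into 10 ms bins; an
avalanche is a maximal run of active bins bounded by empty bins, with size
*s* (total events) and duration *T* (bins). Size and duration distributions
P(s) ∝ s^−τ and P(T) ∝ T^−α are fitted by a discrete maximum-likelihood
power law with Hurwitz-zeta normalization on {x_min, x_min+1, …}, x_min = 3,
optionally with an exponential cutoff P(x) ∝ x^−τ e^−λx. Goodness of fit is
the Kolmogorov–Smirnov distance over the fitted tail. The mean size per
duration gives the scaling exponent γ via ⟨s⟩(T) ∝ T^γ, and the
crackling-noise relation α = 1 + (τ − 1)γ ties the three exponents together
as a consistency check.

**Detrended fluctuation analysis (DFA).** The cumulative sum of the demeaned
signal is divided into 50 %-overlapping windows of log-spaced sizes, each
window is linearly detrended, and the scaling exponent α is the log–log
slope of the pooled residual RMS versus window size over 0.04–2.5 s.
α = 0.5 marks uncorrelated noise, 0.5 < α < 1 stationary long-range temporal
correlations, α > 1 non-stationary integrated dynamics. For stationary
fractional Gaussian noise, DFA α equals the Hurst exponent H.

**Group statistics.** Two-sided unpaired Mann–Whitney U tests with
Benjamini–Hochberg FDR control within each comparison family (band × lobe
for spectra, lobe for DFA), one-way ANOVA with Shapiro–Wilk and Levene
assumption checks, and the compact a(b) uncertainty notation (0.84(2) means
0.84 ± 0.02).

## Worked example

```python
from somnoscale import synthetic as syn, avalanches as av
from somnoscale.dfa import DetrendedFluctuationAnalysis
from somnoscale.recordings import zscore

# long-range temporal correlations of a persistent signal (H = 0.8)
x = syn.gen_fgn(0.8, 12000, seed=42)        # 60 s at 200 Hz
print(DetrendedFluctuationAnalysis(x, fs=200.0).fit().summary())

# avalanche statistics of a critical branching raster embedded in noise
sim = syn.gen_branching_raster(n_channels=16, m_b=1.0, cascades=4000,
                               seed=0, size_cap=200, spacing_bins=10)
epoch = syn.raster_to_signal(sim.raster, seed=1)
raster = av.detect_events(zscore(epoch), threshold_sd=-2.0)
avalanches = av.extract_avalanches(av.bin_raster(raster, bin_ms=10))
print(av.fit_power_law([a.size for a in avalanches]).summary())
```

prints

```
Detrended fluctuation analysis
  alpha     = 0.808(5)  (OLS on log10 F vs log10 dt)
  fit range = 0.04-2.5 s (15 scales)
  regime    = correlated

discrete power law (maximum likelihood)
  exponent  = 1.60(1)   (SE 0.01332, Fisher information)
  xmin      = 3
  n >= xmin = 2020
  KS        = 0.0826
```

The DFA exponent 0.808 recovers the generating Hurst exponent 0.8, in the
stationary correlated regime. The avalanche size exponent 1.60(1) sits near
the mean-field value 3/2 expected for a critical branching process (the
residual excess reflects the finite raster and the detection chain), with
the a(b) form giving one standard error in the last digit.

The same machinery runs from the shell: `somnoscale simulate` writes
synthetic columnar epochs, and `somnoscale run --seed 0 --out results/ …`
executes the configured stages (psd, bands, avalanche, dfa, stats, sweep)
over EDF or columnar inputs, producing tidy TSV tables keyed by patient,
state, channel, region and lobe (regions follow the packaged 38-region,
six-lobe taxonomy).

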