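# Methods

This note documents the models implemented in `ear2cortex`, the choices
made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Cochlear front ends

A cochleagram is computed in three stages.

**Frequency decomposition.** The waveform is framed into 20-ms Hann
windows advanced in 10-ms hops (one output bin per hop, final frames
zero-padded) and Fourier transformed. The 20 ms / 10 ms default matches
the binning regime used in cortical encoding-model work and keeps 25-ms
chord stimuli resolvable; both are configurable. In amplitude mode the
magnitude spectrogram is used, in power mode its square.

**Response integration.** FFT bins are pooled by overlapping triangular
filters whose centers are geometrically spaced between `f_min` (500 Hz)
and `f_max` (22 627 Hz — a 5.5-octave span covering ferret A1 tuning).
Channel *i*'s triangle rises from center *i − 1* to center *i* and falls
to center *i + 1*; virtual edge centers sit one geometric step beyond
the band so all `n_channels` triangles have full support. A
configuration error is raised if any triangle captures no FFT bin
(too many channels for the FFT resolution).

**Compression.** Five pointwise variants, all monotone nondecreasing:

| model | spectrogram | compression |
|---|---|---|
| spec-lin | amplitude | identity |
| spec-log | amplitude | `log(max(x, θ))` |
| spec-log1plus | amplitude | `log(1 + x/s)` |
| spec-power | power | `log(max(x, θ))` |
| spec-Hill | power | thresholded log, then `r^h/(r^h + k^h)` |

The floor θ is resolved per stimulus corpus: 60 dB below the corpus
peak in amplitude mode, 120 dB in power mode (a single dB-relative
parameter; the resolved absolute value is recorded in the cochleagram
provenance). For spec-Hill the thresholded-log output is min-max
rescaled to [0, 1] over the corpus before the Hill stage, so the
half-max `k` and exponent `h` are unit-scaled and corpus-independent;
the rescaling constants are likewise stored in provenance.

**Multithreshold model.** Auditory nerve fibers tuned to the same
frequency come in three spontaneous-rate classes differing in threshold
and dynamic range. The multithreshold front end emulates this by
passing every frequency channel through three Hill functions with
thresholds 60/40/20 dB below the corpus peak. Each class saturates
within its own level range: the low-threshold (HSR-like) class has a
steep, narrow dynamic range just above its threshold (half-max 0.2,
exponent 4), the high-threshold (LSR-like) class a shallow, wide one
(half-max 0.6, exponent 1). Output blocks are stacked low → medium →
high threshold with frequencies ascending within each block, giving
3 × `n_channels` rows. Three identical triples degenerate to an exact
triplication of the single-threshold model — a tested invariant.

Biologically detailed cochlear models (transmission-line filterbanks,
hair-cell/synapse dynamics, adaptive gain control) are deliberately out
of scope; a plugin contract (`PluginFrontEnd`) accepts any callable
`(samples, sample_rate, n_channels) → (values, center_freqs, bin_ms)`,
averaging a declared number of repeats for stochastic providers.

## Encoding models

All models regress the firing rate at bin *t* on the cochleagram over
the preceding 200 ms (20 lags of 10-ms bins — long enough for an
excitatory field plus its lagging inhibitory field; configurable). The
first 800 ms of each stimulus are flagged as onset and excluded from
fitting and scoring by default (an include-onset switch exists). Spike
counts are converted to spike probability per bin by averaging over
repeats.

**Linear (STRF).** Mean squared error plus an L1 penalty on the weights
(bias unpenalized), solved by coordinate descent (scikit-learn `Lasso`;
the package objective `MSE + λ·Σ|w|` maps to `alpha = λ/2`). The
penalty is chosen by 8-fold cross-validation with folds formed from
*contiguous stimulus blocks* (2 snippets per fold for 16 training
snippets), never shuffled bins, to avoid temporal leakage across
autocorrelated samples. The default penalty grid descends three decades
geometrically from half the critical penalty `λ_max = 2·max|Xᵀy|/n`;
the selected value maximizes mean held-out prediction correlation, ties
breaking toward the sparser model. Per-fold Gram matrices depend only
on the design, so one fold cache serves every unit recorded with the
same stimuli — this is what makes population fits fast.

**Linear–nonlinear (LN).** The STRF is fitted first; a 4-parameter
logistic `y = a + b/(1 + exp(−(x − c)/d))` is then least-squares fitted
to the frozen linear drive (no joint refinement). Constraints `a ≥ 0`
(nonnegative rates) and `b ≥ 0, d > 0` (resolving the (b, d) sign
symmetry). Fitting is multi-start over drive quantiles and slopes, with
a near-affine start covering the locally-linear regime; a constant
drive or rate yields a flat sigmoid flagged degenerate, and
non-convergence falls back to an identity-like affine sigmoid with
`converged=False`. Note one consequence of `a ≥ 0`: for responses whose
range touches zero the sigmoid cannot be exactly affine, so the
"identity" regime is only approached over the central drive range.

**Network receptive field (NRF).** A single-hidden-layer network with
sigmoid units at both layers, inputs standardized per feature. The
penalized MSE (L1 on the input-layer weights only, smoothed as
`sqrt(w² + ε)` for differentiability) is minimized by L-BFGS in chunks
of 10 iterations; after each chunk the MSE on a held-out tail (20% of
training rows) is evaluated and the best-so-far parameters kept,
stopping after 5 stale chunks. Fits are bit-reproducible given the
seed. Default 20 hidden units; tests and the acceptance script use 10
with a 150-iteration budget, which reaches within a few thousandths of
the larger configuration on the synthetic populations at a fraction of
the cost.

## Evaluation

With `r_n` the *n*-th of *N* repeats (variances `ddof=1`):

    TP = mean_n Var(r_n)
    SP = (Var(Σ_n r_n) − Σ_n Var(r_n)) / (N(N−1))
    NP = TP − SP
    CC_norm = Cov(ȳ, ŷ) / sqrt(SP · Var(ŷ))
    NR = NP / SP

`SP + NP = TP` holds by construction. CC_norm equals the raw Pearson
correlation when repeats are identical, is invariant to positive affine
transformations of the prediction, and can exceed 1 by sampling noise
when SP is small. Units with SP ≤ 0 get NR = ∞ and are excluded by the
inclusion filter (strictly `NR < 40` by default) regardless of
threshold. Constant predictions or responses score 0 with a warning
rather than propagating NaNs into population means.

STRF characterization: best frequency and latency are the (channel,
lag) of the largest positive weight; the IE score is the ratio of total
negative to total positive weight mass — the absolute-sum ratio, which
is also the definition the ground-truth generator targets.
STRF similarity is the Pearson correlation of flattened weight
matrices, optionally after Gaussian blurring (σ in channels/bins) to
absorb small frequency or temporal shifts.

## Synthetic benchmark

The generator emulates the *structure* of a natural-sound recording
session — 20 five-second snippets, multi-repeat responses binned at the
cochleagram resolution, a 16/4 stimulus split — with two stimulus
families: amplitude-modulated noise (white noise × positive < 20 Hz
envelope, standing in for the slow modulation of natural sounds) and
random chord sequences (24 log-spaced tones, level drawn uniformly over
40 dB per tone per 25-ms hop, 2-ms cross-fades). It does **not**
emulate the higher-order statistics of real natural sounds, cortical
adaptation or gain control, non-Poisson spiking, or anesthetic state —
so passing tests certify the correctness and identifiability of the
pipeline, not biological performance levels.

Each unit is an LN neuron: Gaussian excitatory blob (BF log-uniform
over the central channels, latency 10–40 ms, bandwidth 0.3–0.8 octaves)
minus a delayed inhibitory blob scaled by root finding to hit the
requested IE score; sigmoid midpoint at the 75th percentile of the
unit's drive distribution with width 0.15 of the drive s.d. (sparse,
peaky responses); independent Poisson counts per repeat. Under Poisson
spiking the expected noise ratio is `mean(r)/Var(r)` of the rate trace,
so the rate gain that hits a requested NR has the closed form
`g = mean/(Var · NR)` — the noise dial used to build populations
straddling the NR = 40 inclusion threshold exactly.

**Identifiability of the compression comparison.** On units generated
through a purely logarithmic front end, an LN model reading the
*uncompressed* front end can absorb much of the missing compression
into its output sigmoid under these stimuli — the two model classes
nearly coincide, and the comparison carries no signal. The benchmark
therefore runs the compression comparison on spec-Hill-generated
units: there the saturation acts per channel *before* the linear
summation, which no output nonlinearity after the sum can mimic, and
the matched front end wins decisively for essentially every unit.

## Problem sizes

The acceptance tests fit 20 units on 400 s of stimulus (80 × 5-s
snippets, 64/16 split) at NR ≈ 5 — large enough that the median
fitted-vs-true STRF correlation and held-out CC_norm are stable
population statistics. The acceptance script reruns the full pipeline
at 12 units / 120 s, which reproduces the same statistics to within a
few hundredths in minutes. Degenerate inputs (silent corpora, constant
drives, all-negative STRFs, single repeats) are handled by explicit
flags or errors as described above rather than by silent NaNs.

## Known limitations

* Absolute CC_norm levels reported for real cortical recordings are
  properties of datasets this package does not ship; nothing here
  claims to reproduce them. The package establishes *directions*
  (compression helps; LN ≥ linear; NRF ≈ ≥ LN; the multithreshold
  representation carries level information) on ground-truth data.
* The compression-stage constants (θ, log1plus scale, Hill parameters,
  window lengths) have no canonical published values; the
  corpus-relative defaults above are explicit choices and are recorded
  in every cochleagram's provenance.
* The spec-Hill corpus rescaling makes compressed values depend weakly
  on the corpus via its peak and floor; provenance carries the
  constants so any cochleagram is reproducible, but cochleagrams of the
  same sound under different corpora differ by design.
* No gain control, adaptation, or joint L+N optimization; no multi-layer
  networks; no spike-train-level metrics.
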