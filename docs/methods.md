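# Methods

`earlyvis` models the first stages of the primate visual pathway — retina,
lateral geniculate nucleus (LGN), primary visual cortex (V1) — as three
alternative encoding schemes trained on the same stream of naturalistic
image patches, and measures how the resulting populations compare to
reference physiology. This note records the models, the estimators, the
synthetic data, and the design choices made where the design was genuinely
open.

## Geometry and data

All experiments use a 20°×20° field of view sampled at 5 px/°
(100×100 px images) and 3°×3° patches (15×15 px, 225 pixels). Training
uses 10⁵ patches sampled uniformly at random with replacement (overlap
allowed); the identical patch sequence is fed to all three models.

### Synthetic naturalistic surrogate

Two generators stand in for natural scenes:

* `gen_pink_noise_images` — random-phase images with amplitude spectrum
  ∝ 1/f^γ (γ = 1 by default), the canonical second-order statistic of
  natural scenes. Each image is standardised to zero mean, unit variance.
* `gen_natural_surrogate_images` (pipeline default) — the same 1/f
  background (35% weight) plus a sparse set of random Gabor components
  (0.5 per square degree; Laplacian amplitudes; random position,
  orientation, frequency 0.4–2 c/°, aspect 1–3). A purely Gaussian 1/f
  process has zero negentropy, so ICA has no axis to find and sparse coding
  stays PCA-like; the sparse component layer supplies the higher-order
  structure (edges, contours) that drives generative encoders toward
  localised oriented filters, which is the phenomenon the package measures.

What the surrogate does *not* emulate: occlusion and phase alignment across
scales, luminance/contrast nonstationarity, and the full heavy-tailed
wavelet statistics of real scenes. Consequently model populations trained
on it are *qualitatively* like those trained on photographic datasets
(STDP compact/blobby; ICA and SC oriented and elongated) but the exact
population fractions and divergences differ from runs on real image sets.
Tests passing on the surrogate validate the machinery and the orderings,
not photographic-data numbers. With a directory of real images
(`data.source: image-directory`) the identical pipeline runs unchanged.

A surrogate reference table stands in for macaque single-cell data:
truncated Gaussian mixtures over receptive-field shape vectors
(`gen_reference_sample("fsv")`) and tuning bandwidth (`"bandwidth"`). The
mixture parameters were fixed once to emulate published macaque V1
summaries — roughly 59% of shape vectors inside the [0, 0.5)² square, and
a bandwidth density peaking near 19° with a broad tail. External tables
(CSV) load through the same `ReferenceSample` type with provenance
`external-file`.

## The three encoders

### Sparse coding (SC)

Whitening front end: zero-phase filter H(f) = f·exp(−(f/f₀)⁴) with
f₀ = 10 c/°, applied to whole images in the frequency domain before patch
extraction. At 5 px/° the Nyquist limit is 2.5 c/°, so the high-frequency
trimming term is essentially inert; the filter is implemented exactly as
defined. The DC gain is zero.

The model is the classical energy formulation: patch x ≈ A a with
E(a) = ½‖x − Aa‖² + λ Σᵢ S(aᵢ), S(u) = log(1+u²). Inference is gradient
descent with step 1/L (L = ‖A‖₂² + 2λ), which makes the energy
non-increasing; divergence (five consecutive increases) raises an error.
Learning takes batched gradient steps on the reconstruction error with a
multiplicative per-basis gain adaptation (rate 0.02 on the log-gain)
that equalises coefficient variances; the learning rate halves every
quarter of training.

Two λ values play different roles:

* **Reconstruction / RF recovery:** λ = 0.14·σ with σ² the input-dataset
  variance, entering the linear-stability reverse-correlation formula
  ξ = A[AᵀA + λS″(0)I]⁻¹ with S″(0) = 2.
* **Learning:** λ = 0.8·σ by default. With λ = 0.14·σ the inferred
  coefficients sit in the quadratic region of log(1+x²) (|a| ≪ 1 after
  gain adaptation), the prior acts as ridge rather than sparsity, and the
  basis converges to a PCA-like rotation with no Gabor-like structure
  (verified empirically: zero units with Gabor R² ≥ 0.5). The stronger
  learning prior keeps coefficients in the sparsifying regime; it is
  configurable (`sc_learn(lam=...)`).

The coefficient-variance target of the gain adaptation defaults to the
input variance for the same reason — coefficients of order σ engage the
non-quadratic part of the prior.

### ICA

Front end: truncated PCA of centred patches, L = Ũᵀ(X − ⟨X⟩) with
d = 150 components. The projection is variance-normalised inside
`ica_fit`; a square un-mixing matrix W is then estimated by fixed-point
negentropy maximisation (fastICA, symmetric orthogonalisation, log-cosh
contrast, tol 1e−4, max 200 iterations; cube contrast optional).
Non-convergence is flagged on the model, not raised — on Gaussian input
there is nothing to converge to. Activity is Σ = WL; receptive fields are
ξ = ŨWᵀ + ⟨X⟩, each column sign-flipped so its maximum-|·| pixel is
positive (fit/display stability; for RF-shape analysis the mean term is
omitted by default because the filter, not the dataset mean, carries the
shape). The fastICA step itself is delegated to scikit-learn's
implementation behind this module's surface.

### Rank-order STDP

Front end: difference-of-Gaussians centre–surround filtering (centre
σ = 0.2° = 1 px, surround 3× centre, kernel zero-sum and unit L2 norm;
symmetric boundary padding so constant input is exactly silent), half-wave
rectified into ON and OFF channels, converted to first-spike latencies by
t = 1/r. Only the earliest ⌈10%⌉ of afferent spikes propagate; latency
ties break by afferent index. The code is a pure rank code — any
monotonically decreasing latency map gives identical behaviour, and the
rank order is exactly invariant to global contrast scaling.

**Afferent count.** The network has 225 neurons × 225 afferents = 50,625
plastic weights in the default *merged-polarity* mode: one afferent per
pixel carrying the rectified magnitude of the DoG response (at each pixel
only one polarity is active at a time). For retinal-space RF read-out,
ξ = Σᵢ wᵢψᵢ, the kernel of afferent i is signed by the polarity that
afferent predominantly conveyed to that neuron during learning (a signed
tally of causal-spike DoG responses, accumulated per neuron × afferent). A
*split-polarity* mode (450 afferents, OFF kernels entering negatively)
is available and needs no polarity tally.

**Dynamics.** Each neuron accumulates its afferent weight at every
propagated spike in latency order and fires at the first crossing of θ
(integration then stops). During learning a winner-take-all rule applies:
the earliest-firing neuron (ties → lowest id) alone updates,

* LTP, afferents whose spike arrived at or before the winner's crossing:
  Δw = α⁺(w_max−w)^μ⁺,
* LTD, every other afferent (later spikes and silent ones — the
  depression window is unbounded): Δw = −α⁻(w−w_min)^μ⁻,

with α⁺ = 5×10⁻³, α⁻ = 0.75α⁺, μ⁺ = 0.65, μ⁻ = 0.05, bounds (0, 1). At
w = 0.5 these give +3.19×10⁻³ and −3.62×10⁻³. Because the update is a
discrete step of a continuous soft-bound rule, a raw LTD step can
overshoot w_min for weights within ~3×10⁻³ of it; steps are capped at
half the remaining distance to the bound (plus a 10⁻¹² open-interval
clamp against float rounding), which leaves the rule untouched everywhere
else and keeps all weights strictly inside (0, 1) indefinitely.

**Training threshold.** θ is not part of the rule and must be calibrated.
Default: an untrained neuron (mean weight ½) should cross after ~60% of
the propagated spikes, θ = 0.6 × 0.5 × ⌈0.1·n_afferents⌉ ≈ 6.9 at the
default geometry. The value is configurable and logged. Training raises an
explicit error if no neuron fires for 1,000 consecutive patches.

**Testing.** After convergence inhibition is off; every neuron integrates
independently against θ_test = θ_train(1+s) for a threshold scale s.
Because weights are non-negative, a neuron fires iff its total propagated
drive reaches θ_test — the threshold sweep therefore thresholds one cached
potential pass per stimulus for all seven scales, which is exact and ~7×
faster than re-simulation.

## Measurement suite

### Gabor fits and shape vectors

Receptive fields are fitted with 9-parameter 2-D Gabors (centre,
orientation, carrier frequency, phase, σx along carrier propagation,
σy along the stripes, amplitude, offset) by bounded nonlinear least
squares. Initialisation: carrier frequency and orientation from the
windowed FFT peak, centre from the energy centroid, four carrier-phase
starts plus seeded jitters; best residual wins. R² = 1 − SS_res/SS_tot.
Equivalent parameterisations (±amplitude with phase+180°; θ+180° with
negated phase) are reduced to a canonical form with θ ∈ [0°, 180°) and
positive amplitude. On 200 random noiseless Gabors the fitter recovers
all parameters within 5% in ≥98% of cases (typically 100%).

The frequency-normalised spread vector is [n_x, n_y] = [σx, σy]·f: n_x
tracks lobe count, n_y elongation, and the pair is invariant to
translation, rotation and isotropic rescaling. Population summaries use
the fraction strictly inside the square n_x < 0.5 and n_y < 0.5. Units
with R² < 0.5 are excluded from population shape summaries (threshold
configurable); a Gabor parameter read off a non-Gabor map is noise.

### Orientation tuning

Noisy sine-wave gratings at the unit's preferred frequency (carrier of
its Gabor fit, clamped to Nyquist), orientation 0–178° in 2° steps,
responses averaged over phases 0–355° in 5° steps, at 0 dB SNR.
Bandwidth is the half-width at half the peak response with linear
interpolation between sampled orientations, circular over the 180°
period, capped at 90°; 95% CIs by percentile bootstrap (1,000 resamples)
over 100 repetitions. A curve whose modulation depth is below 5% of its
peak is declared flat (undefined bandwidth) — pixelated stimuli give even
untuned units a few percent of ripple. Responders: ICA/SC units use the
half-wave-rectified linear filter response (the raw linear response
averages to ~0 over phase); STDP uses the threshold-free membrane
potential so the comparison is threshold-independent.

### Fisher information

Population FI with respect to orientation (radians) under unit
independence: per unit, the response distribution at each orientation is
estimated across repetitions (categorical when the response takes ≤16
distinct values — spike indicators, phase-averaged spike counts —
otherwise 8 equal-mass bins pooled over orientations); bin probabilities
are differentiated by central finite differences on the 4° grid with
circular wrap, and J(θ) = Σ_units Σ_bins (∂P/∂θ)²/P. Cells with zero
probability and zero derivative contribute 0. The finite-difference
numerator carries a positive sampling bias of order Var(P̂)/(2h)²; the
estimator subtracts this multinomial-variance term (signed, with J
clipped at 0 per orientation afterwards), which brings it within ~6% of
the closed-form Poisson value at 1,000 repetitions where the raw
estimator errs by ~30%. 95% CIs by leave-one-repetition-out jackknife.
Stimuli: gratings at 1.25 c/°, orientations 0–176° in 4° steps, 8 phases
averaged, SNR −6…+6 dB in 1 dB steps, 100 repetitions.

### Decoding

One-vs-all linear discriminant classifiers over the 45 orientation
classes (error-correcting output-code style prediction by maximum
decision value), 5-fold stratified cross-validation reshuffled per
repetition, accuracy CIs by jackknife over repetitions. Chance is 1/45.

### KL divergence and sparsity

Densities are Gaussian-KDE estimates with Silverman bandwidth on grids of
256 (1-D) or 128² (2-D) points spanning the sample range padded by 10%
and by 4 kernel bandwidths (so the density integrates to ~1 on its grid
even for tiny samples). D_KL(P‖Q) = ∫ p log₂(p/q) dx by trapezoidal
integration with q floored at 10⁻¹², P the reference (physiology-like)
distribution and Q the model. The integration domain is the union of both
padded supports rather than the support of Q alone, so reference mass
where the model assigns no density is penalised rather than discarded.
KDE settings materially affect absolute KL values; comparisons should
hold settings fixed, as the pipeline does.

Sparseness uses the Gini index of the discrete Lorenz curve,
Λ = 1 − 2∫L(F)dF: 0 for uniform activity, (N−1)/N for a one-hot vector
(0.75 at N = 4). Spatial sparsity Λ_S is computed per stimulus across
neurons, temporal sparsity Λ_T per neuron across stimuli, on 10⁴
naturalistic patches; signed (ICA/SC) activities enter as magnitudes,
STDP membrane potentials are non-negative by construction. All-zero
rows/columns are flagged NaN, not raised.

## Reduced problem sizes

The automated checks and `scripts/acceptance.py` run the full pipeline at
a reduced scale chosen so every stage's estimate is stable while the whole
study completes on one CPU in minutes: 40 surrogate images, 2×10⁴
training patches, 100 SC units / 100 ICA components / 100 STDP neurons,
20 probe repetitions (8 for tuning curves, 5 for decoding), SNR grid
{−6, 0, +6} dB, 3×10³ patches for sparsity. The full study conditions
(10⁵ patches, 225/150/225 units, 100 repetitions, 13 SNR levels) are the
library defaults and run unchanged via `earlyvis reproduce`.

## Known limitations

* On the surrogate, STDP receptive fields are blobbier than on
  photographic data; many are so weakly orientation-tuned that their
  bandwidth saturates the 90° cap, so the STDP bandwidth distribution on
  synthetic data is not informative (the ICA/SC distributions are).
* The threshold sweep shows FI rising as the testing threshold drops below
  the training value and collapsing above it, robustly across SNR; at the
  lowest threshold (scale −0.75) spiking probabilities saturate near 1
  under the default θ calibration and FI dips relative to scale −0.5, so
  the effect is an inverted-U over negative scales rather than strictly
  monotone in the threshold.
* FI assumes independent units (it is a sum over units); correlations
  induced by shared stimulus noise are ignored by construction.
* The spatial-sparsity variance ordering between models is sensitive to
  the input statistics and need not match photographic-data runs on the
  surrogate.
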