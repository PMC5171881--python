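# Methods

## Scope and data model

The package analyses two data products of a single-molecule imaging
study of a membrane protein in presynaptic terminals: (i) sptPALM
trajectories — per-molecule tracks of x/y positions (μm) at a fixed
frame interval Δt (default 1/33 s), grouped into imaging fields (one NMJ
chain per field); and (ii) SMLM localization tables — per-frame point
detections (nm) from fixed terminals. Analyses start from these tables;
raw-movie spot detection and linking are upstream tools' responsibility.

## Mobility analysis

**MSD.** Per track, the overlapping time-averaged estimator
MSD(nΔt) = ⟨(x_{i+n} − x_i)² + (y_{i+n} − y_i)²⟩ over all pairs of
observed frames separated by n. Overlapping pairs maximize information
on the short (~11-step) tracks this field produces. Frame gaps simply
contribute no pairs at the affected lags. Tracks shorter than 8
localizations are excluded (the boundary length is kept).

**Diffusion coefficient.** Ordinary least squares of MSD against τ over
the first 4 lags; D = slope/4 (2D), intercept a retained. The intercept
absorbs static localization error and finite-exposure blur (a ≈ 4σ_loc²
for static error), which is why the per-state and per-track coefficients
are *apparent* coefficients. A negative fitted slope — common for
immobile molecules on short tracks — yields D clamped to 0 and flagged;
such tracks classify as immobile. Known estimator property, verified by
simulation: the 4-point OLS D̂ is mean-unbiased, but on ~11-step tracks
its sampling distribution is right-skewed enough that the *median* of
per-track estimates sits ≈10% below the true D. Ensemble MSD curves
average the first 8 lags across tracks, unweighted, with per-lag track
counts and s.e.m. reported; shorter tracks contribute the lags they
have.

**Classification.** Mobile iff D > 0.021 μm² s⁻¹ (the field's standard
threshold); the tie goes to immobile, since mobility is defined by
exceeding the threshold. Per-field outputs: counts, mobile:immobile
ratio (flagged undefined when no track is immobile), and a
relative-frequency histogram of log₁₀ D on fixed bins (−5 to 1 in
0.2-decade steps, D floored at 10⁻⁵ so clamped tracks land in the lowest
bin) so distributions are comparable across conditions.

**Outlier handling.** A ROUT-style per-field outlier test is provided
but off by default: residuals from the median, robust scale from the
68.27th percentile of absolute residuals (small-sample corrected),
two-sided t p-values, Benjamini–Hochberg selection at q = 0.01. It
approximates the robust-regression-plus-FDR idea rather than replicating
any specific commercial implementation.

## Diffusive-state HMM

A molecule in state k takes isotropic 2D Gaussian steps, so the per-step
squared displacement r² is exponential with mean 4·D_k·Δt; the state
sequence is a first-order Markov chain per frame. Localization error is
deliberately not modeled separately — it inflates each D_k by ≈σ_loc²/Δt
and the fitted values are reported as apparent coefficients, matching
how the mobility arm reports D.

Fitting is Baum–Welch EM over all gap-free track segments of a field
(steps across missing frames are excluded as chain breaks), batched by
sorting segments by length so the forward–backward recursions run on
array prefixes. Initialization: a quantile split of the pooled squared
steps into K groups plus 10 random restarts; restarts run 25 iterations
and the best incumbent continues to convergence (tolerance 10⁻⁸ relative
log-likelihood, max 300 iterations). The state count K = 1..5 is chosen
by BIC with K² + K − 1 free parameters per candidate (emission means,
transition rows, initial distribution). BIC rather than a variational
bound keeps the selection objective simple; the contract is the recovery
property (correct K, D within tolerance on synthetic data), which the
acceptance suite checks. Candidate complexity is capped so at least 10
steps per parameter remain; degenerate all-zero data returns a flagged
single-state floor model.

Occupancies are reported both as posterior-weighted empirical step
fractions (the default) and as the stationary distribution of the fitted
transition matrix. Per-step annotation is exact Viterbi per gap-free
segment. Pooling maps each state to immobile (D ≤ 0.021 μm² s⁻¹), fast
(D ≥ 0.15 μm² s⁻¹, configurable — no standard boundary exists for the
slow/fast split) or slow, and sums occupancies; degenerate extra states
therefore merge into the class their coefficient indicates. One model is
fitted per field (fields with ≥~1,000 trajectories give stable fits);
`compare_occupancies` provides descriptive group summaries only —
significance testing is out of scope.

## Nanocluster analysis

**Consolidation.** Localizations within 1 frame and 1 camera pixel
(pixel size declared on the table, default 100 nm) of a growing chain
merge transitively into one record at the unweighted mean position,
first frame, summed intensity — a first-order correction for repeated
blinking.

**Drift correction.** Minimal fiducial-based translation: per-frame mean
displacement of each bead from its own time average, averaged over
beads covering ≥50% of frames, smoothed with a local-linear
(Savitzky–Golay, order 1) filter — exact for steady drift including the
boundary frames — and subtracted. Translation-only by construction.

**g(r).** Two estimators. `fft_image`: render at 10 nm, zero-padded FFT
autocorrelation normalized by the squared mean density and by the
rectangular window autocorrelation (computed analytically), radially
averaged with the zero-offset self-pair excluded. `direct_pairs`: exact
pair distances in annuli with the translation edge correction — the
point-pattern analogue of the window autocorrelation — normalized by
density and annulus area. The two agree within ~1% on CSR patterns once
the render pixel is a few nm; Ripley's K uses the classical isotropic
correction instead (valid for radii below half the window extent).

**Cluster model.** Nonlinear least squares of
g(r) = 1 + exp(−r²/4σ²)/(4πρσ²) + A·(exp(−·/ξ) ⊛ q_σ)(r),
bounded, multi-start over σ and ξ guesses, fitted from the second radial
bin. The first term is over-counting: repeated localizations of one
molecule differ by two error draws, a 2D Gaussian q_σ of width √2·σ per
coordinate; its amplitude ties σ to ρ (an estimate of molecule density,
bounded between 1/20× and 1.2× the measured localization density on
physical grounds — a molecule blinks at least once, and >20-fold repeat
counts are unrealistic). The second term is protein clustering with
correlation length ξ (the mean cluster radius); because every
cross-molecule pair is blurred by the same kernel q_σ, the exponential
is convolved with it — sharing σ, adding no parameter, and leaving the
term's integral unchanged. Without this convolution the fitted ξ is
biased upward by tens of percent when ξ is within a factor of a few of
σ. Reported: ρ, σ, ξ, A, resolution = σ/√2, molecules per cluster
N = 2πρAξ² (the integral of the clustering term; raw parameters are
always emitted so alternative definitions can be recomputed), fit rms
and Jacobian-based standard errors. When ξ ≲ 2σ the over-counting and
clustering terms are weakly identifiable; ρ (hence N) degrades first
while ξ remains usable — the recovery tests quantify this.

**Ripley.** K(r) = |A|·Σ_{i≠j} w_ij 1[d_ij ≤ r]/(n(n−1)) with isotropic
weights, L = √(K/π), per-point local L at a chosen radius for cluster-map
coloring, and CSR envelopes: either the classical pointwise min/max of
99 resimulations or (default) a studentized max-deviation global band
whose exceedance probability is the stated level across the whole curve.

## Synthetic data

The trajectory generator mirrors the HMM's generative assumptions:
Markov-switching 2D Brownian motion, displacement variance 2·D_k·Δt per
coordinate, static Gaussian localization error added to reported
positions, geometric track lengths (memoryless photobleaching, minimum
2 points), state at birth from the stationary distribution. Defaults are
the study scale: 3,500 tracks per field, mean 11 steps, 33 Hz, 20 nm
localization error, three states at (0.005, 0.06, 0.35) μm² s⁻¹ — the
printed record gives the acquisition scale and threshold but not the
per-state coefficients, so the preset values are chosen as realistic for
a membrane SNARE and are not fitted to any published figure. The
stimulated preset shifts the transition matrix so stationary occupancy
moves from immobile toward fast.

The cluster generator: Poisson cluster centers (sampled in a margin
around the fov so the pattern is stationary inside it), Poisson molecule
counts per cluster, Poisson background, geometric blink counts (mean 2)
at uniformly random frames, Gaussian localization error per blink
(20 nm), out-of-window blinks dropped. Cluster offsets default to a
Gaussian scale mixture (variance s ~ Gamma(3/4, 2ξ²)) whose *pair
separation* density is exactly exp(−r/ξ)/(2πξ²) — the generative mirror
of the fitted clustering term, making ξ a genuine ground-truth
parameter. An exponential radial *density* profile is also offered for
robustness tests, but note its pair-correlation is not exponential (its
autocorrelation ∝ r²K₂(r/ξ)), so ξ is not directly recoverable from the
standard fit under that profile. Blink mean 2 makes the over-counting
amplitude self-consistent (E[B(B−1)] = E[B]² for the geometric at mean
2), so the fitted ρ estimates the molecule density; other blink means
bias ρ by β/(2(β−1)). Rest/stimulated presets use cluster radius 83.5 →
60.1 nm, molecule density ≈61 → ≈39 μm⁻², molecules per cluster 40 →
31.5.

What the generators do *not* emulate: motion blur within a frame
(absorbed by the MSD intercept in real data), temporally correlated
blinking (real fluorophores blink in bursts, which consolidation
removes; uniform-frame blinks leave the over-counting term for the model
fit to handle), anomalous/confined diffusion, chromatic or z effects,
and non-Poisson cluster spatial statistics. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every property of real terminals.

## Numerical choices and limitations

- Reproducibility: every stochastic routine takes a seed; fixed seeds
  give bit-identical outputs, and pipeline tables are written with fixed
  float formatting so reruns are byte-identical.
- Problem sizes in tests: recovery tests use ~2,000 tracks × 11 steps
  (≥20,000 steps) for state inference and 10×10 μm fields (~10⁴
  localizations) for cluster fits — the study's own per-field scale.
- The smeared exponential is evaluated by Gauss–Legendre quadrature on
  the non-oscillatory Bessel form (200 nodes over ±10σ around r);
  accuracy ~10⁻³ relative, and its integral is preserved to the same
  order.
- Edge corrections assume a rectangular window; polygonal ROIs are out
  of scope for the pair estimators (select a rectangular ROI first).
- The per-track median D̂ bias (~10% low at 11-step tracks) is a
  property of the prescribed estimator, not removed by this package;
  mean-based and ensemble-based quantities are unbiased.
- Two-population summaries of per-ROI cluster radii (mixture peaks) are
  left to the user; the package reports per-ROI fits.
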