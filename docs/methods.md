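# Methods

This note documents the models and procedures implemented in `vocalvae`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Spectrogram images

A syllable with onset/offset `[t0, t1)` (half-open, seconds) is rendered to
a fixed 128 × 128 image:

1. Log modulus of the short-time Fourier transform, Hann windows.
   Defaults follow songbird practice (window 512 samples, overlap 256);
   mouse ultrasonic recordings use window 1024, overlap 512. "Log" is the
   natural log of (magnitude + ε), ε = 10⁻¹², an explicit numerical floor;
   the base is irrelevant because the clip-and-rescale step below removes
   affine scale.
2. Bilinear interpolation onto 128 target frequencies — mel-spaced
   (m = 2595·log₁₀(1 + f/700)) over 0.4–10 kHz for songbirds, linearly
   spaced over 30–110 kHz for mice — and 128 target times sampled at frame
   centers of the syllable's extent. Interpolation at frame centers (not
   segment edges) was chosen; segments spanning fewer than two STFT frames
   fall back to the two nearest columns rather than erroring.
3. Duration handling: syllables longer than t_max = 200 ms raise a
   dedicated discard signal (`SyllableTooLong`); shorter syllables are
   stretched by √(t_max/t), so the occupied fraction of the time axis is
   √(t/t_max) — monotone in t, hence relative duration order is preserved
   while brief syllables receive more pixels per unit time.
4. Amplitudes are clipped to `[clip_min, clip_max]` and rescaled linearly
   to [0, 1]; the unoccupied time extent is zero-padded symmetrically.
   Clip bounds in the field are usually tuned by eye per dataset; as a
   reproducible surrogate, unset bounds are calibrated as the 2nd and
   99.8th percentiles of log magnitudes over a batch calibration sample,
   frozen into the config, and shared by every image of the batch.

## The VAE

Generative model per image x (D = 16,384 pixels): z ~ N(0, I₃₂),
x | z ~ N(decoder(z), v·I_D) with fixed observation variance v = 0.1.
The approximate posterior is a low-rank-plus-diagonal Gaussian
q(z|x) = N(μ, uuᵀ + diag(d)): richer than mean-field at nearly diagonal
cost, with reparameterized samples z = μ + u·ε₀ + √d ∘ ε (ε₀ scalar,
ε vector standard normal). The KL to the prior is computed in closed form
using the matrix determinant lemma,
log det Σ = Σᵢ log dᵢ + log(1 + uᵀ diag(d)⁻¹ u), so the cost stays linear
in the latent dimension; the implementation is pinned against a dense
full-matrix Gaussian-KL oracle in the tests.

The reconstruction term is the Gaussian log-density *summed* over pixels
(not averaged), matching the N(·, 0.1 I) observation model over the full
image; a single posterior sample per datapoint is used during training.

Encoder and decoder are fully-connected ReLU networks with config-declared
hidden widths (default 512, 128, mirrored in the decoder), linear heads for
μ and u, and a softplus head (plus a 10⁻⁶ floor) keeping d strictly
positive. A convolutional architecture would be the conventional choice
for spectrogram images; the dense architecture was chosen so the entire
model — forward pass, backpropagation, and Adam — could be implemented
directly on numpy arrays, making training dependency-free, single-CPU
friendly, and bit-reproducible. On the synthetic benchmarks this
architecture recovers archetype structure essentially perfectly (≥99%
5-NN ground-truth classification), so no representational ceiling is hit
at the problem sizes used here; for large real corpora a convolutional
encoder would likely be more parameter-efficient.

Training: Adam, learning rate 10⁻³, batch size 64, latent dimension 32.
One master seed spawns three independent streams (initialization, data
order, posterior sampling), so identical seed + data reproduce identical
losses. A non-finite loss aborts with a diagnostic naming the epoch.
Epoch count is fixed by config (no early stopping); the per-epoch mean
ELBO is logged and checkpointed with the parameters.

## Feature-table statistics

**MMD.** Squared maximum mean discrepancy with a spherical Gaussian
kernel. Bandwidth: the median heuristic — σ = f × median pairwise distance
of the aggregate (union) sample, f = 1 by default, f = 0.25 for analyses
that need sensitivity to fine differences (tutor/pupil). The default
estimator is the biased V-statistic (always ≥ 0, appropriate for distance
matrices); the unbiased U-statistic is available and may be slightly
negative. For session × session matrices the bandwidth is resolved per
pair's union by default ("aggregate sample" read as the pair); a pooled
single-bandwidth mode is provided as config. Matrix rows can be ordered by
average-linkage agglomerative clustering.

**Variability index.** V.I. = minᵢ ρ(zᵢ) with ρ(z) = medianⱼ ‖z − zⱼ‖², the
median taken over *all* points including j = i (the self term, distance 0).
The exact form is O(n²); the fast variant evaluates ρ only at the
coordinate-wise median, O(n·d), and agrees within ~10% on Gaussian data at
n = 1000. The index is meaningful within one syllable type: pooled over a
mixed repertoire the median distance is dominated by between-type
geometry, so condition comparisons (`variability_reduction_by_type`)
compute the index per type and average the reductions, mirroring per-
syllable-type analyses of directed vs. undirected song.

**Cross-prediction.** Features are z-scored with training-fold statistics;
k-nearest-neighbor regression (k = 10, Euclidean) predicts one feature set
from the other; the reported variance explained is averaged over five
shuffled folds. The exact "variance explained" formula was an open choice:
residual-based R² is biased by about −1/k on unpredictable targets because
the k-neighbor average carries sampling variance even for an uninformative
predictor, so we report the mean per-column squared Pearson correlation
between held-out predictions and targets (≈0 for independent noise, ≈1 for
faithful prediction, and preserving the information-asymmetry signature on
nested feature sets). Latent features can optionally be projected onto
principal components holding ≥1% of total variance first.

**Effective dimensionality.** Each column is z-scored (handpicked features
carry no natural common scale, and latent features are treated identically
for fairness), PCA is run, and the cumulative explained-variance curve is
returned; zero-variance columns are dropped with a warning. The companion
scalar counts components each holding ≥1% of variance.

**Clustering evaluation.** 10-fold cross-validation; per fold a Gaussian
mixture (k = 6 by default, full covariance, EM) is fit on the training
split and held-out points are scored by mean silhouette,
Calinski–Harabasz, and Davies–Bouldin. The null is a synthetic Gaussian
sample matched for mean, covariance, and size, scored identically with the
same fold structure. Reported values are real-minus-null differences per
fold with Davies–Bouldin negated so that higher always means more
clustered. Held-out splits that collapse to fewer than k clusters are
scored over the nonempty clusters and flagged. GMM label consistency fits
two mixtures on disjoint halves, labels the full set with both, and scores
the best label-permutation agreement via optimal assignment on the
confusion matrix (the matching rule was unspecified; optimal assignment is
the natural choice).

## Shotgun sampling and warping

Fixed-duration windows (120 ms finch, 200 ms mouse, 60 ms tutor/pupil) are
drawn uniformly over the union of admissible onset intervals
[region start, region end − duration], each region weighted by its
admissible length, so the empirical onset distribution is uniform and
windows never cross region boundaries. Window spectrograms are full-frame
(no stretch, no padding) and computed lazily per draw, so a training run
effectively never sees the same image twice.

Time warps map each rendition's extent to a common [0, 1] clock. The
default is the 2-knot linear warp; externally fitted piecewise-linear
multi-knot warps are validated (strictly increasing, endpoints 0 and 1)
and consumed, but the joint warp-fitting optimization itself is out of
scope. Grid latents are collected at n = 200 points equally spaced in
warped time (nonlinearly spaced in real time for nonlinear warps); windows
at rendition edges are shifted inward rather than zero-padded, avoiding
padding artifacts dominating edge latents. Tutor/pupil gridding uses a
fixed 8 ms stride.

## Segmentation

Motif templates are the elementwise mean of a few example log-STFT
spectrograms (cropped to the shortest example; examples must agree in
duration within a relative tolerance), blurred with an isotropic Gaussian
of 0.5 pixel standard deviation. Matching slides the template along the
recording's log-STFT one hop at a time and computes the zero-mean,
unit-norm (Pearson) correlation over the template support; degenerate
constant patches score 0. Matches are strict one-neighbor local maxima
(plateaus credit the earliest offset) whose score exceeds
median + 1.8 × MAD, median and raw MAD (no 1.4826 consistency factor)
taken over that file's correlation trace. Manual curation of match
clusters is replaced by an optional score-rank cutoff for non-interactive
reproducibility. Motif cleanup merges sub-50 ms gaps and then discards
segments outside 0.4–1.5 s; the operation is idempotent and never produces
overlaps.

## Synthetic data: what it emulates, what it does not

Syllables are synthesized by phase accumulation along an
instantaneous-frequency trajectory defined by a few (time-fraction, Hz)
knots, interpolated with a monotone cubic (no overshoot past Nyquist),
with a linear amplitude envelope and optional harmonic stacks — a
caricature of USV contours and song-syllable sweeps. White Gaussian noise
at a configurable floor covers entire recordings, so segmentation-free
windows contain realistic silence + noise. The clustered regime draws an
archetype per syllable and jitters knot frequencies and duration
(multiplicative, relative std = `jitter_scale`); the continuum regime
interpolates knots linearly between adjacent archetypes (ordered by id) at
a uniform coordinate u ∈ [0, 1] — the two regimes differ only in the
archetype-selection rule. Two-condition datasets scale jitter by a known
`variability_ratio`; motif datasets add per-rendition global tempo
factors, and the pupil variant corrupts one archetype's knot frequencies
while sharing per-syllable synthesis seeds with the tutor, so uncorrupted
syllables are bit-identical across the pair.

Default study conditions used by the tests and the acceptance script:
4 archetypes spanning 2–9 kHz at 32 kHz sampling (songbird-like rates keep
runtimes small; the code is rate-agnostic and mouse-band configs are
provided), 200 syllables per repertoire, 5% jitter, noise floor 10⁻³,
25 training epochs. These sizes were chosen so that every recovery
property (archetype classification, regime contrast, variability-ratio
recovery) is comfortably detectable at single-CPU scale.

Passing tests on this generator demonstrate *mechanical correctness and
parameter recovery under the generator's assumptions* — stationary noise,
ideal chirps, perfectly known segment boundaries. They do not certify
performance on real recordings, which add reverberation, overlapping
animals, nonstationary noise, segmentation errors, and richer
within-category acoustic variation. Quantities reported on real data in
the literature (e.g. specific percentages of variance explained or
variability reduction) depend on those recordings and are not reproduced
here.

## Numerical and design notes

- All times are seconds, intervals half-open, bin indices 0-based,
  frequency rows ordered low → high.
- Determinism: every generator and the trainer are pure functions of
  config + seed; pipeline stages derive per-stage seeds from the master
  seed by stable hashing, and stage outputs are cached under hashes of the
  config subtree plus upstream keys.
- Embeddings (UMAP, t-SNE) are presentation artifacts: seeded and
  reproducible, but no quantitative claim in the package rests on embedded
  geometry beyond relative-distance sanity checks (successive-window
  strands embedding closer than random pairs under the 10⁻³
  strand-distance shrink).
- Nearest-neighbor queries break distance ties by ascending row id.
- The biased MMD estimator of identical samples is exactly 0; the matrix
  diagonal is 0 by construction and symmetry is exact.
- `cross_predict` requires row-aligned tables and raises on length
  mismatch; `mmd_matrix` raises and names sessions with fewer than two
  rows.

## Known limitations

- The dense (non-convolutional) VAE scales quadratically in pixel count ×
  hidden width; 128 × 128 images with hidden width 512 are comfortable on
  one CPU, but much larger images would favor a convolutional encoder.
- The piecewise-linear warp *fitting* algorithm is not implemented — only
  the 2-knot default and validation/consumption of external knot tables.
- MMD hypothesis testing (permutation p-values) is intentionally absent.
- The template matcher assumes the motif duration is stable across
  renditions (it is a fixed-size matched filter); strong tempo variation
  degrades the correlation peak.
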