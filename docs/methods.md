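# Methods

This note records the model, the defaults, and the numerical and design
choices behind `cmtfusion`, in the spirit of a package methods appendix.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model

Two simultaneously acquired, temporally aligned views of the same latent
sources:

* **EEG tensor** X ∈ ℝ^(Is×If×Ic): the recording is cut into Is
  contiguous segments of one TR each (one per fMRI volume, anchored at
  sample 0), each segment/channel is transformed with Thomson's
  multitaper method, and squared Fourier amplitudes are averaged into
  half-open frequency bins — by default 58 bins of 0.5 Hz covering
  [1.0, 30.0) Hz.  Entries are nonnegative power.
* **fMRI matrix** Y ∈ ℝ^(Is×Iv): one ROI-averaged BOLD series per
  column.

The coupled model is

    X ≈ Σ_r s_r ∘ f_r ∘ c_r
    Y ≈ Σ_r Σ_k (H_k s_r)(b_k ⊙ v_r)ᵀ + N Pᵀ

with shared temporal signatures s_r.  ⊙ is elementwise over ROIs: the
k-th HRF basis function contributes to ROI v in proportion to B[v,k], so
every ROI has its own response shape Σ_k B[v,k] h_k while the basis
itself is fixed.  We deliberately adopt this elementwise reading of the
coupled term (rather than a Khatri–Rao composition) because it is the one
consistent with an "ROI-specific HRF": B interacts with V only through
the products B[v,k]·V[v,r].

A consequence worth knowing: those products leave a per-ROI gauge freedom
(scale row v of B by 1/g and row v of V by g).  B is left unconstrained
in the fit; comparisons of V across fits should either use similarity
measures dominated by the strongly loaded ROIs (as the clustering metric
is) or fix the gauge by normalizing B rows.

## HRF basis

Canonical double-gamma (response peak ≈ 6 s, undershoot ≈ 16 s,
undershoot ratio 1/6) plus its temporal and dispersion derivatives,
K ∈ {1,2,3}, sampled at TR on lags [0, duration] (default 32 s).  All
curves are normalized to unit peak magnitude so B coefficients are
comparable across basis functions.  Convolution is causal at TR
resolution with zero initial conditions and truncation to Is — finer-grid
convolution would require an upsampling model of s_r that nothing in the
data constrains.  Direct optimization of the gamma shape parameters θ is
out of scope; the ROI-wise coefficients B are what the fit learns.

## Objective and optimization

    J = βx‖X−X̂‖²F + βy‖Y−Ŷ‖²F + γx‖λx‖₁ + γy‖λy‖₁
    λx,r = ‖s_r‖‖f_r‖‖c_r‖        λy,r = Σ_k ‖b_k ⊙ v_r‖

Defaults make J dimensionless: βx = 1/‖X‖²F, βy = 1/‖Y‖²F, and the
amplitude penalties are applied to amplitudes measured relative to the
data norm (effective multipliers γx/‖X‖F, γy/‖Y‖F with γx = γy = 0.01).
Without that relative scaling the penalty would grow with the raw data
scale and could suppress an entire modality's fit; with it, the penalty
is a small, scale-invariant shrinkage.  All four weights are
configurable, and `scale_free=False` restores raw γ multipliers.

The L1-of-norms terms are nonsmooth at zero; every Euclidean norm inside
them is smoothed as √(·² + ε) with ε = 1e−9, which keeps the objective
C¹ for the quasi-Newton solver while changing the value negligibly away
from zero.

Optimization is L-BFGS (scipy, `maxcor=20`) on the concatenated parameter
vector (S, F, C, V, B, N, P) with analytic gradients for every block;
stopping at `max_iter` (default 1000) or relative cost update < 1e−8.
Initialization: S, F, C from a CPD of X; V by ridge least squares of Y on
H₁S; B rows at (1, 0, …); N, P from the truncated SVD of the residual.
This makes a fit deterministic given the CP init.  A cost increase beyond
10× the initial value raises an optimization error; in ensembles, failed
runs are logged and skipped.

The CPD itself is alternating least squares on the exact Frobenius
objective with ridge-regularized (1e−12, trace-scaled) Gram inverses —
the monotone cost trace is exposed in the diagnostics, and any minimizer
reaching the same tolerance on the same objective would be equivalent
downstream.

### Normalization for clustering

Components are put in a canonical form before clustering: F, C, V columns
scaled to unit norm, F/C scale absorbed into S, and a per-component
coupling amplitude `v_scale` absorbing the rest.  The amplitude is
necessary: S is shared between X̂ and Ŷ, so the S rescaling that absorbs
the F/C norms rescales the coupled BOLD term, and B cannot compensate
per component (it is shared across components).  `v_scale` keeps both
reconstructions bit-for-bit unchanged under normalization.  Sign
convention: the largest-magnitude entry of each F, C and V column is
positive, with compensating sign flips in S / `v_scale`.

## Model selection

Per candidate R, an ensemble (default 50 runs) of CPD-initialized coupled
fits is computed and every component of every run becomes a node in a
similarity graph.  Similarity is the product over modes (s, f, c, v) of
absolute cosine similarity; edges join pairs with similarity ≥ 0.9
(configurable); clusters are connected components; the centroid is the
member with maximal summed similarity to the rest; cardinality counts
distinct runs.  Connected components over a thresholded similarity graph
is our concrete instantiation of graph-structured clustering; the
threshold is exposed in the config.

The four indicators:

1. **CORCONDIA** — 100·(1 − ‖G − I‖²F/R) where G is the least-squares
   Tucker core of X given the EEG factors (ridge-regularized
   pseudo-inverses).  Exact CP structure gives exactly 100; the core
   solve is invariant to component permutation and compensated column
   rescaling, so no pre-normalization is needed.  Gate: ≥ 80%.
2. **Reproducibility** — clusters with cardinality strictly greater than
   `min_cardinality` (default 10, intended for 50-run ensembles; scale
   proportionally for smaller ensembles) are retained.
3. **Stimulus similarity** — absolute Pearson correlation between a
   temporal signature and the binary per-volume stimulus indicator
   (absolute because CP signs are indeterminate).  The raw binary vector
   is used by default; convolving it with h₁ first is available as an
   option.
4. **SnPM significance** — per ROI, the |t| statistic of the slope of
   Y[:,v] on the canonical-HRF-convolved signature; the null is built by
   circular shifts of that regressor (uniform random shift per
   permutation, default 999), taking the max |t| over ROIs.  P-values are
   (1 + #{null ≥ T})/(n_perm + 1), so familywise error over ROIs is
   controlled at α (default 0.05) essentially exactly under an
   exchangeable noise null.  Computed per subject/run.

**Automatic choice of R** (the study's selection was manual and
acknowledged as ambiguous; we codify a deterministic rule and keep the
full trace for human override via `--force-r`): a candidate is eligible
if CORCONDIA ≥ 80 and its best-similarity centroid component is in a
retained cluster; among eligible candidates the highest stimulus
similarity wins, ties to smaller R; if none is eligible the least-bad
candidate is returned flagged `no_eligible_model`.

## Synthetic data

The generator emulates the study conditions: an 80-trial win/lose
paradigm (trial = 4 s choice + 2 s gaze + 2 s feedback + 2 s score + 4 s
rest = 14 s, so 80 trials = 1120 s = 18 min 40 s = 560 volumes at
TR = 2 s; the 4 s choice window is the one duration not dictated by the
paradigm description and is chosen to match the stated total length),
64-channel EEG at 250 Hz, 90 ROIs.  A volume is marked as stimulated when
its half-open acquisition interval overlaps the feedback phase of a trial
matching the requested condition; wins are Bernoulli(p_win) per trial.
Inter-trial jitter and response-time variability are not modeled; the
schedule is fixed and configurable.

Ground-truth factors: temporal signatures are unit-variance — the
stimulus-driven column is the binary stimulus smoothed with a short
3-tap kernel (0.15, 0.7, 0.15) plus AR(1) noise at 10% relative standard
deviation, the others are smooth Gaussian processes; unit variance makes
the sources enter both modalities at comparable amplitude.  Spectral
signatures are unimodal nonnegative bumps at distinct centers in
[1, 30) Hz; channel topographies are smooth over the channel index; ROI
maps are sparse (15% of ROIs by default, ≤ 20% enforced) with random
signs and amplitudes in [0.5, 1.5]; HRF coefficient rows are (1, 0, …)
plus N(0, 0.1) perturbations so every ROI is near-canonical and the
temporal alignment stays identifiable.  Noise on both modalities is
additive white Gaussian at a stated SNR, defined as
10·log₁₀(‖signal‖²F/‖noise‖²F) — the simplest model consistent with the
least-squares fit terms.  Raw EEG synthesis emits per-source sinusoid
mixtures whose per-segment band power follows max(S, 0) (power cannot be
negative), mixed through C, for end-to-end tests of the tensorization.

What the generator does **not** emulate — and hence what passing tests do
not establish about real recordings: MR gradient/pulse artifacts and
their residuals, 1/f background spectra, nonstationary alpha dynamics,
head motion, physiological confounds shared across modalities, regional
HRF variability beyond the linear basis, and any nonlinearity of
neurovascular coupling.  The pipeline assumes its preprocessed inputs are
clean.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| TR | 2 s | volume interval = EEG segment length |
| bins | [1, 30) Hz, 0.5 Hz | 58 half-open frequency bins |
| NW / tapers | 2 / 3 | multitaper bandwidth and DPSS count (method names no values; these suit 2 s segments and are configurable) |
| K | 3 (2 in the compact configs) | HRF basis size |
| HRF duration | 32 s | lag support |
| γx, γy | 0.01 (scale-free) | amplitude shrinkage |
| ensemble runs | 50 | CP inits per candidate R |
| cluster threshold | 0.9 | similarity cutoff |
| min cardinality | 10 (of 50) | strict retention cutoff |
| α / permutations | 0.05 / 999 | SnPM FWE level / null size |
| CPD tol / iters | 1e−8 / 2000 | ALS stopping rule |
| CMTF tol / iters | 1e−8 / 1000 | L-BFGS stopping rule |

Per-segment mean removal is applied before the spectral transform
(prevents DC leakage into the lowest bin; the target recordings are
band-passed anyway).  No further detrending or windowing beyond the
tapers.

## Problem sizes used in the test suite

Tests run on one CPU, so simulations are scaled: the coupled
parameter-recovery check runs at Is=200, If=20, Ic=16, Iv=30, R=2, K=2,
Q=1, SNR 20 dB with 10 initializations; ensemble-stability checks use
50 runs at Is=70, If=10, Ic=8, Iv=15; the rank-selection experiment uses
10 replicates × candidates R ∈ {1..4} × 20-run ensembles with the
retention cutoff scaled by the same 1/5 ratio (cardinality > 4 of 20);
FWE calibration uses 200 null datasets of 120 × 30 with 199 permutations.
The pipeline's `default_config()` mirrors this compact scale and comments
each study-scale value inline.

## Known limitations

* CP/CMTF objectives are non-convex; the ensemble machinery mitigates
  but does not eliminate local optima.
* The coupled model assumes the EEG and BOLD temporal signatures are
  identical up to HRF convolution; real neurovascular coupling need not
  satisfy this.
* B/V products are identifiable only up to the per-ROI gauge described
  above; reported ROI maps should be read with that in mind.
* The SnPM circular-shift null assumes temporally exchangeable noise
  after shifting; strongly autocorrelated BOLD noise makes it
  approximate.
* Volume-level fMRI, multi-subject/group models and anatomical rendering
  are out of scope; the fMRI entry point is the ROI series matrix.
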