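# Methods

## Problem and models

A motion-capture session with `m` markers over `n` frames is a matrix
`X ∈ R^{n×3m}` of millimetre coordinates; occlusions leave NaN gaps that, for
a physical occlusion, always cover all three coordinates of a marker over a
contiguous frame interval.  `gaitfill` completes `X` under the constraint
that every observed entry is reproduced exactly (measurements are trusted;
the solver is not a smoother), with two convex priors:

- a **nuclear norm** `‖X‖*` — gait trajectories of different markers are
  highly correlated, so the matrix is approximately low rank;
- a **weighted spectral sparsity penalty** on `F X`, the unitary DFT of every
  channel along time.  Gait is periodic and band-limited: almost all energy
  sits at the stride frequency and a few harmonics.  The diagonal weight
  matrix `W` charges `high_weight = 100` to every frequency bin whose folded
  index `min(i, n − i)` exceeds the cutoff `θ_f` and `low_weight = 1` below
  it, so out-of-band energy is strongly discouraged but the pass band is
  still (weakly) sparsified.  S-LR uses the entrywise `‖W F X‖₁`; GS-LR uses
  the row-group `‖W F X‖₁,₂`, which zeroes whole frequency rows across all
  channels jointly, encoding the observation that all limbs move at the same
  (stride-locked) frequencies.

Orientation matters: time must run down the rows so that a row of `F X` is
one frequency bin shared by all channels — this is what makes the `ℓ₁,₂` row
norm mean "joint frequency support", and it is the convention used
throughout.

The DFT is unitary (`1/√n` scaling), so its adjoint is its inverse, Parseval
holds exactly, and `F X` has the same singular values as `X`; consequently
the single nuclear-norm prior constrains the rank in both domains, and the
X-update below is an exact minimiser.  Because a real signal's spectrum is
conjugate-symmetric, the weights are folded symmetrically (penalising only
`i > θ_f` one-sidedly would drive reconstructions complex); the real part is
taken after every inverse transform.

## Solver

ADMM on the splitting `Q = X`, `R = F X` with multipliers `A`, `B` and
penalty weights `μ_A`, `μ_B`:

1. **X-step** (exact): at unobserved entries
   `X = [μ_A (Q + A) + μ_B Re F⁻¹(R + B)] / (μ_A + μ_B)`; observed entries
   are copied from `Y` bit-exactly.
2. **Q-step**: singular-value thresholding `svt(X − A, 1/μ_A)` — the prox of
   the nuclear norm.
3. **R-step**: with `C = F X − B` and per-row thresholds `λ wᵢ / μ_B`,
   entrywise magnitude shrinkage (S-LR) or row-norm shrinkage (GS-LR).
   Shrinkage is phase-preserving on complex entries (`max(|c| − γ, 0)·c/|c|`),
   which reduces to `sign`-based soft thresholding on reals; zero entries/rows
   map to zero.
4. **Dual ascent**: `A += Q − X`, `B += R − F X`.

Initialisation is deterministic: unobserved entries filled by per-channel
linear interpolation (constant extension at the ends), `Q = X`, `R = F X`,
`A = B = 0`.  Convergence is declared when both relative primal residuals
`‖Q − X‖_F / max(1, ‖X‖_F)` and `‖R − F X‖_F / max(1, ‖F X‖_F)` fall below
`tol` (default `1e-6`, `max_iter = 500`); hitting `max_iter` logs a warning
and returns the iterate with `converged=False` rather than raising.  The
residuals decay with a damped short-period oscillation, so monotonicity
checks should compare envelopes, not raw iterates.  A channel with zero
observed samples is unrecoverable and raises immediately, naming the
marker/coordinate.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `lam` (λ) | `1e4` | sparsity vs low-rank trade-off; **scale dependent** — 1e4–1e5 suits millimetre-scale gait captures of a few thousand frames; use `lambda_sweep` to pick it for other scales. `λ = 0` degenerates to pure nuclear-norm completion; `λ → ∞` erases all penalised spectral content. |
| `mu_a`, `mu_b` | `1.0` | augmented-Lagrangian weights; they affect convergence speed, not the optimum, and the solver is not very sensitive to them. |
| `theta_f` (θ_f) | `100` bins | penalty cutoff. In Hz it is `θ_f · rate / n`; `SpectralWeights.from_cutoff_hz` converts. It should sit comfortably above the highest gait harmonic (for the synthetic generator the harness uses 1.5× the highest harmonic bin). θ_f is a bin index, not Hz. |
| `high_weight`, `low_weight` | `100`, `1` | out-of-band / in-band penalty weights. |
| `window_frames` | off | optional non-overlapping windows solved independently (short-time analysis of non-stationary captures). No overlap-add is attempted; window boundaries may show small seams, so the default processes the full sequence. |

## PCA baseline

`pca_impute` is a conventional EM-style iterative principal-subspace
completion: interpolate, then alternate (centre → rank-k SVD projection →
restore observed entries) until the imputed block changes by less than `tol`.
`k` is fixed once, from the initialised matrix, either directly
(`n_components`) or as the smallest k explaining `variance_threshold`
(default 0.95) of the variance.  Component signs are fixed
(largest-magnitude loading positive) for determinism.  It represents the
PCA-family reconstruction methods used in gait analysis; it is *not* a
reimplementation of any specific published variant, so benchmark conclusions
against it are directional, not reproductions of published per-dataset
numbers.

## Synthetic gait generator

Real gait captures are not redistributable here, so the benchmark runs on a
synthetic generator built to exhibit exactly the three structural properties
the models exploit: a shared basis of sines/cosines at the stride fundamental
(`1/cycle_frames`) and its first `n_harmonics` multiples is mixed through a
`latent_rank`-dimensional factor model into unit-RMS latent factors, then
into channels with amplitudes drawn from `amplitude_range` (default
10–100 mm, typical limb-marker oscillation), static per-channel offsets
(default ±500 mm, marker positions in the capture volume) and optional
i.i.d. Gaussian sensor noise.  Defaults emulate a common capture: 37 markers,
240 Hz, one-second cycles, 4 harmonics, latent rank 5.  The noiseless matrix
has rank ≤ `latent_rank` (+1 for the DC offset direction), exactly shared
harmonic spectral support (choose `n_frames` an integer multiple of
`cycle_frames` to avoid leakage), and perfect periodicity.

What it does **not** model: soft-tissue artifact, stride-to-stride timing
variability, drift, skeleton constraints, or any anatomy.  Passing benchmarks
on this data therefore demonstrates correctness of the optimisation and the
expected *ordering* of methods on data satisfying the priors — reconstruction
errors are far smaller than on real captures, where the low-rank/band-limited
structure holds only approximately.

Gap simulation follows the occlusion protocol: per trial, 5–20 gaps, each
hiding one marker's three coordinates over 10–50 % of a gait cycle, placed
uniformly over markers and time, repeated 20 times with seeds derived from a
master seed; overlapping gaps merge, as real occlusions do.  Gaps on
different markers may overlap in time.

## Benchmark harness and statistics

`run_experiment` generates a fresh capture per repetition, punches gaps, runs
every method on the *identical* gapped input (seeds are derived from the
master seed and repetition index, and the input hash is logged), and scores
only originally-missing marker-frames with the 3D position error
`‖p_rec − p_true‖₂` in mm.  Methods are compared with the paired Wilcoxon
signed-rank test on per-repetition mean errors (zero differences discarded;
all-zero difference vectors report the degenerate p = 1 with a warning);
20 repetitions give a paired sample of size 20.  The reduced-marker setting
keeps 11 of the 37 markers (every third), emulating one trajectory per limb.

The shipped study conditions are scaled for a desk-class machine: 600 frames
(five 120-frame cycles) × 111 channels, sensor noise 0.5 mm, solver at
`tol = 1e-5`, `max_iter = 200`, and per-method λ fixed once by a one-off
`lambda_sweep` on a held-out instance (S-LR 1e3, GS-LR 1e4, `θ_f = 30`).
Findings on this data: both convex models beat the PCA baseline by one to two
orders of magnitude in mean error (one-sided signed-rank p < 1e-5), GS-LR is
at least as accurate as S-LR, and PCA's failures grow sharply in the
11-marker setting while the convex models are essentially unaffected.  The
exact per-seed numbers are what `scripts/acceptance.py` recomputes.

## Numerical notes and limitations

- Observed-entry fidelity is enforced by construction in the X-step, so it
  holds bit-exactly regardless of convergence.
- `svt` needs no tie-breaking: the result depends only on the product
  `U·S(Σ)·Vᵀ`, which is invariant to SVD sign/ordering ambiguity.
- `recover` is a deterministic function of its inputs; all benchmark
  randomness lives in the generator and gap simulator and is seed-driven.
- On exactly low-rank, exactly band-limited synthetic data the median
  method-difference statistics are heavy-tailed across seeds (most gap
  configurations are easy for every method; a few are catastrophic for PCA),
  so per-seed medians fluctuate more than means.
- File formats: CSV (canonical, with `# frame_rate_hz` comment) and a minimal
  TRC dialect, both NaN-for-missing and round-trip safe to well below
  1e-9 mm; C3D is read-only behind the optional `ezc3d` dependency.  A
  marker-frame with only some coordinates missing is promoted to fully
  missing on read.
- Matrices are desk-scale (≤ ~10⁴ frames × ~10² channels); each iteration
  costs one thin SVD plus two FFTs.  No streaming or GPU path.
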