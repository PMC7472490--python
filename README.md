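# gaitfill

Gap filling for optical motion-capture (MoCap) marker trajectories by convex
low-rank + spectrum-sparse matrix completion.

Optical capture of human gait loses markers to occlusion: a marker blocked by
a limb or equipment leaves a contiguous gap in its 3D trajectory.  `gaitfill`
reconstructs those gaps without training data or a kinematic model, by
exploiting three structural properties of gait trajectories:

1. trajectories of different markers are strongly correlated (the frame ×
   channel matrix is approximately low rank);
2. each trajectory is periodic and dominated by low frequencies;
3. different channels share the same few frequencies (joint spectral support).

## The models

Stack the capture as `X ∈ R^{n×3m}` (n frames, m markers, columns are x/y/z
channels in millimetres) with observed entries `Ω`.  With `F` the unitary DFT
along time and `W` a diagonal matrix of per-frequency weights (weight 100
above a cutoff bin `θ_f`, weight 1 below — penalising energy outside the
gait band), the package solves

- **S-LR**  `min ‖X‖* + λ ‖W F X‖₁       s.t.  P_Ω(X) = P_Ω(Y)`
- **GS-LR** `min ‖X‖* + λ ‖W F X‖₁,₂     s.t.  P_Ω(X) = P_Ω(Y)`

where `‖·‖*` is the nuclear norm, `‖M‖₁,₂ = Σᵢ ‖mᵢ‖₂` sums row (frequency
bin) norms so the GS-LR penalty zeroes whole frequency bins across all
channels jointly.  Both are solved by ADMM with auxiliary variables `Q = X`
(nuclear prox via singular-value thresholding) and `R = FX` ((group)
soft-thresholding), and an exact X-step that keeps observed samples
bit-exact.  An iterative-PCA imputer is included as the conventional
baseline, plus a synthetic gait generator and a repeated-gap benchmark
harness with paired Wilcoxon comparison.

## Worked example

```python
import numpy as np
from gaitfill import (GaitSimConfig, GapSpec, GroupSparseLowRankImputer,
                      generate_trajectories, simulate_gaps)

cfg = GaitSimConfig(n_markers=12, n_frames=600, cycle_frames=120,
                    noise_sd=0.5, rng_seed=0)
observable, truth = generate_trajectories(cfg)
gapped, mask, gaps = simulate_gaps(observable, GapSpec(rng_seed=1), cfg.cycle_frames)

imputer = GroupSparseLowRankImputer(lam=1e4, theta_f=30, tol=1e-5, max_iter=200)
completed = imputer.fit_transform(gapped.values)

missing = ~mask.observed
err = np.linalg.norm(
    (completed - truth.values).reshape(-1, 3)[missing.reshape(-1, 3).any(axis=1)],
    axis=1)
print(f"{len(gaps)} gaps, {missing.mean():.1%} of entries missing")
print(f"mean reconstruction error {err.mean():.3f} mm after {imputer.n_iter_} iterations")
```

prints

```
12 gaps, 6.3% of entries missing
mean reconstruction error 0.112 mm after 200 iterations
```

i.e., twelve simulated occlusions covering ~6 % of the matrix are refilled
with ~0.1 mm mean 3D position error on this synthetic capture — around the
0.5 mm sensor noise floor, far below marker size.  The same solvers are
available functionally (`gaitfill.recover`, `gaitfill.pca_impute`) and from
the shell:

```bash
gaitfill simulate --n-markers 12 --n-frames 600 --cycle-frames 120 --seed 0 \
    --out truth.csv --gapped gapped.csv --gaps gaps.csv
gaitfill recover --input gapped.csv --method gs-lr --lambda 1e4 --theta-f 30 \
    --out completed.csv
gaitfill evaluate --truth truth.csv --methods s-lr,gs-lr,pca --reps 20 \
    --cycle-frames 120 --lambda 1e4 --theta-f 30 --seed 0 --out report.json
```

`λ` is scale dependent (1e4–1e5 suits millimetre data); `gaitfill
sweep-lambda` plots the error curve for choosing it.

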