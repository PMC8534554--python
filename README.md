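# idest — intrinsic dimension estimation

`idest` estimates the **intrinsic dimension (ID)** of a numeric point cloud —
the minimum number of parameters needed to describe the data with little
information loss. Real datasets (transcriptomic profiles, molecular
fingerprints, image features, clinical tables) usually occupy a manifold or
effective distribution of far lower dimension than their feature count, and
knowing that dimension governs how many components to keep, how severely the
curse of dimensionality bites, and which downstream methods are trustworthy.

The package provides, behind a uniform scikit-learn-style API
(`fit` → `dimension_`):

- **Spectral (linear) criteria** on the covariance eigenvalues
  λ₁ ≥ … ≥ λ_p: Fukunaga–Olsen thresholding (count of λᵢ/λ₁ > α), the Fan
  ratio/cumulative stopping rule, the largest consecutive-ratio gap,
  cumulative explained variance, the participation ratio (Σλ)²/Σλᵢ², the
  Kaiser rule and the broken-stick model (`lPCA`).
- **Fractal / nearest-neighbor estimators**: the correlation-integral slope
  d = Δln C(r) / Δln r (`CorrInt`); the Levina–Bickel maximum-likelihood
  estimator with the MacKay–Ghahramani inverse averaging (`MLE`); the
  two-nearest-neighbor Pareto-ratio estimator, μ = r₂/r₁ with
  P(μ > t) = t^(−d) (`TwoNN`); the manifold-adaptive two-radius ratio
  ln 2 / ln(r_k/r_{k/2}) (`MADA`); the method of moments m₁/(r_k − m₁)
  (`MOM`); the tight-locality estimator from chord-normalized pairwise
  distances (`TLE`); minimum-neighbor-distance maximum likelihood over
  ρ = r₁/r_k (`MiND_ML`); and the scaling of k-NN-graph length with sample
  size, L(n) ∝ n^((d−γ)/d) (`KNN`).
- **Concentration-of-measure estimators**: Fisher-separability analysis
  (`FisherS`), expected simplex skewness from E|sin θ| between random
  directions (`ESS`), and joint norm/angle concentration with seeded
  calibration (`DANCo`).
- **Local estimation**: any global estimator applied per point to its
  k-nearest-neighbor sub-cloud, segmenting clouds by local dimension.
- **Synthetic benchmarks**: seeded generators of balls, spheres, cubes,
  Gaussians, swiss roll, Möbius band, helix, nonlinear embeddings, affine
  subspaces, and the Line–Disk–Ball mixture with known per-segment ID.
- **Meta-analysis**: batch profiling of many datasets × 19 methods with
  per-method size caps and validity accounting, deterministic imputation,
  the **consensus ID** (per-dataset mean of method-wise z-scores), method
  correlation, PCA of ID profiles, redundancy sensitivity under feature
  duplication, and the runtime model Time = c · Nobj^α · Nvar^β.

## Worked example

```python
import numpy as np
import idest
from idest import datasets
from idest.core import estimate_local

# a 2-manifold (swiss roll) embedded in 3-D
swiss = datasets.generate("swiss_roll", 2000, seed=0)
for tag in ("MLE", "TwoNN", "FisherS", "lPCA_FO"):
    est = idest.estimate(swiss.points, tag)
    print(f"{tag:8s} {est.value:.3f}  ({est.status})")

# local dimension segments the Line-Disk-Ball mixture
ldb = datasets.line_disk_ball((1000, 1000, 1000), seed=0)
field = estimate_local("lPCA_FO", ldb.points, k=40)
for lab in ("line", "disk", "ball"):
    print(lab, np.nanmean(field.values[ldb.labels == lab]))
```

prints

```
MLE      1.949  (ok)
TwoNN    1.992  (ok)
FisherS  2.930  (ok)
lPCA_FO  3.000  (ok)
line 1.0
disk 2.0
ball 3.0
```

The nearest-neighbor estimators see through the curling of the roll and
report the manifold dimension ≈ 2, while the global spectral criterion
reports the ambient rank 3 and the separability-based estimate falls in
between — exactly the disagreement pattern that motivates profiling a
dataset with many estimators at once. The local spectral estimate cleanly
labels the three segments of the mixture with their true dimensions 1, 2, 3.

The same operations are available from the shell:

```bash
idest generate --name line_disk_ball --n 1000,1000,1000 --seed 0 --out ldb.csv
idest local    --input ldb.csv --method lPCA_FO --k 40 --out local_id.csv
idest estimate --input ldb.csv --method all --seed 0
idest profile  --inputs data_dir/ --methods all --seed 0 --out profile.csv
idest consensus --profile profile.csv --out consensus.json
idest sensitivity --input ldb.csv --method lPCA_FO
```

All commands are byte-deterministic for a fixed `--seed`.

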