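# aftractometry

Along-tract DTI tractometry of the arcuate fasciculus (AF), the
white-matter bundle connecting frontal and temporal language regions.
The package is aimed at neuroimaging researchers who want to compare a
patient's tract microstructure against a healthy-control (HC) normative
reference — for example in presurgical mapping of language-eloquent
gliomas — and at anyone who needs exact small-sample nonparametric
statistics for tiny clinical cohorts.

It provides, as a library, a CLI (`aftractometry`) and a reproducible
pipeline:

* **Spectral tract parameterization** — a probabilistic-tractography
  density map is thresholded at 10% of its maximum and turned into a
  voxel graph; the Fiedler vector of the graph Laplacian `L = D − A`
  (the eigenvector of the smallest non-zero eigenvalue) gives a smooth
  along-tract coordinate `t ∈ [0, 1]`, anchored at the frontal end,
  linearized in arc length and cut into K = 15 equal segments.
* **Tractometry** — per-segment medians of FA, MD, AD, RD
  (diffusivities in 10⁻³ mm²/s) form along-tract profiles.
* **Normative modelling** — per parameter and hemisphere, HC profiles
  are de-medianed per segment, pooled, trimmed at 3× the mean absolute
  deviation, and the 2.5th–97.5th percentile band is estimated as
  `m_k ± 1.96 σ`.  Patient segments strictly outside the band are
  abnormal (decreased FA/AD, increased MD/RD), counted per subject.
* **fMRI laterality** — `LI = (L − R)/(L + R)` over suprathreshold
  (`Z > 3.1`) voxel counts in homologous left/right lobar ROIs.
* **Statistics** — exact (full-permutation, tie-safe) Mann–Whitney U,
  Benjamini–Hochberg FDR (declared at FDR < 0.1), and Spearman rank
  correlations with exact p at very small n.
* **Synthetic phantoms** — an AF-like curved tube with known arc-length
  ground truth, HC/patient DTI cohorts with configurable focal lesions,
  and activation maps realizing a target LI, so the entire pipeline is
  testable without MRI data.

See `docs/methods.md` for the model details and assumptions.

## Worked example

The bundled nine-patient glioma cohort summary (four low-grade vs five
high-grade tumors) reproduces the classic small-sample arithmetic:

```python
import numpy as np
from aftractometry import mann_whitney_exact, bh_adjust
from aftractometry.datasets import TUMOR_VOLUMES_CM3, GROUP_COMPARISON_PVALUES

lg, hg = TUMOR_VOLUMES_CM3["LG"], TUMOR_VOLUMES_CM3["HG"]
res = mann_whitney_exact(lg, hg)
print(f"U = {res.u:g}, two-sided p = {res.p:g} ({res.method})")
print("medians:", np.median(lg), np.median(hg))
print("q =", np.round(bh_adjust(GROUP_COMPARISON_PVALUES), 2))
```

```
U = 10, two-sided p = 1 (exact)
medians: 32.9 26.4
q = [1.   0.11 0.21 0.37 0.08 0.07 0.07 0.07 0.17 0.29 0.21 0.88]
```

The tumor volumes are perfectly interleaved between groups — U equals
n₁n₂/2 = 10, so the exact two-sided p is 1 — and of the twelve
comparisons only the four with q < 0.1 (median AD, median MD, and the
counts of increased-MD and increased-RD segments) survive FDR control.

Parameterizing the default synthetic phantom:

```python
from aftractometry import TractModel
from aftractometry.synthetic import PhantomSpec, make_centerline, rasterize_tube

spec = PhantomSpec()
density, t_truth = rasterize_tube(make_centerline(spec.curve_control_points), spec)
fit = TractModel(density).fit()
print(fit.summary())
```

```
Spectral tract parameterization
===============================
voxels in tract:       878
graph edges:           7448 (26-connectivity)
Fiedler eigenvalue:    0.0132392
segments (K):          15
voxels per segment:    min 48, median 60, max 66
anchor (t=0):          frontal
```

The 878 tube voxels split into 15 segments of 48–66 voxels each, and
the recovered coordinate matches the tube's true arc-length fraction at
Spearman ρ > 0.999.  The full pipeline — simulate a cohort,
parameterize both hemispheres, build normative ranges, classify
patients, compute laterality indices and the group comparison — runs
from the shell:

```sh
aftractometry run --out runs/demo --seed 1 --report
```

writing stage TSVs, a JSON manifest (config hash, seeds, versions,
timings) and per-parameter profile plots with the shaded HC normative
band.  Identical configs produce byte-identical TSV outputs.

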