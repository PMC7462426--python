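# smoothsweep

How does the spatial-smoothing kernel chosen during fMRI preprocessing
change the *outcome* of a group comparison of functional brain networks?
`smoothsweep` implements the full measurement pipeline for that
question: it sweeps Gaussian kernels over voxel time series, builds
per-subject ROI connectivity matrices, detects group-different
subnetworks with the network-based statistic (NBS), and quantifies how
the detections shift across kernels. A synthetic two-group cohort
generator with a planted, known group-difference subnetwork makes every
stage testable without any imaging downloads.

It is aimed at methods-minded neuroimaging researchers who want to
reason about (or simulate) preprocessing sensitivity of network-level
group statistics.

## The statistics at the core

* **Smoothing (per kernel FWHM):**
  `x_i(t) ← Σ_j G_i(j) x_j(t) / Σ_j G_i(j)` over in-mask voxels —
  mask-aware renormalized Gaussian averaging, with
  σ = FWHM / (2√(2 ln 2)). Sweep default: 0, 4, 6, …, 32 mm (16
  kernels), each applied to the original data.
* **Connectivity:** Pearson correlation of ROI-mean series → Fisher
  z = artanh r → link-wise OLS removal of site and head-motion (mean
  framewise displacement) covariates → tanh back.
* **NBS:** per-link two-group F (df = 1, F = t²); suprathreshold links
  (default F > 12.25); connected components sized in links; permutation
  null of the maximal component size; component
  p = (1 + #{null ≥ size}) / (M + 1).
* **Sweep comparisons:** Cohen's d from F, |d| = √(F(1/n₁+1/n₂)),
  signed by the group mean difference; Hamming distance between
  subnetwork link masks; link persistence across kernels; Spearman ρ
  between physical link length (mm between ROI centroids) and F.
* **Traditional graph analysis:** 7%-density binarized graphs, five
  node/graph measures, 10,000-permutation tests, Benjamini–Hochberg FDR.

## Worked example

```python
from smoothsweep import CohortSpec, KernelSweep, generate_cohort
from smoothsweep.nbs import NBSConfig
from smoothsweep.sweep import SweepConfig, run_sweep

spec = CohortSpec(n_per_group=10, n_rois=12, T=256, delta=0.5, r0=0.1,
                  voxel_noise_sd=0.5, intrinsic_fwhm=3.0, seed=90)
cohort = generate_cohort(spec, mode="volume")
res = run_sweep(cohort, KernelSweep((0.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0)),
                SweepConfig(nbs=NBSConfig(12.25, 300, 0.05), seed=17))
print(dict(zip(res.fwhms, res.n_links)))
print(res.persistence_summary)
print(int(res.hamming.max()))
```

prints (this exact run is `analysis/05_kernel_sweep.py`):

```
{0.0: 5, 4.0: 5, 6.0: 5, 8.0: 5, 10.0: 10, 12.0: 13, 14.0: 16, 16.0: 17}
{'n_links_any': 17, 'n_links_all_kernels': 5, 'n_links_75pct': 5}
12
```

Reading: the 5 planted links are detected at every kernel, but from
10 mm upward the subnetwork inflates with neighbour links mixed in by
the wide kernels — at 16 mm the detected subnetwork has 17 links, and
the most distant kernel pair (0 vs 16 mm) differs in 12 link positions.
The kernel choice visibly reshapes the "finding" even when the true
contrast is fixed.

The same pipeline is scriptable from the shell:

```bash
smoothsweep run --config cfg.toml --out results_dir --seed 9
smoothsweep simulate --out sim --seed 3
smoothsweep smooth --in sim/sub-000_bold.nii --fwhm 8 --out sub-000_s8.nii
```

## The analysis scripts

`analysis/01…05` are thin numbered drivers over the library, each
writing tables under `results/`: cohort generation and ground truth,
smoothness-estimator validation, NBS type-I calibration (500 null
cohorts), planted-subnetwork recovery power (50 runs), and the headline
kernel sweep.

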