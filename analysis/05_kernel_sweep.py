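#!/usr/bin/env python
"""The headline experiment: how the detected subnetwork changes with the
smoothing kernel.

A planted volume-mode cohort is swept over kernels 0-16 mm; per kernel
the pipeline smooths the original volumes, extracts ROI connectivity,
cleans nuisance structure and runs the network-based statistic.  Writes
the per-kernel subnetworks, effect-size grid, link persistence, Hamming
similarity matrix and length-F rank correlations under results/sweep/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from smoothsweep.io import write_matrix
from smoothsweep.nbs import NBSConfig
from smoothsweep.smoothing import KernelSweep
from smoothsweep.sweep import SweepConfig, run_sweep
from smoothsweep.synthetic import CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "sweep"
OUT.mkdir(parents=True, exist_ok=True)

spec = CohortSpec(n_per_group=10, n_rois=12, T=256, delta=0.5, r0=0.1,
                  voxel_noise_sd=0.5, intrinsic_fwhm=3.0, seed=90)
cohort = generate_cohort(spec, mode="volume")
sweep = KernelSweep((0.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0))
res = run_sweep(cohort, sweep, SweepConfig(nbs=NBSConfig(12.25, 300, 0.05), seed=17))

write_matrix(res.hamming.astype(float), OUT / "hamming.tsv")
res.d_grid.to_csv(OUT / "d_grid.tsv", sep="\t", float_format="%.6g")
res.persistence.to_csv(OUT / "persistence.tsv", sep="\t", index=False)
pd.DataFrame(
    {"fwhm": res.fwhms, "n_links": res.n_links, "rho_length_vs_f": np.round(res.rho, 4),
     "mean_detected_length_mm": [
         round(float(l.mean()), 2) if l.size else float("nan")
         for l in res.length_distributions
     ]}
).to_csv(OUT / "per_kernel_summary.tsv", sep="\t", index=False)

planted = set(cohort.ground_truth.planted_links)
print("per-kernel subnetwork link counts:", dict(zip(res.fwhms, res.n_links)))
print("links significant at all kernels:", res.persistence_summary["n_links_all_kernels"],
      f"(planted: {len(planted)})")
print("links significant at >=75% of kernels:", res.persistence_summary["n_links_75pct"])
print("max Hamming distance between kernel pairs:", int(res.hamming.max()),
      f"(most distant pair: FWHMs "
      f"{tuple(res.fwhms[i] for i in np.unravel_index(res.hamming.argmax(), res.hamming.shape))})")
print("wide kernels admit extra neighbour links into the subnetwork while the "
      "planted core persists; tables written to", OUT)
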