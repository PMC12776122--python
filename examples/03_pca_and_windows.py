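"""Reduce condition-averaged slope maps with spatial PCA and build the
stimulus-anchored 160-ms analysis windows.

The spatial PCA (covariance extraction, Empirical Kaiser Criterion
retention, varimax rotation, 1/x variance filter) recovers the generator's
three scalp sources; the temporal PCA's FWHM motivates the 160-ms window
width used for statistics.
"""

import numpy as np

from aperislope import SimConfig, run_spatial_pca, run_temporal_pca, segment_windows
from aperislope.layout import default_layout
from aperislope.pipeline import RunConfig, compute_slope_maps

maps, trials, logs = compute_slope_maps(
    RunConfig(sim=SimConfig(n_participants=3, n_trials_per_cell=6, rng_seed=2))
)
print("per-participant retained epochs:",
      {p: f"{v['n_retained']}/{v['n_epochs']}" for p, v in logs.items()})

model = run_spatial_pca(maps, layout=default_layout())
print(f"\nspatial PCA: EKC retained {model.n_ekc} components")
for j in range(model.loadings_rotated.shape[1]):
    mark = "kept" if model.retained[j] else "dropped (1/x filter)"
    print(f"  {model.names[j]:<14s} share of solution variance = "
          f"{model.explained_of_solution[j]:.2f}  [{mark}]")

tmodel, tcomps = run_temporal_pca(maps)
if tcomps:
    fwhms = [c.fwhm_ms for c in tcomps]
    print(f"\ntemporal PCA: {len(tcomps)} retained components, "
          f"mean FWHM = {np.mean(fwhms):.0f} ms")

ws = segment_windows(crop_ms=(-300.0, 1300.0), width_ms=160.0)
print(f"\n160-ms windows anchored at stimulus onset ({len(ws.windows)} windows):")
print("  " + "  ".join(ws.labels))
print("square brackets include the boundary; the pre-stimulus window is the")
print("baseline for the stimulus-induced steepening contrasts.")
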