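"""Post-process single-technique suitability models into a binary range.

Walks the whole chain for one toy species: evaluate members (TSS/AUC),
filter, build the TSS-weighted ensemble, binarise at the 10-percentile
presence threshold, clip to occurrences, and restrict a future projection
by dispersal distance.
"""

import numpy as np

from parep import (
    GridSpec,
    SuitabilityMap,
    apply_dispersal,
    average_gcms,
    clip_to_occurrences,
    ensemble,
    evaluate_auc,
    evaluate_tss,
    filter_members,
    threshold_10pct,
)

rng = np.random.default_rng(0)
grid = GridSpec(20, 20, cell_side=2.0)
cx, cy = grid.cell_centers()

# a "true" suitability bump plus technique-specific noise
truth = np.exp(-(((cx - 12) ** 2 + (cy - 25) ** 2) / 150.0)).reshape(grid.shape)
members = []
for tag, noise in [("maxent", 0.05), ("rf", 0.08), ("brt", 0.30)]:
    vals = np.clip(truth + rng.normal(0, noise, grid.shape), 0, 1)
    m = SuitabilityMap("sp1", tag, vals, grid)
    # evaluate against points sampled from the truth
    pres = np.column_stack([cx, cy])[truth.ravel() > 0.5][:20]
    abse = np.column_stack([cx, cy])[truth.ravel() < 0.1][:40]
    m.tss = evaluate_tss(vals > 0.4, pres, abse, grid)
    m.auc = evaluate_auc(vals, pres, abse, grid)
    print(f"{tag:<8} TSS {m.tss:5.2f}  AUC {m.auc:5.2f}")
    members.append(m)

kept = filter_members(members)
print(f"members kept by the TSS>0.8 & AUC>0.8 filter: "
      f"{[m.technique_tag for m in kept]}")

ens = ensemble(kept)
occ = np.column_stack([cx, cy])[truth.ravel() > 0.6][:15]
binary = threshold_10pct(ens, occ)
print(f"ensemble binarised at the 10-percentile presence threshold: "
      f"{binary.n_cells} cells ({binary.range_km2:.0f} km2)")

clipped = clip_to_occurrences(binary, occ, max_dist=10.0)
print(f"after clipping to within 10 km of occurrences: "
      f"{clipped.n_cells} cells")

# a future projection: the bump moves and two GCMs disagree slightly
fut_truth = np.exp(-(((cx - 20) ** 2 + (cy - 25) ** 2) / 150.0))
gcms = [
    SuitabilityMap("sp1", g, np.clip(fut_truth.reshape(grid.shape)
                                     + rng.normal(0, s, grid.shape), 0, 1),
                   grid)
    for g, s in [("hadgem2", 0.04), ("mpi", 0.04)]
]
fut = threshold_10pct(average_gcms(gcms), occ, scenario="rcp45")
restricted = apply_dispersal(fut, clipped, max_dist=6.0)
print(f"future range {fut.n_cells} cells; within 6 km dispersal of the "
      f"current range: {restricted.n_cells} cells")
# The noisy technique fails the filter; the dispersal restriction removes
# the part of the future range the species cannot plausibly reach.
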