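"""Seed-based resting-state network maps and their thresholding.

Simulates one control run, takes the right anterior cingulate region
(ACAr) as the seed, correlates its mean time course with every brain
voxel, and applies the joint magnitude (|r| >= 0.15) + significance
(p < 0.05, uncorrected) threshold.  Prints how much of the brain the
thresholded network covers and which regions it touches most.
"""
import numpy as np

from mousefc import connectome, synth

atlas, table = synth.build_synthetic_atlas(dims=(24, 12, 6), n_regions=20,
                                           rng_seed=0)
template = synth.cohort_correlation_template("control", table)
vol = synth.simulate_bold_run(atlas, template, T=310, rng_seed=7)

seed_id = int(table.loc[table.acronym == "ACAr", "id"].iloc[0])
series = connectome.region_time_series(vol, atlas)
seed_row = int(np.flatnonzero(series.region_ids == seed_id)[0])
smap = connectome.seed_correlation_map(vol, series.values[seed_row],
                                       mask=atlas.mask,
                                       seed_region_id=seed_id)
kept = connectome.threshold_seed_map(smap, r_min=0.15, alpha=0.05)

n_brain = int(atlas.mask.sum())
n_kept = int(np.isfinite(kept.r).sum())
print(f"seed ACAr: {n_kept}/{n_brain} brain voxels "
      f"({100 * n_kept / n_brain:.0f}%) survive |r|>=0.15 and p<0.05")

cover = []
for rid, acr in zip(table.id, table.acronym):
    sel = atlas.labels == rid
    frac = np.isfinite(kept.r[sel]).mean()
    cover.append((frac, acr))
print("regions most covered by the ACAr network "
      "(fraction of region voxels kept):")
for frac, acr in sorted(cover, reverse=True)[:5]:
    print(f"  {acr:<6} {frac:.2f}")
print("\nThe seed's own family (isocortex) dominates: those regions share "
      "the seed's\nlatent network signal, exactly what a resting-state "
      "network map should show.")
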