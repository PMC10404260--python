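"""Simulate a synthetic mouse cohort and inspect its connectivity structure.

Builds a desk-size atlas (20 regions), the three cohort correlation
templates, and one BOLD run per cohort; prints each template's thresholded
global connectivity strength next to the value measured from the simulated
run.  The control/treated templates are calibrated to 0.23/0.25; the
mutant is attenuated and lands below control.
"""
import numpy as np

from mousefc import connectome, synth

atlas, table = synth.build_synthetic_atlas(dims=(24, 12, 6), n_regions=20,
                                           rng_seed=0)
print(f"atlas: {atlas.dims} voxels, {atlas.n_regions} regions, "
      f"{int(atlas.mask.sum())} brain voxels")
print(f"families: {', '.join(dict.fromkeys(table.family))}")

templates = synth.cohort_templates(table)
print(f"\n{'cohort':<10} {'template strength':>18} {'measured (1 run)':>18}")
for cohort, tpl in templates.items():
    vol = synth.simulate_bold_run(atlas, tpl, T=310, rng_seed=1)
    series = connectome.region_time_series(vol, atlas)
    cm = connectome.connectivity_matrix(series)
    measured = connectome.global_connectivity_strength(cm, r_min=0.15)
    print(f"{cohort:<10} {tpl.strength(0.15):>18.3f} {measured:>18.3f}")

print("\nThe strength statistic is the mean of region-pair correlations "
      "strictly above 0.15;\nmutant < control <= treated mirrors the "
      "disease model and its rescue by gene therapy.")
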