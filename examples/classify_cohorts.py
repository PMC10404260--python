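"""Bagged logistic-LASSO classification of the three cohorts.

Runs the classifier chain at desk scale: simulate a cohort of runs, build
multi-resolution grid features of the ACAr/CAr/MDr seed maps, fit one
bagged multinomial LASSO ensemble per seed (B=20 here for speed), combine
them by probability averaging, and print the one-vs-rest AUCs and the
most frequently selected predictor networks.
"""
import numpy as np

from mousefc import netclass
from mousefc.config import PipelineConfig
from mousefc.pipeline import build_bundle, classify, process_runs

cfg = PipelineConfig(
    outdir="mousefc_out", seed=0, dims=(24, 12, 6), n_regions=20, T=310,
    B=20, lambda_strategy="shared", cv_folds=2, lam_grid_size=5,
    run_plan={"control": [3, 2], "mutant": [3, 2], "treated": [3, 2]},
)
bundle = build_bundle(cfg)
runs = process_runs(cfg, bundle)
print(f"simulated {len(runs.run_ids)} runs, "
      f"{runs.features['ACAr'].shape[1]} grid features per seed map")

clf = classify(cfg, bundle, runs)
classes = [r.class_label for r in clf["rocs"]["combined"]]
print(f"\n{'classifier':<10} " + " ".join(f"{c:>9}" for c in classes))
for label, rocs in clf["rocs"].items():
    aucs = " ".join(f"{100 * r.auc:>8.1f}%" for r in rocs)
    print(f"{label:<10} {aucs}")

report = clf["predictor_report"]
if len(report):
    print("\nsignificant predictor networks (selection freq >= 0.5, "
          "best pairwise Welch p < 0.001):")
    cols = ["seed", "predictor_acronym", "selection_freq", "p_value",
            "direction"]
    print(report[cols].head(8).to_string(index=False))
print("\nAUC = 100% per class is expected here: the synthetic cohorts are "
      "strong-separation\nby construction, so this demonstrates the "
      "machinery, not real-data difficulty.")
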