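"""End-to-end orchestration: synthesis -> (preproc) -> connectome ->
classification -> cohort statistics -> figures, with a JSON manifest.

Runs are simulated, preprocessed and reduced one at a time (region
series, connectivity matrix, seed maps, grid features), so a full cohort
never has to sit in memory as raw 4-D data.
"""
from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohortstats, connectome, netclass, preproc, synth, viz
from .config import PipelineConfig
from .types import COHORTS, ConnMatrix, SeedMap


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class CohortBundle:
    """Static study material: atlas, regions, templates, design, assays."""

    atlas: object
    region_table: pd.DataFrame
    templates: dict
    design: pd.DataFrame
    assays: pd.DataFrame
    params: synth.TemplateParams


@dataclass
class RunResults:
    """Per-run derived quantities for the whole cohort design."""

    conn_matrices: list = field(default_factory=list)
    strengths: list = field(default_factory=list)       # per run
    seed_maps: dict = field(default_factory=dict)       # acr -> list of SeedMap
    features: dict = field(default_factory=dict)        # acr -> (n_runs, p)
    cohorts: list = field(default_factory=list)         # per run
    subjects: list = field(default_factory=list)
    run_ids: list = field(default_factory=list)
    grid_spec: object = None


def build_bundle(cfg: PipelineConfig) -> CohortBundle:
    atlas, table = synth.build_synthetic_atlas(
        dims=cfg.dims, n_regions=cfg.n_regions, rng_seed=cfg.seed)
    params = synth.TemplateParams(**cfg.template) if cfg.template \
        else synth.TemplateParams()
    templates = {c: synth.cohort_correlation_template(c, table, params)
                 for c in COHORTS}
    design = synth.make_cohort_design(cfg.run_plan)
    assays = synth.simulate_assays(rng_seed=cfg.seed)
    return CohortBundle(atlas=atlas, region_table=table, templates=templates,
                        design=design, assays=assays, params=params)


def process_runs(cfg: PipelineConfig, bundle: CohortBundle) -> RunResults:
    """Simulate and reduce every run of the cohort design."""
    atlas, table = bundle.atlas, bundle.region_table
    acr_to_id = dict(zip(table["acronym"], table["id"]))
    for acr in cfg.seed_regions:
        if acr not in acr_to_id:
            raise ValueError(f"seed region {acr!r} not in the region table")
    spec = netclass.GridSpec(map_dims=atlas.dims, cube_dims=cfg.cubes)
    out = RunResults(grid_spec=spec)
    out.seed_maps = {a: [] for a in cfg.seed_regions}
    feats = {a: [] for a in cfg.seed_regions}
    ids = atlas.region_ids
    row_of = {int(r): i for i, r in enumerate(ids)}

    drift = synth.DriftSpec() if cfg.drift else None
    motion = synth.MotionSpec() if cfg.motion else None
    for run_idx, run in bundle.design.iterrows():
        rng = synth.substream(cfg.seed, "run", run_idx)
        vol = synth.simulate_bold_run(
            atlas, bundle.templates[run.cohort], T=cfg.T, tr_s=cfg.tr_s,
            noise_sd=cfg.noise_sd, drift_spec=drift, motion_spec=motion,
            rng_seed=rng)
        if cfg.preprocess:
            if cfg.motion:
                vol, _ = preproc.realign(vol, passes=1)
            vol = preproc.remove_drift(vol)
        series = connectome.region_time_series(vol, atlas)
        cm = connectome.connectivity_matrix(series)
        out.conn_matrices.append(cm)
        out.strengths.append(connectome.global_connectivity_strength(
            cm, r_min=cfg.r_threshold))
        for acr in cfg.seed_regions:
            seed_row = row_of[acr_to_id[acr]]
            smap = connectome.seed_correlation_map(
                vol, series.values[seed_row], mask=atlas.mask,
                seed_region_id=acr_to_id[acr])
            out.seed_maps[acr].append(smap)
            fv = netclass.grid_features(smap, spec, sample_id=run.run_id,
                                        seed_acronym=acr)
            feats[acr].append(fv)
        out.cohorts.append(run.cohort)
        out.subjects.append(run.subject_id)
        out.run_ids.append(run.run_id)
    out.features = {a: netclass.feature_matrix(v) for a, v in feats.items()}
    return out


def _aggregate_to_subjects(runs: RunResults):
    """Average run-level features within subject (unit='subject')."""
    subjects = pd.unique(np.asarray(runs.subjects))
    X_per_seed = {}
    for acr, X in runs.features.items():
        rows = [X[np.asarray(runs.subjects) == s].mean(axis=0)
                for s in subjects]
        X_per_seed[acr] = np.stack(rows)
    y = np.array([np.asarray(runs.cohorts)[
        np.asarray(runs.subjects) == s][0] for s in subjects])
    return X_per_seed, y, list(subjects)


def classify(cfg: PipelineConfig, bundle: CohortBundle, runs: RunResults):
    """Per-seed bagged ensembles, the combined classifier, ROC and the
    significant-predictor report."""
    if cfg.unit == "subject":
        X_per_seed, y, sample_ids = _aggregate_to_subjects(runs)
    else:
        X_per_seed = runs.features
        y = np.asarray(runs.cohorts)
        sample_ids = runs.run_ids
    ensembles, rocs, predictors = {}, {}, []
    for acr, X in X_per_seed.items():
        grid = netclass.default_lambda_grid(X, y, n=cfg.lam_grid_size)
        ens = netclass.bag_ensemble(
            X, y, B=cfg.B, frac=cfg.frac, rng_seed=cfg.seed,
            lambda_strategy=cfg.lambda_strategy, lam_grid=grid,
            cv_folds=cfg.cv_folds, tol=cfg.lasso_tol)
        ensembles[acr] = ens
        probs = netclass.ensemble_predict(ens, X)
        rocs[acr] = netclass.roc_auc(probs, y, classes=ens.classes)
        rep = netclass.significant_predictors(
            ens, X, y, runs.grid_spec, bundle.atlas, bundle.region_table,
            seed_acronym=acr, alpha=cfg.predictor_alpha)
        predictors.append(rep)
    combined_probs, classes = netclass.combine_ensembles(ensembles, X_per_seed)
    rocs["combined"] = netclass.roc_auc(combined_probs, y, classes=classes)
    predictors = [p for p in predictors if len(p)]
    report = (pd.concat(predictors, ignore_index=True) if predictors
              else pd.DataFrame())
    return dict(ensembles=ensembles, rocs=rocs, predictor_report=report,
                combined_probs=combined_probs, y=y, sample_ids=sample_ids,
                X_per_seed=X_per_seed)


def cohort_statistics(cfg: PipelineConfig, bundle: CohortBundle,
                      runs: RunResults) -> dict:
    """Assay and connectivity-strength group statistics."""
    assays = bundle.assays
    idua = [assays.loc[assays.cohort == c, "idua_value"].to_numpy()
            for c in COHORTS]
    gag = [assays.loc[assays.cohort == c, "gag_value"].to_numpy()
           for c in COHORTS]
    strength = [np.asarray(runs.strengths)[np.asarray(runs.cohorts) == c]
                for c in COHORTS]
    idua_gate = cohortstats.assumption_gate(idua)
    gag_gate = cohortstats.assumption_gate(gag)
    kw_idua = cohortstats.kruskal_wallis(idua)
    anova_gag = cohortstats.one_way_anova(gag)
    anova_strength = cohortstats.one_way_anova(strength)
    gag_means = [g.mean() for g in gag]
    strength_means = [s.mean() for s in strength]
    r, r2 = cohortstats.correlation_r2(gag_means, strength_means)
    summaries = {c: {"idua": vars(cohortstats.group_summary(i, c)),
                     "gag": vars(cohortstats.group_summary(g, c)),
                     "strength": vars(cohortstats.group_summary(s, c))}
                 for c, i, g, s in zip(COHORTS, idua, gag, strength)}
    return {
        "idua_gate": idua_gate.test, "gag_gate": gag_gate.test,
        "kw_idua": {"H": kw_idua.statistic, "df": kw_idua.df,
                    "p": kw_idua.p},
        "dunn_idua": {f"{COHORTS[i]}|{COHORTS[j]}": p for (i, j), p
                      in cohortstats.pairwise_posthoc(idua, "dunn").items()},
        "anova_gag": {"F": anova_gag.statistic, "df": anova_gag.df,
                      "p": anova_gag.p},
        "anova_strength": {"F": anova_strength.statistic,
                           "df": anova_strength.df, "p": anova_strength.p},
        "gag_fold_mutant_over_control": gag_means[1] / gag_means[0],
        "gag_strength_r": r, "gag_strength_r2": r2,
        "strength_by_cohort": dict(zip(COHORTS, strength_means)),
        "summaries": summaries,
    }


def render_report(cfg: PipelineConfig, bundle: CohortBundle,
                  runs: RunResults, clf: dict, outdir: Path) -> list:
    """Figures: cohort matrices, connectogram, group-map overlay, ROC."""
    written = []
    cohorts = np.asarray(runs.cohorts)
    avg = {}
    for c in COHORTS:
        mats = [m for m, cc in zip(runs.conn_matrices, cohorts) if cc == c]
        avg[c] = connectome.cohort_average_matrix(mats)
        path = outdir / f"matrix_{c}.png"
        viz.render_matrix_heatmap(avg[c], path)
        written.append(path.name)
    cg = viz.build_connectogram(avg["control"], bundle.region_table,
                                threshold=cfg.connectogram_threshold,
                                seed_regions=list(cfg.seed_regions))
    viz.render_connectogram(cg, outdir / "connectogram_control.png")
    written.append("connectogram_control.png")

    acr0 = cfg.seed_regions[0]
    ctrl_maps = [m for m, cc in zip(runs.seed_maps[acr0], cohorts)
                 if cc == "control"]
    if len(ctrl_maps) >= 2:
        gmap = connectome.group_mean_map(ctrl_maps)
        anatomy = synth.reference_image(bundle.atlas)
        viz.render_overlay(gmap, anatomy, outdir / f"groupmap_{acr0}.png",
                           r_min=cfg.r_threshold)
        written.append(f"groupmap_{acr0}.png")

    from matplotlib.figure import Figure
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    fig = Figure(figsize=(5, 5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for label, rocs in clf["rocs"].items():
        for rr in rocs:
            if np.isfinite(rr.auc) and label == "combined":
                ax.plot(rr.fpr, rr.tpr,
                        label=f"{rr.class_label} AUC={rr.auc * 100:.1f}%")
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.savefig(str(outdir / "roc_combined.png"), dpi=120,
                metadata={"Software": None})
    written.append("roc_combined.png")
    return written


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Execute the pipeline and write a manifest; returns the manifest.

    ``stages`` limits which outputs are produced (any of ``simulate``,
    ``preprocess``, ``connectome``, ``classify``, ``stats``, ``report``);
    upstream results are always computed in memory as needed.
    """
    from . import io as mio
    all_stages = ("simulate", "preprocess", "connectome", "classify",
                  "stats", "report")
    wanted = set(all_stages if stages is None else stages)
    unknown = wanted - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}

    try:
        bundle = build_bundle(cfg)
        record("simulate", "ok", n_cohorts=len(COHORTS),
               n_regions=int(bundle.atlas.n_regions),
               n_runs=int(len(bundle.design)),
               template_strengths={c: t.strength(cfg.r_threshold)
                                   for c, t in bundle.templates.items()})
        if "simulate" in wanted:
            mio.save_atlas(bundle.atlas, outdir / "atlas.nii.gz")
            mio.save_region_table(bundle.region_table, outdir / "regions.tsv")
            bundle.design.to_csv(outdir / "design.csv", index=False)
            bundle.assays.to_csv(outdir / "assays.csv", index=False)
    except Exception as exc:
        record("simulate", "failed", error=str(exc))
        _write_manifest(manifest, outdir)
        raise StageError("simulate", exc) from exc

    try:
        runs = process_runs(cfg, bundle)
        record("preprocess", "ok" if cfg.preprocess else "skipped")
        strengths = pd.DataFrame({"run_id": runs.run_ids,
                                  "cohort": runs.cohorts,
                                  "strength": runs.strengths})
        record("connectome", "ok",
               mean_strength_by_cohort={
                   c: float(strengths.loc[strengths.cohort == c,
                                          "strength"].mean())
                   for c in COHORTS})
        if "connectome" in wanted:
            strengths.to_csv(outdir / "global_strength.csv", index=False)
            for c in COHORTS:
                mats = [m for m, cc in zip(runs.conn_matrices, runs.cohorts)
                        if cc == c]
                mio.save_conn_matrix(connectome.cohort_average_matrix(mats),
                                     bundle.region_table,
                                     outdir / f"connectome_{c}.tsv")
    except Exception as exc:
        record("connectome", "failed", error=str(exc))
        _write_manifest(manifest, outdir)
        raise StageError("connectome", exc) from exc

    clf = None
    if wanted & {"classify", "report"}:
        try:
            clf = classify(cfg, bundle, runs)
            aucs = {label: {str(r.class_label): r.auc for r in rocs
                            if np.isfinite(r.auc)}
                    for label, rocs in clf["rocs"].items()}
            record("classify", "ok", B=cfg.B,
                   n_seed_classifiers=len(cfg.seed_regions),
                   combined=True, auc=aucs)
            if "classify" in wanted:
                for acr, ens in clf["ensembles"].items():
                    mio.save_ensemble_json(ens, outdir / f"ensemble_{acr}.json")
                clf["predictor_report"].to_csv(
                    outdir / "significant_networks.tsv", sep="\t", index=False)
                rows = []
                for label, rocs in clf["rocs"].items():
                    for rr in rocs:
                        rows.append({"classifier": label,
                                     "class": str(rr.class_label),
                                     "auc": rr.auc})
                pd.DataFrame(rows).to_csv(outdir / "roc_auc.csv", index=False)
        except Exception as exc:
            record("classify", "failed", error=str(exc))
            _write_manifest(manifest, outdir)
            raise StageError("classify", exc) from exc

    if "stats" in wanted:
        try:
            stats_out = cohort_statistics(cfg, bundle, runs)
            record("stats", "ok", **stats_out)
            (outdir / "cohort_stats.json").write_text(
                json.dumps(stats_out, indent=2, default=float))
        except Exception as exc:
            record("stats", "failed", error=str(exc))
            _write_manifest(manifest, outdir)
            raise StageError("stats", exc) from exc

    if "report" in wanted:
        try:
            figures = render_report(cfg, bundle, runs, clf, outdir)
            record("report", "ok", figures=figures)
        except Exception as exc:
            record("report", "failed", error=str(exc))
            _write_manifest(manifest, outdir)
            raise StageError("report", exc) from exc

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
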