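"""Network classifiers from multi-resolution grid features of seed maps.

The classifier mirrors the study design: each seed-based correlation map
is segmented into cubic grids of several sizes (3x2x1, 6x4x2 and 12x8x4
voxels by default — sizes that tile the 96x48x12 acquisition matrix
exactly); the mean correlation within each cube, concatenated across
resolutions, is the feature vector.  A bootstrap-aggregated ensemble of
multinomial logistic LASSO models (stratified 80% subsamples, one
penalized fit each, probabilities averaged) classifies cohorts; features
selected by many ensemble members and separating cohorts at p < 0.001
(Welch t, best pairwise contrast) are reported as significant predictor
networks, and performance is summarized by one-vs-rest ROC/AUC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import _lasso
from .synth import substream
from .types import AtlasVolume, SeedMap

DEFAULT_CUBES = ((3, 2, 1), (6, 4, 2), (12, 8, 4))
DEFAULT_B = 1000
DEFAULT_FRAC = 0.8


# ---------------------------------------------------------------------------
# Multi-resolution grid features
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Cubic-grid segmentation of a 3-D map at several resolutions.

    Features are ordered resolution-major (in the listed cube order) and
    x-fastest within a resolution.
    """

    map_dims: tuple
    cube_dims: tuple = DEFAULT_CUBES

    def __post_init__(self):
        self.map_dims = tuple(int(d) for d in self.map_dims)
        self.cube_dims = tuple(tuple(int(c) for c in cd) for cd in self.cube_dims)
        for cd in self.cube_dims:
            if any(c < 1 for c in cd):
                raise ValueError("cube dimensions must be positive")
            if any(c > d for c, d in zip(cd, self.map_dims)):
                raise ValueError(f"cube {cd} larger than map {self.map_dims}")

    @property
    def grid_shapes(self):
        return [tuple(-(-d // c) for d, c in zip(self.map_dims, cd))
                for cd in self.cube_dims]

    @property
    def counts(self):
        return [int(np.prod(g)) for g in self.grid_shapes]

    @property
    def n_features(self) -> int:
        return int(sum(self.counts))

    def feature_info(self, index: int):
        """(resolution index, cube multi-index, voxel slices) of a feature."""
        if not (0 <= index < self.n_features):
            raise IndexError("feature index out of range")
        offset = 0
        for res, (count, shape, cd) in enumerate(
                zip(self.counts, self.grid_shapes, self.cube_dims)):
            if index < offset + count:
                lin = index - offset
                nx, ny, nz = shape
                ix = lin % nx
                iy = (lin // nx) % ny
                iz = lin // (nx * ny)
                slices = tuple(
                    slice(i * c, min((i + 1) * c, d))
                    for i, c, d in zip((ix, iy, iz), cd, self.map_dims))
                return res, (ix, iy, iz), slices
            offset += count
        raise AssertionError("unreachable")


@dataclass
class FeatureVector:
    values: np.ndarray
    missing: np.ndarray     # cubes with no valid voxel (stored as 0)
    spec: GridSpec
    sample_id: str = ""
    seed_acronym: str = ""


def grid_features(seed_map, spec: GridSpec, sample_id: str = "",
                  seed_acronym: str = "") -> FeatureVector:
    """Mean correlation per cube, across all grid resolutions.

    NaN voxels (outside the brain mask or undefined correlations) are
    ignored; cubes with no valid voxel yield 0 and a missingness flag.
    """
    vals = seed_map.r if isinstance(seed_map, SeedMap) else np.asarray(seed_map)
    if vals.shape != spec.map_dims:
        raise ValueError(f"map dims {vals.shape} != spec dims {spec.map_dims}")
    parts, missing_parts = [], []
    for cd, shape in zip(spec.cube_dims, spec.grid_shapes):
        cx, cy, cz = cd
        nx, ny, nz = shape
        padded = np.full((nx * cx, ny * cy, nz * cz), np.nan)
        padded[:vals.shape[0], :vals.shape[1], :vals.shape[2]] = vals
        blocks = padded.reshape(nx, cx, ny, cy, nz, cz)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(blocks, axis=(1, 3, 5))
        flat = means.ravel(order="F")
        miss = ~np.isfinite(flat)
        flat = np.where(miss, 0.0, flat)
        parts.append(flat)
        missing_parts.append(miss)
    return FeatureVector(values=np.concatenate(parts),
                         missing=np.concatenate(missing_parts),
                         spec=spec, sample_id=sample_id,
                         seed_acronym=seed_acronym)


def feature_matrix(feature_vectors) -> np.ndarray:
    """Stack feature vectors into an (n_samples, n_features) design."""
    return np.stack([fv.values for fv in feature_vectors], axis=0)


def cube_region_acronyms(spec: GridSpec, feature_index: int,
                         atlas: AtlasVolume, region_table: pd.DataFrame,
                         top: int = 3):
    """Region acronyms overlapping a cube, by decreasing voxel count
    (majority label first)."""
    _, _, slices = spec.feature_info(feature_index)
    block = atlas.labels[slices]
    ids, counts = np.unique(block[block > 0], return_counts=True)
    if ids.size == 0:
        return []
    order = np.argsort(counts)[::-1][:top]
    lut = dict(zip(region_table["id"], region_table["acronym"]))
    return [lut[int(i)] for i in ids[order]]


# ---------------------------------------------------------------------------
# Penalized multinomial logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    """One penalized multinomial fit, coefficients on the original scale."""

    coef: np.ndarray        # (K, p)
    intercept: np.ndarray   # (K,)
    classes: np.ndarray
    lam: float
    method: str = "multinomial"

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.intercept[None, :] + np.asarray(X) @ self.coef.T

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.decision(X)
        if self.method == "ovr":
            s = 1.0 / (1.0 + np.exp(-eta))
            return s / s.sum(axis=1, keepdims=True)
        m = eta.max(axis=1, keepdims=True)
        p = np.exp(eta - m)
        return p / p.sum(axis=1, keepdims=True)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _encode(y, classes=None):
    y = np.asarray(y)
    classes = np.unique(y) if classes is None else np.asarray(classes)
    if np.setdiff1d(np.unique(y), classes).size:
        raise ValueError("labels outside the declared class list")
    index = {c: i for i, c in enumerate(classes)}
    codes = np.array([index[v] for v in y])
    onehot = np.eye(len(classes))[codes]
    return classes, codes, onehot


def fit_logistic_lasso(X, y, lam: float, classes=None, tol: float = 1e-6,
                       max_outer: int = 500, method: str = "multinomial",
                       warm: tuple | None = None) -> LassoFit:
    """Penalized multinomial logistic regression.

    Maximizes ``loglik - lam * sum|w|`` by coordinate descent on
    internally standardized features; returned coefficients are on the
    original feature scale.  ``method="ovr"`` fits one-vs-rest binary
    models instead of the joint multinomial.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    classes, codes, onehot = _encode(y, classes)
    if np.unique(codes).size < 2:
        raise ValueError("need at least 2 classes present in y")
    Xs, mu, sd = _standardize(X)
    lam_eff = max(lam, 1e-10)  # lam=0 is honored up to the iteration cap
    if method == "multinomial":
        W, b, _ = _lasso.fit_multinomial_cd(Xs, onehot, lam_eff, tol=tol,
                                            max_outer=max_outer, warm=warm)
    elif method == "ovr":
        K = len(classes)
        W = np.zeros((K, X.shape[1]))
        b = np.zeros(K)
        for k in range(K):
            oh = np.column_stack([1.0 - onehot[:, k], onehot[:, k]])
            Wk, bk, _ = _lasso.fit_multinomial_cd(Xs, oh, lam_eff, tol=tol,
                                                  max_outer=max_outer)
            W[k] = Wk[1] - Wk[0]
            b[k] = bk[1] - bk[0]
    else:
        raise ValueError("method must be 'multinomial' or 'ovr'")
    coef = W / sd[None, :]
    intercept = b - coef @ mu
    return LassoFit(coef=coef, intercept=intercept, classes=classes,
                    lam=lam, method=method)


def _deviance(fit: LassoFit, X, onehot) -> float:
    p = np.clip(fit.predict_proba(X), 1e-12, None)
    return float(-2.0 * (onehot * np.log(p)).sum())


def default_lambda_grid(X, y, n: int = 8, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from the data's lambda_max down to ratio*lambda_max."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    _, _, onehot = _encode(y)
    lmax = _lasso.lambda_max(Xs, onehot)
    return lmax * np.logspace(0, np.log10(ratio), n)


def select_lambda(X, y, folds: int = 5, lam_grid=None,
                  tol: float = 1e-4) -> float:
    """Cross-validated lambda: minimal mean held-out deviance, ties broken
    toward the larger (sparser) value.  Folds are stratified; the fold
    count is reduced when a class is too small to appear in every fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if lam_grid is None:
        lam_grid = default_lambda_grid(X, y)
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))[::-1]
    if lam_grid.size == 1:
        return float(lam_grid[0])
    classes, codes, _ = _encode(y)
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 members for stratified CV")
    folds = int(min(folds, counts.min()))
    # deterministic stratified folds: round-robin within class
    fold_of = np.empty(len(y), dtype=int)
    for k in range(len(classes)):
        idx = np.flatnonzero(codes == k)
        fold_of[idx] = np.arange(idx.size) % folds
    dev = np.zeros(lam_grid.size)
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        _, _, onehot_te = _encode(y[te], classes)
        warm = None
        for i, lam in enumerate(lam_grid):  # warm-started path, dense -> sparse
            fit = fit_logistic_lasso(X[tr], y[tr], lam, classes=classes,
                                     tol=tol, warm=warm)
            Xs, mu, sd = _standardize(X[tr])
            warm = (fit.coef * sd[None, :], fit.intercept + fit.coef @ mu)
            dev[i] += _deviance(fit, X[te], onehot_te)
    dev /= folds
    best = np.flatnonzero(dev <= dev.min() + 1e-9)
    return float(lam_grid[best[0]])  # grid is descending: first = largest


# ---------------------------------------------------------------------------
# Bootstrap aggregating
# ---------------------------------------------------------------------------

@dataclass
class BaggedEnsemble:
    """B penalized models on stratified subsamples plus their average."""

    models: list
    selection_freq: np.ndarray
    averaged: LassoFit
    classes: np.ndarray
    B: int
    frac: float
    subsample_indices: list
    lambdas: np.ndarray
    rng_seed: int
    lambda_strategy: str = "per-bootstrap"

    @property
    def n_features(self) -> int:
        return self.averaged.coef.shape[1]


def _stratified_counts(counts: np.ndarray, n_sub: int) -> np.ndarray:
    """Largest-remainder apportionment of the subsample across classes."""
    quota = counts * n_sub / counts.sum()
    base = np.floor(quota).astype(int)
    rem = n_sub - base.sum()
    order = np.argsort(quota - base)[::-1]
    base[order[:rem]] += 1
    return np.minimum(base, counts)


def bag_ensemble(X, y, B: int = DEFAULT_B, frac: float = DEFAULT_FRAC,
                 rng_seed: int = 0, lambda_strategy: str = "per-bootstrap",
                 lam: float | None = None, lam_grid=None, cv_folds: int = 5,
                 replace: bool = False, tol: float = 1e-4,
                 method: str = "multinomial") -> BaggedEnsemble:
    """Bootstrap-aggregated logistic LASSO ensemble.

    Draws ``B`` stratified subsamples of size ``round(frac * n)`` (without
    replacement by default — the "80% subsample" scheme; classic
    with-replacement bagging via ``replace=True``), fits one penalized
    model per subsample, and stores per-feature selection frequencies and
    the coefficient-averaged model.  ``lambda_strategy`` is
    ``"per-bootstrap"`` (cross-validated within each subsample),
    ``"shared"`` (cross-validated once on the full data) or ``"fixed"``
    (use ``lam`` as given).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if B < 1:
        raise ValueError("B must be >= 1")
    classes, codes, _ = _encode(y)
    n = len(y)
    n_sub = int(round(frac * n))
    if n_sub < len(classes):
        raise ValueError("subsample smaller than the number of classes")
    counts = np.bincount(codes, minlength=len(classes))
    sub_counts = _stratified_counts(counts, n_sub)
    rng = substream(rng_seed, "bagging")

    if lambda_strategy == "shared":
        lam_shared = select_lambda(X, y, folds=cv_folds, lam_grid=lam_grid)
    elif lambda_strategy == "fixed":
        if lam is None:
            raise ValueError("lambda_strategy='fixed' needs lam")
        lam_shared = float(lam)
    elif lambda_strategy != "per-bootstrap":
        raise ValueError("unknown lambda_strategy")

    models, indices, lambdas = [], [], []
    sel_counts = np.zeros(X.shape[1])
    for _ in range(B):
        idx = []
        for k in range(len(classes)):
            pool = np.flatnonzero(codes == k)
            take = rng.choice(pool, size=int(sub_counts[k]), replace=replace)
            idx.append(take)
        idx = np.sort(np.concatenate(idx))
        if lambda_strategy == "per-bootstrap":
            lam_b = select_lambda(X[idx], y[idx], folds=cv_folds,
                                  lam_grid=lam_grid, tol=tol)
        else:
            lam_b = lam_shared
        fit = fit_logistic_lasso(X[idx], y[idx], lam_b, classes=classes,
                                 tol=tol, method=method)
        sel_counts += (fit.coef != 0.0).any(axis=0)
        models.append(fit)
        indices.append(idx)
        lambdas.append(lam_b)

    averaged = LassoFit(
        coef=np.mean([m.coef for m in models], axis=0),
        intercept=np.mean([m.intercept for m in models], axis=0),
        classes=classes, lam=float(np.mean(lambdas)), method=method)
    return BaggedEnsemble(models=models, selection_freq=sel_counts / B,
                          averaged=averaged, classes=classes, B=B, frac=frac,
                          subsample_indices=indices,
                          lambdas=np.asarray(lambdas), rng_seed=rng_seed,
                          lambda_strategy=lambda_strategy)


def ensemble_predict(ens: BaggedEnsemble, X) -> np.ndarray:
    """Class probabilities: mean of the member models' softmax outputs."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != ens.n_features:
        raise ValueError("feature length mismatch")
    probs = np.mean([m.predict_proba(X) for m in ens.models], axis=0)
    return probs / probs.sum(axis=1, keepdims=True)


def ensemble_predict_oob(ens: BaggedEnsemble, X) -> np.ndarray:
    """Out-of-bag class probabilities.

    Each sample is scored only by the member models whose subsample did
    not contain it — the honest null-calibration estimate (in-sample
    probabilities are optimistic whenever lambda is small).  Samples that
    appear in every subsample fall back to uniform probabilities.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != ens.n_features:
        raise ValueError("feature length mismatch")
    n = X.shape[0]
    K = len(ens.classes)
    acc = np.zeros((n, K))
    counts = np.zeros(n)
    for model, idx in zip(ens.models, ens.subsample_indices):
        out = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if out.size:
            acc[out] += model.predict_proba(X[out])
            counts[out] += 1
    never = counts == 0
    acc[never] = 1.0 / K
    counts[never] = 1.0
    probs = acc / counts[:, None]
    return probs / probs.sum(axis=1, keepdims=True)


def combine_ensembles(ensembles: dict, X_per_seed: dict,
                      method: str = "average", y=None, **bag_kwargs):
    """Combine per-seed ensembles into one classifier.

    ``method="average"`` (default) averages the per-seed predicted
    probabilities over the same samples; ``method="stack"`` refits one
    bagged ensemble on the concatenated per-seed features (requires
    ``y``; extra keyword arguments go to :func:`bag_ensemble`).  Returns
    ``(probs, classes)``.
    """
    if set(ensembles) != set(X_per_seed):
        raise ValueError("seed sets of ensembles and features differ")
    seeds = sorted(ensembles)
    n_samples = {s: np.asarray(X_per_seed[s]).shape[0] for s in seeds}
    if len(set(n_samples.values())) != 1:
        raise ValueError("sample sets differ across seeds")
    classes = ensembles[seeds[0]].classes
    for s in seeds:
        if not np.array_equal(ensembles[s].classes, classes):
            raise ValueError("class lists differ across seeds")
    if method == "average":
        probs = np.mean([ensemble_predict(ensembles[s], X_per_seed[s])
                         for s in seeds], axis=0)
    elif method == "stack":
        if y is None:
            raise ValueError("method='stack' requires y")
        X = np.hstack([np.asarray(X_per_seed[s], dtype=float)
                       for s in seeds])
        stacked = bag_ensemble(X, y, **bag_kwargs)
        probs = ensemble_predict(stacked, X)
    else:
        raise ValueError("method must be 'average' or 'stack'")
    return probs / probs.sum(axis=1, keepdims=True), classes


# ---------------------------------------------------------------------------
# Evaluation and reporting
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    class_label: object
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    flagged: str = ""


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    ranks = stats.rankdata(scores)  # mid-ranks: ties get half credit
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(probs: np.ndarray, y, classes=None):
    """One-vs-rest ROC per class; AUC by the rank statistic.

    Classes absent from ``y`` get NaN AUC with a flag rather than an
    exception.
    """
    probs = np.asarray(probs, dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    y = np.asarray(y)
    classes = (np.unique(y) if classes is None else np.asarray(classes))
    results = []
    for k, c in enumerate(classes):
        pos = y == c
        if pos.all() or not pos.any():
            results.append(ROCResult(class_label=c, auc=float("nan"),
                                     fpr=np.array([]), tpr=np.array([]),
                                     flagged="class absent from y"))
            continue
        auc = _rank_auc(probs[:, k], pos)
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), probs[:, k])
        results.append(ROCResult(class_label=c, auc=auc, fpr=fpr, tpr=tpr))
    return results


def significant_predictors(ens: BaggedEnsemble, X, y, spec: GridSpec,
                           atlas: AtlasVolume, region_table: pd.DataFrame,
                           seed_acronym: str = "", alpha: float = 0.001,
                           freq_floor: float = 0.5) -> pd.DataFrame:
    """Predictor networks behind the ensemble (significance report).

    Candidates are features selected in at least ``freq_floor`` of the
    member models; each is tested by Welch two-sample t-tests on all
    cohort pairs and kept when the smallest pairwise p is below ``alpha``
    (uncorrected, by design).  Cubes are mapped to atlas regions by
    majority voxel label.  An empty report is a valid outcome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    candidates = np.flatnonzero(ens.selection_freq >= freq_floor)
    rows = []
    classes = ens.classes
    for j in candidates:
        best_p, best_pair = 1.0, None
        for a in range(len(classes)):
            for b in range(a + 1, len(classes)):
                xa, xb = X[y == classes[a], j], X[y == classes[b], j]
                if len(xa) < 2 or len(xb) < 2:
                    continue
                if np.var(xa) == 0.0 and np.var(xb) == 0.0:
                    p = 1.0
                else:
                    p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
                if p < best_p:
                    best_p, best_pair = p, (classes[a], classes[b])
        if best_p >= alpha:
            continue
        res, cube_idx, _ = spec.feature_info(int(j))
        regions = cube_region_acronyms(spec, int(j), atlas, region_table)
        lut = dict(zip(region_table["acronym"], region_table["name"]))
        direction = ""
        if "control" in y and "mutant" in y:
            mu_ctrl = X[y == "control", j].mean()
            mu_mut = X[y == "mutant", j].mean()
            direction = ("lower in mutant" if mu_mut < mu_ctrl
                         else "higher in mutant")
        rows.append(dict(
            seed=seed_acronym, feature=int(j), resolution=res,
            cube_index=cube_idx,
            predictor_acronym=";".join(regions),
            predictor_name=";".join(lut.get(a, "") for a in regions),
            selection_freq=float(ens.selection_freq[j]), p_value=best_p,
            contrast=f"{best_pair[0]} vs {best_pair[1]}",
            direction=direction,
        ))
    return pd.DataFrame(rows, columns=[
        "seed", "feature", "resolution", "cube_index", "predictor_acronym",
        "predictor_name", "selection_freq", "p_value", "contrast",
        "direction"])
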