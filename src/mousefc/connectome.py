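"""Seed-based functional connectivity of parcellated BOLD runs.

Each atlas region acts as a seed: its mean time course is correlated with
every brain voxel (a resting-state network map) and with every other
region's mean course (the region-to-region correlation matrix, the
connectome).  The scalar summary statistic is the global functional
connectivity strength — the mean of region-pair correlations strictly
exceeding a threshold (0.15 here).  Group-level inference operates on
Fisher-z transformed correlations: variance-stabilized one-sample and
Welch two-sample t-tests per voxel, uncorrected, as is conventional for
exploratory seed maps.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .types import (
    AtlasVolume, ConnMatrix, GroupMap, RegionSeries, SeedMap, Volume4D,
)

DEFAULT_R_THRESHOLD = 0.15
DEFAULT_ALPHA = 0.05

_Z_CLIP = 1.0 - 1e-7  # |r| cap before arctanh


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


# ---------------------------------------------------------------------------
# Series and correlation maps
# ---------------------------------------------------------------------------

def region_time_series(vol: Volume4D, atlas: AtlasVolume,
                       region_ids=None) -> RegionSeries:
    """Mean BOLD series per region (row i = mean over voxels labeled i).

    Regions requested but absent from the atlas yield NaN rows and are
    listed in ``missing`` rather than silently returned as zeros.
    """
    if vol.dims != atlas.dims:
        raise ValueError("volume is not on the atlas grid")
    ids = (atlas.region_ids if region_ids is None
           else np.asarray(region_ids, dtype=int))
    labels = atlas.labels.ravel()
    flat = vol.data.reshape(-1, vol.n_timepoints)
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    values = np.full((ids.size, vol.n_timepoints), np.nan)
    missing = []
    for row, rid in enumerate(ids):
        lo = np.searchsorted(sorted_labels, rid)
        hi = np.searchsorted(sorted_labels, rid, side="right")
        if hi > lo:
            values[row] = flat[order[lo:hi]].mean(axis=0)
        else:
            missing.append(int(rid))
    return RegionSeries(values=values, region_ids=ids, missing=missing)


def seed_correlation_map(vol: Volume4D, seed_series: np.ndarray,
                         mask: np.ndarray | None = None,
                         seed_region_id: int = -1) -> SeedMap:
    """Pearson correlation of one seed series with every in-mask voxel.

    Constant voxel series give NaN (undefined correlation, not zero);
    a constant seed series is a usage error and raises.
    """
    seed = np.asarray(seed_series, dtype=float).ravel()
    T = vol.n_timepoints
    if seed.size != T:
        raise ValueError("seed series length must equal the number of volumes")
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    seed_c = seed - seed.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss == 0.0:
        raise ValueError("zero-variance seed series")

    if mask is None:
        mask = np.ones(vol.dims, dtype=bool)
    flat = vol.data[mask]
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    vox_ss = np.einsum("ij,ij->i", flat_c, flat_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (flat_c @ seed_c) / np.sqrt(vox_ss * seed_ss)
    r[vox_ss == 0.0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    out = np.full(vol.dims, np.nan)
    out[mask] = r
    return SeedMap(seed_region_id=int(seed_region_id), r=out, n_timepoints=T)


def correlation_p_value(r, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r via the t transform with df = n - 2."""
    r = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))


def threshold_seed_map(seed_map: SeedMap, r_min: float = DEFAULT_R_THRESHOLD,
                       alpha: float = DEFAULT_ALPHA) -> SeedMap:
    """Mask a seed map: keep voxels with ``|r| >= r_min`` AND ``p < alpha``.

    Both criteria apply jointly — the magnitude threshold controls
    practical relevance, the (uncorrected) correlation p-value controls
    chance level at the run's number of timepoints.
    """
    if not (0.0 <= r_min < 1.0):
        raise ValueError("r_min must lie in [0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if seed_map.n_timepoints < 4:
        raise ValueError("need at least 4 timepoints to threshold")
    p = correlation_p_value(seed_map.r, seed_map.n_timepoints)
    keep = (np.abs(seed_map.r) >= r_min) & (p < alpha)
    out = np.where(keep, seed_map.r, np.nan)
    return SeedMap(seed_region_id=seed_map.seed_region_id, r=out,
                   n_timepoints=seed_map.n_timepoints,
                   provenance=f"threshold r_min={r_min} alpha={alpha}")


def connectivity_matrix(series: RegionSeries) -> ConnMatrix:
    """Pairwise Pearson correlations of the region series (the connectome).

    Zero-variance (or missing) regions give NaN rows/columns and are
    reported in ``degenerate_ids``.
    """
    values = series.values
    if values.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = values.std(axis=1)
    bad = (sd == 0.0) | ~np.isfinite(sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(values)
    m = np.clip(m, -1.0, 1.0)
    m[bad, :] = np.nan
    m[:, bad] = np.nan
    di = np.diag_indices_from(m)
    m[di] = np.where(bad, np.nan, 1.0)
    return ConnMatrix(values=m, region_ids=series.region_ids,
                      n_timepoints=values.shape[1],
                      degenerate_ids=series.region_ids[bad].tolist())


def global_connectivity_strength(m: ConnMatrix,
                                 r_min: float = DEFAULT_R_THRESHOLD) -> float:
    """Mean of region-pair correlations strictly greater than ``r_min``.

    Pairs are the unique upper-triangle entries (diagonal excluded);
    negative and sub-threshold correlations do not contribute.  Returns
    NaN when no pair qualifies.
    """
    if m.n_regions == 0:
        raise ValueError("empty correlation matrix")
    vals = m.upper_triangle()
    vals = vals[np.isfinite(vals)]
    kept = vals[vals > r_min]
    return float(kept.mean()) if kept.size else float("nan")


# ---------------------------------------------------------------------------
# Group-level statistics
# ---------------------------------------------------------------------------

_P_FLOOR = np.finfo(float).tiny


def _stack_z(maps) -> np.ndarray:
    dims = maps[0].dims
    for m in maps:
        if m.dims != dims:
            raise ValueError("seed maps are not on a common grid")
    return np.stack([fisher_z(m.r) for m in maps], axis=0)


def group_mean_map(maps) -> GroupMap:
    """Voxelwise one-sample t-test of Fisher-z values against zero.

    The displayed effect is the z-mean back-transformed to r.  Voxels
    where every subject agrees exactly (zero variance, nonzero mean) have
    infinite t; their p is floored at the smallest positive float and the
    voxels are flagged in ``capped``.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    z = _stack_z(maps)
    n = z.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(z, axis=0)
        sd = np.nanstd(z, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    capped = np.isinf(t)
    p = np.where(capped, _P_FLOOR, p)
    p = np.where(np.isnan(t), np.nan, np.maximum(p, _P_FLOOR))
    return GroupMap(t=t, p=p, mean_r=inverse_fisher_z(mean), n=(n,),
                    df=float(df), contrast="one-sample vs 0", capped=capped)


def group_difference_map(maps_a, maps_b, contrast: str = "A-B") -> GroupMap:
    """Voxelwise Welch two-sample t-test on Fisher-z values (A minus B)."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    za, zb = _stack_z(maps_a), _stack_z(maps_b)
    if za.shape[1:] != zb.shape[1:]:
        raise ValueError("groups are not on a common grid")
    na, nb = za.shape[0], zb.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ma, mb = np.nanmean(za, axis=0), np.nanmean(zb, axis=0)
        va = np.nanvar(za, axis=0, ddof=1) / na
        vb = np.nanvar(zb, axis=0, ddof=1) / nb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    capped = np.isinf(t)
    p = np.where(capped, _P_FLOOR, p)
    p = np.where(np.isnan(t), np.nan, np.maximum(p, _P_FLOOR))
    return GroupMap(t=t, p=p, mean_r=inverse_fisher_z(ma - mb), n=(na, nb),
                    df=df, contrast=contrast, capped=capped)


def average_seed_maps(maps) -> SeedMap:
    """Fisher-z average of several seed maps (e.g. runs within a subject)."""
    z = _stack_z(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_r = inverse_fisher_z(np.nanmean(z, axis=0))
    return SeedMap(seed_region_id=maps[0].seed_region_id, r=mean_r,
                   n_timepoints=maps[0].n_timepoints,
                   provenance=f"z-average of {len(maps)} maps")


def cohort_average_matrix(matrices) -> ConnMatrix:
    """Entrywise Fisher-z average of connectomes, back-transformed to r."""
    if not matrices:
        raise ValueError("no matrices to average")
    ids0 = matrices[0].region_ids
    for m in matrices:
        if not np.array_equal(m.region_ids, ids0):
            raise ValueError("region order mismatch across matrices")
    z = np.stack([fisher_z(m.values) for m in matrices], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = inverse_fisher_z(np.nanmean(z, axis=0))
    np.fill_diagonal(avg, 1.0)
    degenerate = sorted({i for m in matrices for i in m.degenerate_ids})
    return ConnMatrix(values=avg, region_ids=ids0,
                      n_timepoints=matrices[0].n_timepoints,
                      degenerate_ids=degenerate)
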