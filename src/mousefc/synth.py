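"""Synthetic mouse cohorts for end-to-end testing of the connectome pipeline.

The real study population is three cohorts — normal controls, IDUA-deficient
(MPS I) mutants, and mutants treated by gene therapy — scanned with
high-resolution rs-fMRI and parcellated into 235 atlas regions.  Because no
such acquisition is bundled here, this module generates:

* a brain-shaped integer label atlas with bilaterally paired regions,
* cohort-specific region-correlation templates (dense in controls,
  attenuated in mutants — hardest on limbic and interhemispheric links —
  and largely restored in treated animals),
* 4-D BOLD runs whose region signals are multivariate Gaussian with
  covariance equal to the template, plus white noise, polynomial drift and
  optional rigid motion with recorded ground truth,
* enzyme/substrate assay tables (IDUA activity, GAG concentration) whose
  group means match the published cohort summaries, with the mutant IDUA
  values tied at the below-detection floor.

Everything is deterministic for a fixed master seed; named substreams keep
atlas, BOLD and assay randomness independent of one another.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import (
    AtlasVolume, MotionTrace, Volume4D, COHORTS, default_affine,
    validate_region_table,
)

DEFAULT_DIMS = (96, 48, 12)
DEFAULT_VOXEL_MM = (0.25, 0.25, 0.5)
DEFAULT_N_REGIONS = 235
DEFAULT_T = 310
DEFAULT_TR_S = 1.0

# Anatomical families used for network blocks and connectogram ordering.
# Each entry: (family, number of bilateral pairs at the 235-region default,
# curated acronym bases).  Extra regions get generated names.
_FAMILY_PLAN = (
    ("isocortex", 28, ["ACA", "MO", "SS", "GU", "VISC", "AUD", "VIS", "RSP",
                       "PTLp", "TEa", "PERI", "ECT", "PL", "ILA", "ORB", "AI",
                       "FRP", "MOp", "MOs", "SSp", "SSs", "VISp", "VISl",
                       "VISam", "AUDd", "AUDp", "AUDv", "RSPd"]),
    ("olfactory", 8, ["MOB", "AOB", "AON", "TT", "DP", "PIR", "COA", "NLOT"]),
    ("hippocampus", 12, ["CA", "DG", "SUB", "PAR", "POST", "PRE", "ENT",
                         "CA1", "CA2", "CA3", "FC", "IG"]),
    ("cortical subplate", 6, ["CLA", "EP", "BLA", "BMA", "LA", "PAA"]),
    ("striatum", 8, ["STR", "CP", "ACB", "FS", "LS", "OT", "CEA", "AAA"]),
    ("pallidum", 4, ["PAL", "GPe", "GPi", "MA"]),
    ("thalamus", 14, ["MD", "AV", "AM", "AD", "LD", "LP", "VAL", "VPM",
                      "VPL", "RE", "RH", "CM", "PVT", "PT"]),
    ("hypothalamus", 8, ["HY", "LHA", "MBO", "PVH", "VMH", "AHN", "SO", "SCH"]),
    ("midbrain", 10, ["SC", "IC", "PRT", "MRN", "VTA", "SNr", "APN", "RN",
                      "NOT", "PAG"]),
    ("pons", 6, ["P", "PG", "PRNc", "PSV", "SOC", "TRN"]),
    ("medulla", 8, ["MY", "GRN", "IRN", "MARN", "PARN", "SPVC", "VII", "XII"]),
    ("cerebellum", 5, ["CB", "VERM", "HEM", "FN", "IP"]),
)

_REGION_NAMES = {
    "ACA": "Anterior cingulate area", "CA": "Ammon's horn",
    "MD": "Mediodorsal nucleus of thalamus", "MO": "Somatomotor areas",
    "GU": "Gustatory areas", "PAR": "Parasubiculum",
    "MA": "Magnocellular nucleus", "RE": "Nucleus of reuniens",
    "LS": "Lateral septal nucleus", "PERI": "Perirhinal area",
    "PRT": "Pretectal region", "PAA": "Piriform-amygdalar area",
    "BMA": "Basomedial amygdalar nucleus", "SUB": "Subiculum",
    "RSP": "Retrosplenial area", "STR": "Striatum", "DG": "Dentate gyrus",
}

_LIMBIC_FAMILIES = ("hippocampus", "thalamus")


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named RNG substream fanned out from one integer master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=(key, int(index))))


def _as_rng(seed_or_rng, name: str) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return substream(seed_or_rng, name)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def _brain_mask(dims) -> np.ndarray:
    """Ellipsoidal whole-brain mask with ~1 voxel of air margin per face
    (as in a real FOV, and required for motion/normalization to be
    recoverable without clipping brain off the grid)."""
    grids = np.indices(dims).astype(float)
    d = np.asarray(dims, dtype=float)
    c = (d - 1.0) / 2.0
    r = np.maximum(d / 2.0 - 1.0, d * 0.25)
    d2 = sum(((grids[i] - c[i]) / r[i]) ** 2 for i in range(3))
    mask = d2 <= 1.0
    if not mask.any():  # grid too small for an air margin: inscribe fully
        r = d / 2.0
        d2 = sum(((grids[i] - c[i]) / r[i]) ** 2 for i in range(3))
        mask = d2 <= 1.0
    return mask


def _region_catalog(n_regions: int) -> pd.DataFrame:
    """Region table rows (id, acronym, name, hemisphere, family)."""
    n_pairs = n_regions // 2
    midline = n_regions - 2 * n_pairs
    # candidate (family, base) list; seed regions ACA / CA / MD come first so
    # they exist even in very small atlases
    candidates = []
    for fam, quota, bases in _FAMILY_PLAN:
        names = list(bases)
        k = 0
        while len(names) < quota:
            names.append(f"{fam[:3].upper()}{k:02d}")
            k += 1
        candidates.extend((fam, b) for b in names[:quota])
    seeds = [("isocortex", "ACA"), ("hippocampus", "CA"), ("thalamus", "MD")]
    candidates = seeds + [c for c in candidates if c not in seeds]
    k = 0
    while len(candidates) < n_pairs:
        candidates.append(("isocortex", f"X{k:03d}"))
        k += 1
    rows = []
    next_id = 1
    for fam, base in candidates[:n_pairs]:
        name = _REGION_NAMES.get(base, f"{fam} region {base}")
        for suffix, hemi in (("l", "left"), ("r", "right")):
            rows.append(dict(id=next_id, acronym=base + suffix,
                             name=f"{name}, {hemi}", hemisphere=hemi, family=fam))
            next_id += 1
    if midline:
        rows.append(dict(id=next_id, acronym="MLN",
                         name="Midline nucleus", hemisphere="midline",
                         family="midbrain"))
    return pd.DataFrame(rows, columns=["id", "acronym", "name", "hemisphere", "family"])


def build_synthetic_atlas(dims=DEFAULT_DIMS, n_regions=DEFAULT_N_REGIONS,
                          rng_seed: int = 0, voxel_size_mm=DEFAULT_VOXEL_MM):
    """Tile a brain-shaped mask into ``n_regions`` connected label clusters.

    Bilateral regions are grown by seeded Voronoi tessellation on the left
    half of the mask and mirrored to the right, giving paired ``l``/``r``
    acronyms; an odd region count adds one midline region at the mask
    center.  Cells of a Euclidean Voronoi diagram restricted to the convex
    ellipsoid mask are intersections of convex sets, hence connected.

    Returns ``(AtlasVolume, region_table)``.
    """
    dims = tuple(int(d) for d in dims)
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    mask = _brain_mask(dims)
    n_mask = int(mask.sum())
    if n_mask < n_regions:
        raise ValueError(
            f"dims {dims} host only {n_mask} brain voxels, fewer than "
            f"{n_regions} regions")
    rng = substream(rng_seed, "atlas")
    table = _region_catalog(n_regions)
    labels = np.zeros(dims, dtype=np.int32)
    coords = np.argwhere(mask)
    scale = np.asarray(voxel_size_mm, dtype=float)

    n_pairs = n_regions // 2
    y_mid = (dims[1] - 1) / 2.0
    left_idx = coords[:, 1] < y_mid
    midline_ids = table.loc[table.hemisphere == "midline", "id"].tolist()

    use_mirror = dims[1] >= 2 and left_idx.sum() >= n_pairs
    if use_mirror:
        taken = np.zeros(len(coords), dtype=bool)
        if midline_ids:
            # symmetric blob at the mask center, sized ~ one region's share
            n_mid = max(1, n_mask // n_regions)
            c = (np.asarray(dims, dtype=float) - 1.0) / 2.0
            d = np.linalg.norm((coords - c) * scale, axis=1)
            order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d))
            chosen: set = set()
            for i in order:
                if len(chosen) >= n_mid:
                    break
                x, y, z = coords[i]
                j_mirror = (x, dims[1] - 1 - y, z)
                chosen.add((x, y, z))
                if mask[j_mirror]:
                    chosen.add(j_mirror)
            for (x, y, z) in chosen:
                labels[x, y, z] = midline_ids[0]
            for i, (x, y, z) in enumerate(coords):
                if (x, y, z) in chosen:
                    taken[i] = True
        left_coords = coords[left_idx & ~taken]
        pick = rng.choice(len(left_coords), size=n_pairs, replace=False)
        seeds_vox = left_coords[np.sort(pick)]
        tree = cKDTree(seeds_vox * scale)
        _, nearest = tree.query(left_coords * scale)
        pair_rows = table[table.hemisphere == "left"].reset_index(drop=True)
        left_ids = pair_rows["id"].to_numpy()
        right_ids = left_ids + 1  # right partner follows its left mate
        for (x, y, z), cell in zip(left_coords, nearest):
            labels[x, y, z] = left_ids[cell]
            ym = dims[1] - 1 - y
            if mask[x, ym, z] and labels[x, ym, z] == 0:
                labels[x, ym, z] = right_ids[cell]
        # any stragglers (mirror fell on the midline blob's asymmetric rim)
        rest = np.argwhere(mask & (labels == 0))
        if len(rest):
            filled = np.argwhere(labels > 0)
            tree = cKDTree(filled * scale)
            _, nn = tree.query(rest * scale)
            for (x, y, z), j in zip(rest, nn):
                labels[x, y, z] = labels[tuple(filled[j])]
    else:
        # grid too small to mirror: plain Voronoi, hemispheres by position
        pick = rng.choice(n_mask, size=n_regions, replace=False)
        seeds_vox = coords[np.sort(pick)]
        tree = cKDTree(seeds_vox * scale)
        _, nearest = tree.query(coords * scale)
        for (x, y, z), cell in zip(coords, nearest):
            labels[x, y, z] = cell + 1
        hemi = []
        for _, row in table.iterrows():
            sy = seeds_vox[row.id - 1][1]
            hemi.append("midline" if dims[1] == 1
                        else ("left" if sy < y_mid else "right"))
        table = table.assign(hemisphere=hemi)

    atlas = AtlasVolume(labels=labels, voxel_size_mm=tuple(voxel_size_mm),
                        affine=default_affine(voxel_size_mm))
    validate_region_table(table, atlas)
    return atlas, table


# ---------------------------------------------------------------------------
# Correlation templates
# ---------------------------------------------------------------------------

@dataclass
class TemplateParams:
    """Knobs of the cohort correlation structure.

    ``target_strength`` fixes the thresholded global connectivity strength
    (mean of region-pair correlations strictly above ``r_min``) of the
    calibrated cohorts.  The mutant cohort is not calibrated: its links are
    the control links scaled down — by ``attenuation`` on limbic-family and
    interhemispheric pairs, and by the milder ``(1+attenuation)/2`` on the
    rest, echoing the predominantly limbic/interhemispheric loss seen in
    the disease model.  In the treated cohort a fraction
    ``restored_fraction`` of network blocks is re-calibrated to the treated
    target; the remainder (or an explicit ``unrestored_pairs`` list) stays
    at the mutant level.
    """

    target_strength: dict = field(default_factory=lambda: {"control": 0.23,
                                                           "treated": 0.25})
    attenuation: float = 0.4
    restored_fraction: float = 0.95
    unrestored_pairs: list | None = None
    r_min: float = 0.15
    background_rho: float = 0.0
    block_weight_range: tuple = (0.75, 1.25)
    limbic_families: tuple = _LIMBIC_FAMILIES


@dataclass
class CorrelationTemplate:
    """Target population correlation matrix for one cohort."""

    matrix: np.ndarray
    cohort: str
    region_ids: np.ndarray
    blocks: dict            # family -> list of region ids
    descriptor: dict        # limbic / unrestored bookkeeping

    def strength(self, r_min: float = 0.15) -> float:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        vals = self.matrix[iu]
        kept = vals[vals > r_min]
        return float(kept.mean()) if kept.size else float("nan")


def _repair_psd(m: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and rescale the diagonal to one."""
    w, v = np.linalg.eigh(m)
    if w.min() >= -1e-10:
        return m
    w = np.clip(w, 0.0, None)
    m2 = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(m2), 1e-12, None))
    m2 = m2 / np.outer(d, d)
    np.fill_diagonal(m2, 1.0)
    return m2


def cohort_correlation_template(cohort: str, region_table: pd.DataFrame,
                                params: TemplateParams | None = None
                                ) -> CorrelationTemplate:
    """Build the target R x R correlation matrix for one cohort.

    Network blocks are the anatomical families of the region table; block k
    gets a within-block correlation ``scale * w_k`` with deterministic
    weights ``w_k`` spread over ``block_weight_range``.  The control (and
    treated) scale is chosen in closed form so that the pair-count-weighted
    mean of the within-block correlations — which is exactly the
    thresholded global strength when every block clears ``r_min`` — equals
    the cohort target.
    """
    if params is None:
        params = TemplateParams()
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    if not (0.0 <= params.attenuation <= 1.0):
        raise ValueError("attenuation factor must lie in [0, 1]")

    table = region_table.reset_index(drop=True)
    ids = table["id"].to_numpy()
    fam = table["family"].to_numpy()
    hemi = table["hemisphere"].to_numpy()
    families = list(dict.fromkeys(fam))
    K = len(families)
    lo, hi = params.block_weight_range
    w = np.linspace(lo, hi, K) if K > 1 else np.array([1.0])
    sizes = np.array([(fam == f).sum() for f in families])
    pair_counts = sizes * (sizes - 1) // 2
    if pair_counts.sum() == 0:
        raise ValueError("no within-family region pairs; families too small")

    def block_matrix(rho_per_family) -> np.ndarray:
        R = len(table)
        m = np.full((R, R), params.background_rho, dtype=float)
        for f, rho in zip(families, rho_per_family):
            idx = np.flatnonzero(fam == f)
            m[np.ix_(idx, idx)] = rho
        np.fill_diagonal(m, 1.0)
        return m

    w_bar = float((pair_counts * w).sum() / pair_counts.sum())
    scale_ctrl = params.target_strength["control"] / w_bar
    rho_ctrl = scale_ctrl * w

    mild = (1.0 + params.attenuation) / 2.0
    limbic = np.array([f in params.limbic_families for f in families])

    descriptor = {"limbic_families": list(params.limbic_families),
                  "unrestored_families": [], "unrestored_pairs": []}

    if cohort == "control":
        m = block_matrix(rho_ctrl)
    elif cohort == "mutant":
        rho_mut = rho_ctrl * np.where(limbic, params.attenuation, mild)
        m = block_matrix(rho_mut)
        # interhemispheric pairs take the severe hit in every family
        inter = np.not_equal.outer(hemi, hemi) & (hemi[:, None] != "midline") \
            & (hemi[None, :] != "midline")
        same_fam = np.equal.outer(fam, fam)
        sel = inter & same_fam
        rho_ctrl_mat = _family_rho_lookup(fam, families, rho_ctrl)
        m[sel] = rho_ctrl_mat[sel] * params.attenuation
        np.fill_diagonal(m, 1.0)
    else:  # treated
        n_unres = int(round((1.0 - params.restored_fraction) * K))
        unres_fams = [f for f, is_l in zip(families, limbic) if is_l][:n_unres]
        if len(unres_fams) < n_unres:
            unres_fams += [f for f in families if f not in unres_fams][
                : n_unres - len(unres_fams)]
        restored = np.array([f not in unres_fams for f in families])
        w_bar_res = float((pair_counts[restored] * w[restored]).sum()
                          / max(pair_counts[restored].sum(), 1))
        scale_tr = params.target_strength["treated"] / w_bar_res
        rho_mut = rho_ctrl * np.where(limbic, params.attenuation, mild)
        rho_tr = np.where(restored, scale_tr * w, rho_mut)
        m = block_matrix(rho_tr)
        descriptor["unrestored_families"] = unres_fams
        for f in unres_fams:
            accs = table.loc[fam == f, "acronym"].tolist()
            descriptor["unrestored_pairs"].extend(
                (a, b) for i, a in enumerate(accs) for b in accs[i + 1:])
        if params.unrestored_pairs:
            acr_index = {a: i for i, a in enumerate(table["acronym"])}
            rho_mut_mat = _family_rho_lookup(fam, families, rho_mut)
            for a, b in params.unrestored_pairs:
                i, j = acr_index[a], acr_index[b]
                m[i, j] = m[j, i] = rho_mut_mat[i, j]
                descriptor["unrestored_pairs"].append((a, b))

    m = _repair_psd(m)
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ArithmeticError("template not PSD after repair")
    blocks = {f: table.loc[fam == f, "id"].tolist() for f in families}
    return CorrelationTemplate(matrix=m, cohort=cohort, region_ids=ids,
                               blocks=blocks, descriptor=descriptor)


def _family_rho_lookup(fam, families, rho_per_family) -> np.ndarray:
    """R x R matrix holding each within-family pair's block correlation."""
    rho_of = dict(zip(families, rho_per_family))
    rho_vec = np.array([rho_of[f] for f in fam])
    same = np.equal.outer(fam, fam)
    return np.where(same, np.minimum.outer(rho_vec, rho_vec), 0.0)


def cohort_templates(region_table: pd.DataFrame,
                     params: TemplateParams | None = None) -> dict:
    """Templates for all three cohorts under one parameter set."""
    return {c: cohort_correlation_template(c, region_table, params)
            for c in COHORTS}


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def reference_image(atlas: AtlasVolume, baseline: float = 100.0) -> np.ndarray:
    """Atlas-space anatomical reference: the noise-free mean image of a
    simulated run.

    Intensity combines a smooth large-scale profile (the long-range
    gradients that drive intensity-based registration) with mild
    per-region contrast; zero outside the brain.
    """
    labels = atlas.labels
    dims = labels.shape
    img = np.zeros(dims, dtype=float)
    mask = atlas.mask
    u, v, w = [2.0 * g / max(d - 1, 1) - 1.0
               for g, d in zip(np.indices(dims).astype(float), dims)]
    smooth = 0.85 + 0.20 * u + 0.12 * v - 0.10 * w + 0.10 * u * v \
        - 0.15 * (u ** 2 + v ** 2)
    flat = labels[mask]
    img[mask] = baseline * (smooth[mask]
                            + 0.08 * ((flat * 7919) % 101) / 100.0)
    return img

@dataclass
class DriftSpec:
    """Slow scanner drift: Legendre polynomial in time, shared shape with
    per-voxel gain, in raw signal units."""

    order: int = 2
    amplitude: float = 1.0


@dataclass
class MotionSpec:
    """Rigid head motion.  Either explicit per-volume parameters or a
    random walk with the given step scales."""

    translations_mm: np.ndarray | None = None   # (T, 3)
    rotations_deg: np.ndarray | None = None     # (T, 3)
    step_mm: float = 0.05
    step_deg: float = 0.05

    def realize(self, T: int, rng: np.random.Generator):
        if self.translations_mm is not None:
            t = np.asarray(self.translations_mm, dtype=float)
            r = (np.zeros((T, 3)) if self.rotations_deg is None
                 else np.asarray(self.rotations_deg, dtype=float))
        else:
            t = np.cumsum(rng.normal(0, self.step_mm, size=(T, 3)), axis=0)
            r = np.cumsum(rng.normal(0, self.step_deg, size=(T, 3)), axis=0)
            t[0] = 0.0
            r[0] = 0.0
        if t.shape != (T, 3) or r.shape != (T, 3):
            raise ValueError("motion parameter arrays must be (T, 3)")
        return t, r


def simulate_bold_run(atlas: AtlasVolume, template: CorrelationTemplate,
                      T: int = DEFAULT_T, tr_s: float = DEFAULT_TR_S,
                      noise_sd: float = 1.0,
                      drift_spec: DriftSpec | None = None,
                      motion_spec: MotionSpec | None = None,
                      rng_seed: int = 0, baseline: float = 100.0,
                      signal_sd: float = 1.0) -> Volume4D:
    """One 4-D BOLD run whose region signals follow the cohort template.

    Latent region series are multivariate Gaussian with covariance equal to
    the template (unit variances), every voxel carries its region's latent
    signal plus i.i.d. white noise, a region-dependent baseline provides
    anatomical contrast for registration, and optional drift/motion
    corruptions are layered on top.  Injected motion parameters are
    recorded as ground truth on the returned volume.
    """
    if T < 2:
        raise ValueError("need at least 2 volumes")
    R = len(template.region_ids)
    if atlas.n_regions != R:
        raise ValueError("template dimension does not match atlas region count")
    evals = np.linalg.eigvalsh(template.matrix)
    if evals.min() < -1e-8:
        raise ValueError("template correlation matrix is not PSD")
    rng = _as_rng(rng_seed, "bold")
    cov = template.matrix + 1e-9 * np.eye(R)
    L = np.linalg.cholesky(cov)
    latent = L @ rng.standard_normal((R, T))  # (R, T), unit variance

    labels = atlas.labels
    mask = atlas.mask
    lut = np.zeros(int(template.region_ids.max()) + 1, dtype=np.int64)
    lut[template.region_ids] = np.arange(R)

    data = np.zeros(labels.shape + (T,), dtype=float)
    flat_labels = labels[mask]
    base = reference_image(atlas, baseline)[mask]
    data[mask] = base[:, None] + signal_sd * latent[lut[flat_labels]]
    if noise_sd > 0:
        data[mask] += noise_sd * rng.standard_normal((int(mask.sum()), T))

    if drift_spec is not None:
        if drift_spec.order < 1:
            raise ValueError("drift order must be >= 1")
        tt = np.linspace(-1.0, 1.0, T)
        basis = np.polynomial.legendre.legvander(tt, drift_spec.order)[:, 1:]
        coefs = rng.normal(0.0, drift_spec.amplitude, size=drift_spec.order)
        drift = basis @ coefs                     # (T,)
        gain = rng.uniform(0.5, 1.5, size=int(mask.sum()))
        data[mask] += gain[:, None] * drift[None, :]

    trace = None
    if motion_spec is not None:
        from ._geometry import center_of_volume_mm, resample, rigid_world_matrix
        t_mm, r_deg = motion_spec.realize(T, rng)
        center = center_of_volume_mm(labels.shape, atlas.affine)
        for t in range(T):
            if np.any(t_mm[t]) or np.any(r_deg[t]):
                m = rigid_world_matrix(t_mm[t], r_deg[t], center)
                data[..., t] = resample(np.ascontiguousarray(data[..., t]),
                                        m, atlas.affine)
        trace = MotionTrace(translations_mm=t_mm, rotations_deg=r_deg,
                            reference_index=0)

    vol = Volume4D(data=data, voxel_size_mm=atlas.voxel_size_mm, tr_s=tr_s,
                   affine=atlas.affine.copy(),
                   provenance=[f"simulated cohort={template.cohort} T={T} "
                               f"seed={rng_seed}"],
                   motion_truth=trace)
    return vol


# ---------------------------------------------------------------------------
# Cohort design and assays
# ---------------------------------------------------------------------------

DEFAULT_RUN_PLAN = {
    # 6 + 6 + 8 mice, 45 runs total (15 per cohort); run counts follow the
    # "two to five runs per animal" acquisition style at desk scale
    "control": [3, 3, 3, 2, 2, 2],
    "mutant": [3, 3, 3, 2, 2, 2],
    "treated": [2, 2, 2, 2, 2, 2, 2, 1],
}


def make_cohort_design(run_plan: dict | None = None) -> pd.DataFrame:
    """Deterministic cohort design table: one row per rs-fMRI run."""
    plan = DEFAULT_RUN_PLAN if run_plan is None else run_plan
    rows = []
    run_id = 0
    for cohort, runs_per_subject in plan.items():
        for s_idx, n_runs in enumerate(runs_per_subject):
            if n_runs < 1:
                raise ValueError("every subject needs at least one run")
            subject = f"{cohort[:3]}{s_idx + 1:02d}"
            sex = "M" if s_idx < len(runs_per_subject) / 2 else "F"
            for scan in range(n_runs):
                rows.append(dict(run_id=f"run{run_id:03d}", subject_id=subject,
                                 cohort=cohort, sex=sex, scan_index=scan))
                run_id += 1
    return pd.DataFrame(rows)


#: Published cohort summaries: IDUA nmol/h/mg protein, GAG ug/mg protein,
#: means +/- SEM; mutant IDUA is below detection level.
ASSAY_DEFAULTS = {
    "control": dict(n=9, idua_mean=8.3, idua_sem=0.2, idua_bdl=False,
                    gag_mean=8.2, gag_sem=0.4),
    "mutant": dict(n=9, idua_mean=0.0, idua_sem=0.0, idua_bdl=True,
                   gag_mean=24.5, gag_sem=0.4),
    "treated": dict(n=8, idua_mean=141.3, idua_sem=4.9, idua_bdl=False,
                    gag_mean=6.9, gag_sem=0.2),
}


def simulate_assays(design: pd.DataFrame | None = None,
                    group_params: dict | None = None,
                    bdl_floor: float = 0.0, rng_seed: int = 0) -> pd.DataFrame:
    """Per-animal IDUA/GAG assay table matching the cohort summaries.

    SDs are reconstructed from the published SEMs (SD = SEM * sqrt(n)).
    Mutant IDUA is stored as the shared detection floor with ``idua_bdl``
    set, producing the tie block that the rank tests must handle.
    """
    params = {c: dict(v) for c, v in ASSAY_DEFAULTS.items()}
    if group_params:
        for c, v in group_params.items():
            params.setdefault(c, {}).update(v)
    if design is not None:
        subjects = design.drop_duplicates("subject_id")
        for c in params:
            params[c]["n"] = int((subjects.cohort == c).sum())
    rng = _as_rng(rng_seed, "assay")
    rows = []
    for cohort, p in params.items():
        n = int(p["n"])
        for key in ("idua_sem", "gag_sem"):
            if p[key] < 0:
                raise ValueError(f"negative SD-producing {key}")
        idua_sd = p["idua_sem"] * np.sqrt(n)
        gag_sd = p["gag_sem"] * np.sqrt(n)
        idua = rng.normal(p["idua_mean"], idua_sd, size=n) if idua_sd > 0 \
            else np.full(n, p["idua_mean"])
        gag = rng.normal(p["gag_mean"], gag_sd, size=n) if gag_sd > 0 \
            else np.full(n, p["gag_mean"])
        gag = np.clip(gag, 1e-6, None)
        for i in range(n):
            bdl = bool(p["idua_bdl"])
            rows.append(dict(animal_id=f"{cohort[:3]}{i + 1:02d}",
                             cohort=cohort,
                             idua_value=bdl_floor if bdl else max(idua[i], 0.0),
                             idua_bdl=bdl,
                             gag_value=gag[i]))
    return pd.DataFrame(rows)
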