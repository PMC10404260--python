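"""rs-fMRI preprocessing: rigid realignment, drift removal, atlas normalization.

The chain mirrors a standard single-run BOLD pipeline: each volume is
rigid-registered (6 parameters, least-squares intensity criterion,
trilinear resampling) to a within-run reference, slow scanner drift is
regressed out voxelwise, and the run is resampled onto the atlas grid via
a 12-parameter affine.  No spatial smoothing and no band-pass filtering
beyond the drift removal are applied.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from ._geometry import (
    affine_world_matrix, center_of_volume_mm, resample, rigid_world_matrix,
)
from .types import AtlasVolume, MotionTrace, Volume4D


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Registration engine
# ---------------------------------------------------------------------------

_RIGID_STEPS = np.array([0.25, 0.25, 0.25, 0.5, 0.5, 0.5])
_AFFINE_STEPS = np.array([0.25] * 3 + [0.5] * 3 + [0.02] * 3 + [0.02] * 3)
_AFFINE_INIT = np.array([0.0] * 6 + [1.0] * 3 + [0.0] * 3)


def _prep(img: np.ndarray, sigma: float):
    """Smooth and z-score an image for the least-squares cost.

    Returns the image and the value a zero (air) voxel maps to, used as
    the out-of-field fill so borders do not distort the cost.
    """
    out = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img.astype(float)
    sd = out.std()
    if sd == 0:
        raise RegistrationError("image has zero intensity variance")
    mean = out.mean()
    return (out - mean) / sd, float(-mean / sd)


def _optimize_transform(moving, fixed, make_matrix, x0, steps,
                        in_affine, out_affine, out_shape, cval=0.0):
    def cost(params):
        warped = resample(moving, make_matrix(params), in_affine,
                          out_affine=out_affine, out_shape=out_shape,
                          cval=cval)
        return float(np.mean((warped - fixed) ** 2))

    res = optimize.minimize(cost, x0, method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8,
                                     "direc": np.diag(steps), "maxiter": 400})
    return np.asarray(res.x, dtype=float), float(res.fun)


def register_rigid(moving: np.ndarray, fixed: np.ndarray, affine: np.ndarray,
                   init=None, smooth_sigma: float = 1.0) -> np.ndarray:
    """Six-parameter rigid registration of ``moving`` onto ``fixed``.

    Returns the motion parameters ``(tx, ty, tz, rx, ry, rz)`` such that
    applying the rigid transform to the *reference pose* produces the
    observed volume; realignment therefore resamples with the inverse.
    """
    mv, bg = _prep(moving, smooth_sigma)
    fx, _ = _prep(fixed, smooth_sigma)
    center = center_of_volume_mm(moving.shape, affine)

    def make_matrix(params):
        # cost maps observed -> reference with the inverse motion
        m = rigid_world_matrix(params[:3], params[3:], center)
        return np.linalg.inv(m)

    x0 = np.zeros(6) if init is None else np.asarray(init, dtype=float)
    best, _ = _optimize_transform(mv, fx, make_matrix, x0, _RIGID_STEPS,
                                  affine, affine, moving.shape, cval=bg)
    return best


def register_affine(moving: np.ndarray, fixed: np.ndarray,
                    in_affine: np.ndarray, out_affine: np.ndarray,
                    out_shape, smooth_sigma: float = 1.0) -> np.ndarray:
    """Twelve-parameter affine registration; returns the world-space 4x4
    mapping moving-world coordinates onto fixed-world coordinates."""
    mv, bg = _prep(moving, smooth_sigma)
    fx, _ = _prep(fixed, smooth_sigma)

    def make_matrix(params):
        return affine_world_matrix(params)

    # stage 1: translations + rotations only (Powell), then the full
    # 12 parameters, then Gauss-Newton refinement on the residual image
    x0 = _AFFINE_INIT.copy()
    rigid_steps = _AFFINE_STEPS.copy()
    rigid_steps[6:] = 1e-12  # effectively frozen, keeps direc full rank
    x0, _ = _optimize_transform(mv, fx, make_matrix, x0, rigid_steps,
                                in_affine, out_affine, tuple(out_shape),
                                cval=bg)
    x0, _ = _optimize_transform(mv, fx, make_matrix, x0,
                                _AFFINE_STEPS, in_affine, out_affine,
                                tuple(out_shape), cval=bg)

    # coarse-to-fine Gauss-Newton: first at smooth_sigma with trilinear
    # warps, then at half the smoothing with cubic warps for sub-voxel
    # accuracy
    for sigma, order in ((smooth_sigma, 1), (smooth_sigma / 2.0, 3)):
        mv_s, bg_s = _prep(moving, sigma)
        fx_s, _ = _prep(fixed, sigma)

        def residual(params, mv_s=mv_s, fx_s=fx_s, bg_s=bg_s, order=order):
            warped = resample(mv_s, make_matrix(params), in_affine,
                              out_affine=out_affine,
                              out_shape=tuple(out_shape), cval=bg_s,
                              order=order)
            return (warped - fx_s).ravel()

        res = optimize.least_squares(residual, x0, diff_step=1e-3,
                                     x_scale=np.maximum(_AFFINE_STEPS, 1e-3),
                                     max_nfev=60)
        x0 = res.x
    return affine_world_matrix(x0)


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def realign(vol: Volume4D, reference_strategy="mean", passes: int = 2,
            smooth_sigma: float = 1.0):
    """Motion-correct a run; returns ``(realigned, MotionTrace)``.

    ``reference_strategy`` is ``"mean"`` (default: register to the mean
    volume, re-estimated over ``passes`` rounds) or an integer volume
    index.  With a mean reference the reported parameters are re-expressed
    relative to the least-moved volume so that the trace's reference entry
    is exactly zero (a small-angle approximation, adequate for the
    sub-voxel motion this corrects).
    """
    T = vol.n_timepoints
    if T < 2:
        raise ValueError("need >= 2 volumes to realign")
    data = vol.data
    params = np.zeros((T, 6))
    degenerate = [t for t in range(T) if not np.any(data[..., t])]

    def realign_all(p):
        out = np.empty_like(data)
        center = center_of_volume_mm(vol.dims, vol.affine)
        for t in range(T):
            if np.any(p[t]):
                m = rigid_world_matrix(p[t][:3], p[t][3:], center)
                out[..., t] = resample(np.ascontiguousarray(data[..., t]),
                                       np.linalg.inv(m), vol.affine)
            else:
                out[..., t] = data[..., t]
        return out

    if reference_strategy == "mean":
        realigned = data
        for _ in range(max(1, passes)):
            ref = realigned.mean(axis=3)
            for t in range(T):
                if t in degenerate:
                    continue
                params[t] = register_rigid(
                    np.ascontiguousarray(data[..., t]), ref, vol.affine,
                    init=params[t], smooth_sigma=smooth_sigma)
            realigned = realign_all(params)
        ok = [t for t in range(T) if t not in degenerate]
        ref_idx = int(min(ok, key=lambda t: np.linalg.norm(params[t])))
        params = params - params[ref_idx]
        realigned = realign_all(params)
    else:
        ref_idx = int(reference_strategy)
        ref = np.ascontiguousarray(data[..., ref_idx])
        for t in range(T):
            if t == ref_idx or t in degenerate:
                continue
            params[t] = register_rigid(np.ascontiguousarray(data[..., t]),
                                       ref, vol.affine,
                                       smooth_sigma=smooth_sigma)
        realigned = realign_all(params)

    trace = MotionTrace(translations_mm=params[:, :3],
                        rotations_deg=params[:, 3:],
                        reference_index=ref_idx, degenerate=degenerate)
    out = vol.with_data(realigned, f"realign ref={reference_strategy} "
                                   f"passes={passes}")
    return out, trace


def _drift_basis(T: int, tr_s: float, method: str, order_or_cutoff):
    tt = np.linspace(-1.0, 1.0, T)
    if method == "polynomial":
        order = int(order_or_cutoff if order_or_cutoff is not None else 2)
        if order >= T:
            raise ValueError("polynomial order must be < number of volumes")
        if order < 1:
            return np.empty((T, 0))
        return np.polynomial.legendre.legvander(tt, order)[:, 1:]
    if method == "highpass-cosine":
        cutoff = float(order_or_cutoff if order_or_cutoff is not None else 0.01)
        # DCT-II components with frequency k/(2*T*TR) below the cutoff
        k_max = int(np.floor(2.0 * T * tr_s * cutoff))
        n = np.arange(T)
        cols = [np.cos(np.pi * k * (n + 0.5) / T) for k in range(1, k_max + 1)]
        return np.column_stack(cols) if cols else np.empty((T, 0))
    raise ValueError("method must be 'polynomial' or 'highpass-cosine'")


def remove_drift(vol: Volume4D, method: str = "highpass-cosine",
                 order_or_cutoff=None) -> Volume4D:
    """Regress slow drift out of every voxel's series, keeping the mean.

    ``method="polynomial"`` removes Legendre polynomials up to
    ``order_or_cutoff`` (default 2); ``method="highpass-cosine"`` removes
    cosine components below the cutoff frequency in Hz (default 0.01).
    The residual series are orthogonal to the removed basis.
    """
    T = vol.n_timepoints
    basis = _drift_basis(T, vol.tr_s, method, order_or_cutoff)
    if basis.shape[1] == 0:
        return vol.with_data(vol.data.copy(), f"remove_drift {method} (no-op)")
    basis = basis - basis.mean(axis=0)
    q, _ = np.linalg.qr(basis)
    flat = vol.data.reshape(-1, T)
    mean = flat.mean(axis=1, keepdims=True)
    centered = flat - mean
    resid = centered - (centered @ q) @ q.T
    out = (resid + mean).reshape(vol.data.shape)
    return vol.with_data(out, f"remove_drift {method} k={basis.shape[1]}")


def normalize_to_atlas(vol: Volume4D, atlas: AtlasVolume,
                       transform: np.ndarray | None = None,
                       smooth_sigma: float = 1.0) -> Volume4D:
    """Resample a run onto the atlas grid.

    ``transform`` is a world-space 4x4 mapping run coordinates to atlas
    coordinates; if omitted it is estimated by 12-parameter affine
    registration of the run's mean image to the atlas-space anatomical
    reference.  A failed registration (insufficient brain overlap after
    warping) is flagged in the provenance log.
    """
    from .synth import reference_image

    mean_img = vol.data.mean(axis=3)
    if transform is None:
        fixed = reference_image(atlas)
        transform = register_affine(mean_img, fixed, vol.affine, atlas.affine,
                                    atlas.dims, smooth_sigma=smooth_sigma)
    transform = np.asarray(transform, dtype=float)

    identity_case = (np.allclose(transform, np.eye(4))
                     and vol.dims == atlas.dims
                     and np.allclose(vol.affine, atlas.affine))
    if identity_case:
        out_data = vol.data.copy()
    else:
        T = vol.n_timepoints
        out_data = np.empty(atlas.dims + (T,), dtype=float)
        for t in range(T):
            out_data[..., t] = resample(
                np.ascontiguousarray(vol.data[..., t]), transform,
                vol.affine, out_affine=atlas.affine, out_shape=atlas.dims)

    warped_support = resample((mean_img != 0).astype(float), transform,
                              vol.affine, out_affine=atlas.affine,
                              out_shape=atlas.dims) > 0.5
    overlap = float((warped_support & atlas.mask).sum() / max(atlas.mask.sum(), 1))
    note = (f"normalize_to_atlas overlap={overlap:.2f}"
            + ("" if overlap >= 0.25 else " REGISTRATION_FAILED"))
    out = Volume4D(data=out_data, voxel_size_mm=atlas.voxel_size_mm,
                   tr_s=vol.tr_s, affine=atlas.affine.copy(),
                   provenance=[*vol.provenance, note,
                               "transform=" + np.array2string(
                                   transform, precision=4, separator=",")],
                   motion_truth=vol.motion_truth)
    return out
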