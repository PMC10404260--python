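"""File formats: NIfTI volumes/maps, TSV/CSV tables, JSON ensembles, YAML.

NIfTI files carry the voxel->world affine; region tables are TSV with the
canonical columns; connectivity matrices are TSV with region-acronym
headers; ensembles are serialized to JSON with sparse coefficients.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .netclass import BaggedEnsemble, LassoFit
from .types import AtlasVolume, ConnMatrix, SeedMap, Volume4D


def save_volume(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size_mm) + (vol.tr_s,))
    img.header["descrip"] = b"mousefc BOLD run"
    nib.save(img, str(path))


def load_volume(path, tr_s: float | None = None) -> Volume4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    tr = float(tr_s if tr_s is not None
               else (zooms[3] if len(zooms) > 3 and zooms[3] > 0 else 1.0))
    return Volume4D(data=data, voxel_size_mm=tuple(float(z) for z in zooms[:3]),
                    tr_s=tr, affine=np.asarray(img.affine),
                    provenance=[f"loaded {Path(path).name}"])


def save_atlas(atlas: AtlasVolume, path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.affine)
    img.header.set_zooms(tuple(atlas.voxel_size_mm))
    nib.save(img, str(path))


def load_atlas(path) -> AtlasVolume:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    return AtlasVolume(labels=labels,
                       voxel_size_mm=tuple(float(z) for z in zooms),
                       affine=np.asarray(img.affine))


def save_seed_map(seed_map: SeedMap, path,
                  affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(seed_map.r.astype(np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def save_group_map(group_map, path, affine: np.ndarray | None = None) -> None:
    """Write a group statistic map as a 4-D NIfTI: volumes are the
    voxelwise t, the uncorrected p, and the displayed mean r."""
    stack = np.stack([group_map.t, group_map.p, group_map.mean_r],
                     axis=-1).astype(np.float32)
    img = nib.Nifti1Image(stack, np.eye(4) if affine is None else affine)
    img.header["descrip"] = b"vol0=t vol1=p vol2=mean_r"
    nib.save(img, str(path))


def save_region_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_region_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_conn_matrix(m: ConnMatrix, region_table: pd.DataFrame, path) -> None:
    lut = dict(zip(region_table["id"], region_table["acronym"]))
    names = [lut.get(int(i), str(i)) for i in m.region_ids]
    pd.DataFrame(m.values, index=names, columns=names).to_csv(path, sep="\t")


def load_conn_matrix(path, region_table: pd.DataFrame,
                     n_timepoints: int = 0) -> ConnMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lut = dict(zip(region_table["acronym"], region_table["id"]))
    ids = np.array([lut[a] for a in df.index])
    return ConnMatrix(values=df.to_numpy(dtype=float), region_ids=ids,
                      n_timepoints=n_timepoints)


def save_ensemble_json(ens: BaggedEnsemble, path) -> None:
    """Sparse JSON serialization of a bagged ensemble."""
    def fit_dict(fit: LassoFit):
        nz = np.nonzero(fit.coef)
        return {"shape": list(fit.coef.shape),
                "rows": nz[0].tolist(), "cols": nz[1].tolist(),
                "values": fit.coef[nz].tolist(),
                "intercept": fit.intercept.tolist(),
                "lam": fit.lam, "method": fit.method}

    payload = {
        "classes": [str(c) for c in ens.classes],
        "B": ens.B, "frac": ens.frac, "rng_seed": ens.rng_seed,
        "lambda_strategy": ens.lambda_strategy,
        "lambdas": ens.lambdas.tolist(),
        "selection_freq": ens.selection_freq.tolist(),
        "averaged": fit_dict(ens.averaged),
        "models": [fit_dict(m) for m in ens.models],
        "subsample_indices": [idx.tolist() for idx in ens.subsample_indices],
    }
    Path(path).write_text(json.dumps(payload))


def load_ensemble_json(path) -> BaggedEnsemble:
    payload = json.loads(Path(path).read_text())
    classes = np.array(payload["classes"])

    def fit_from(d):
        coef = np.zeros(tuple(d["shape"]))
        coef[d["rows"], d["cols"]] = d["values"]
        return LassoFit(coef=coef, intercept=np.array(d["intercept"]),
                        classes=classes, lam=d["lam"], method=d["method"])

    return BaggedEnsemble(
        models=[fit_from(d) for d in payload["models"]],
        selection_freq=np.array(payload["selection_freq"]),
        averaged=fit_from(payload["averaged"]), classes=classes,
        B=payload["B"], frac=payload["frac"],
        subsample_indices=[np.array(i) for i in payload["subsample_indices"]],
        lambdas=np.array(payload["lambdas"]), rng_seed=payload["rng_seed"],
        lambda_strategy=payload["lambda_strategy"])


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
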