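"""File formats: covariate CSV, per-vertex surface CSV + JSON sidecar, NIfTI volumes.

Conventions (documented once, used everywhere):

* CSVs are comma-separated, UTF-8, '.' decimal, header row mandatory.
* Volumes (lesion masks, skeleton maps, stat volumes) are NIfTI-1 with an
  identity-scaled affine from the geometry voxel size; voxel indexing is
  0-based in array order. Skeleton-space vectors are embedded into the grid
  on write and gathered back through the geometry's skeleton index on read.
* Surface maps are CSV with a ``vertex`` column and one column per subject;
  vertices are 0-based. Geometry travels as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import EffectTruth
from .errors import DataError
from .geometry import Geometry
from .types import LesionMask, ScalarMap, StatMap, WScoreMap

COVARIATE_HEADER = ["subject_id", "group", "age", "sex", "icv"]


def write_covariates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse covariate table {path}: {exc}") from exc
    missing = [c for c in COVARIATE_HEADER if c not in table.columns]
    if missing:
        raise DataError(f"covariate table {path}: missing columns {missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataError(f"covariate table {path}: duplicate subject_id {dup!r}")
    bad_sex = ~table["sex"].isin((0, 1))
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise DataError(f"covariate table {path}: sex not in {{0,1}} at row {row}")
    for col, lo in (("age", 0.0), ("icv", 0.0)):
        bad = table[col] <= lo
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataError(f"covariate table {path}: non-positive {col} at row {row}")
    return table


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def write_volume(data: np.ndarray, path, voxel_size_mm: float = 2.0) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, float]:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise DataError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    voxel = float(img.header.get_zooms()[0])
    return data, voxel


def write_lesion_mask(mask: LesionMask, path) -> None:
    write_volume(mask.voxels, path, mask.voxel_size_mm)


def read_lesion_mask(path, subject_id: str | None = None) -> LesionMask:
    data, voxel = read_volume(path)
    return LesionMask(subject_id or Path(path).stem, data, voxel)


def write_skeleton_map(smap: ScalarMap, geometry: Geometry, path) -> None:
    """Embed a skeleton-space map into the full grid and save as NIfTI."""
    if smap.space != "skeleton":
        raise DataError(f"map for {smap.subject_id} is not in skeleton space")
    vol = geometry.embed_skeleton_values(smap.values)
    write_volume(vol, path, geometry.voxel_size_mm)


def read_skeleton_map(path, geometry: Geometry, modality: str, subject_id=None) -> ScalarMap:
    data, _ = read_volume(path)
    if data.shape != geometry.grid_shape:
        raise DataError(
            f"volume {path}: shape {data.shape} does not match grid {geometry.grid_shape}"
        )
    values = geometry.extract_skeleton_values(data)
    return ScalarMap(subject_id or Path(path).stem, modality, "skeleton", values)


def write_surface_maps(maps: list[ScalarMap], path) -> None:
    """One CSV: a ``vertex`` column then one column of values per subject."""
    if not maps:
        raise DataError("no surface maps to write")
    n = maps[0].n_locations
    cols = {"vertex": np.arange(n)}
    for m in maps:
        if m.space != "surface":
            raise DataError(f"map for {m.subject_id} is not in surface space")
        if m.n_locations != n:
            raise DataError(f"map for {m.subject_id}: vertex count mismatch")
        cols[m.subject_id] = m.values
    pd.DataFrame(cols).to_csv(path, index=False)


def read_surface_maps(path, modality: str) -> list[ScalarMap]:
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse surface map file {path}: {exc}") from exc
    if "vertex" not in table.columns:
        raise DataError(f"surface map file {path}: missing 'vertex' column")
    expected = np.arange(len(table))
    if not np.array_equal(table["vertex"].to_numpy(), expected):
        raise DataError(f"surface map file {path}: vertex column is not 0..n-1")
    return [
        ScalarMap(str(c), modality, "surface", table[c].to_numpy(dtype=float))
        for c in table.columns
        if c != "vertex"
    ]


def write_geometry(geometry: Geometry, path) -> None:
    Path(path).write_text(json.dumps(geometry.to_dict()))


def read_geometry(path) -> Geometry:
    return Geometry.from_dict(json.loads(Path(path).read_text()))


def write_truth(truth: EffectTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict()))


def read_truth(path) -> EffectTruth:
    return EffectTruth.from_dict(json.loads(Path(path).read_text()))


# -- model / W-map / stat-map serialization ----------------------------------


def write_normative_model(model, outdir) -> None:
    from .types import NormativeModel  # local to avoid cycle in type hints

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {
        "modality": model.modality,
        "space": model.space,
        "n_controls": model.n_controls,
        "df_resid": model.df_resid,
        "covariates": list(model.covariates),
        "dropped_covariates": list(model.dropped_covariates),
    }
    (outdir / "model.json").write_text(json.dumps(header))
    table = pd.DataFrame(model.coef.T, columns=["intercept", *model.covariates])
    table["resid_sd"] = model.resid_sd
    table["degenerate"] = model.degenerate.astype(int)
    table.to_csv(outdir / "coefficients.csv", index=False)


def read_normative_model(outdir):
    from .types import NormativeModel

    outdir = Path(outdir)
    header = json.loads((outdir / "model.json").read_text())
    table = pd.read_csv(outdir / "coefficients.csv")
    covs = header["covariates"]
    coef = table[["intercept", *covs]].to_numpy(dtype=float).T
    return NormativeModel(
        coef=coef,
        resid_sd=table["resid_sd"].to_numpy(dtype=float),
        n_controls=int(header["n_controls"]),
        df_resid=int(header["df_resid"]),
        degenerate=table["degenerate"].to_numpy(dtype=bool),
        modality=header["modality"],
        space=header["space"],
        covariates=tuple(covs),
        dropped_covariates=tuple(header["dropped_covariates"]),
    )


def write_wscore_maps(wmaps: list[WScoreMap], geometry: Geometry, outdir) -> None:
    """W-maps in the same container as their input maps (CSV surface, NIfTI skeleton)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not wmaps:
        return
    space = wmaps[0].space
    if space == "surface":
        maps = [
            ScalarMap(wm.subject_id, "other", "surface", np.nan_to_num(wm.w))
            for wm in wmaps
        ]
        write_surface_maps(maps, outdir / "wscores.csv")
    else:
        for wm in wmaps:
            vol = geometry.embed_skeleton_values(np.nan_to_num(wm.w))
            write_volume(vol, outdir / f"{wm.subject_id}_w.nii", geometry.voxel_size_mm)


def write_statmap(statmap: StatMap, geometry: Geometry | None, outdir, name: str) -> None:
    """t/p pair (NIfTI for voxel spaces, CSV for surface) plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "contrast": list(statmap.contrast),
        "correction": statmap.correction,
        "alpha": statmap.alpha,
        "df": statmap.df,
        "space": statmap.space,
        "n_in_mask": int(statmap.in_mask.sum()),
        "n_significant": statmap.n_significant,
    }
    (outdir / f"{name}_summary.json").write_text(json.dumps(summary))
    p_out = statmap.p_corrected if statmap.p_corrected is not None else statmap.p
    if statmap.space == "surface":
        pd.DataFrame(
            {
                "vertex": np.arange(statmap.t.shape[0]),
                "t": statmap.t,
                "p": statmap.p,
                "p_corrected": p_out,
                "significant": statmap.significant.astype(int),
                "in_mask": statmap.in_mask.astype(int),
            }
        ).to_csv(outdir / f"{name}.csv", index=False)
    elif statmap.space == "skeleton":
        assert geometry is not None
        write_volume(
            geometry.embed_skeleton_values(np.nan_to_num(statmap.t)),
            outdir / f"{name}_t.nii",
            geometry.voxel_size_mm,
        )
        write_volume(
            geometry.embed_skeleton_values(np.nan_to_num(p_out, nan=1.0)),
            outdir / f"{name}_p.nii",
            geometry.voxel_size_mm,
        )
    else:  # full volume grid
        shape = statmap.grid_shape
        voxel = geometry.voxel_size_mm if geometry is not None else 2.0
        write_volume(np.nan_to_num(statmap.t).reshape(shape), outdir / f"{name}_t.nii", voxel)
        write_volume(
            np.nan_to_num(p_out, nan=1.0).reshape(shape), outdir / f"{name}_p.nii", voxel
        )
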