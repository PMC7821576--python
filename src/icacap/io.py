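"""File I/O: TSV matrices, covariate tables, JSON fits, optional NIfTI.

Formats
-------
covariates.tsv : header row of column names (first is ``intercept``),
    one subject per row.
<subject>.tsv : plain tab-separated T x K (or T x V) float matrix,
    no header, one time point per row.
truth.json / capfit.json / bootstrap.json : nested JSON mirroring the
    corresponding objects' ``to_dict``.
NIfTI : 4-D volumes with a 3-D binary mask; voxels are the mask's
    nonzero positions in x-fastest (Fortran) order, so column j of a
    series corresponds to the j-th nonzero mask voxel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CovariateDesign
from .simulate import SubjectSeries, TrueModel


# --- covariates ------------------------------------------------------------

def write_covariates(design: CovariateDesign, path: str | Path) -> None:
    design.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_covariates(path: str | Path) -> CovariateDesign:
    df = pd.read_csv(path, sep="\t")
    return CovariateDesign.from_dataframe(df)


# --- series ----------------------------------------------------------------

def write_series(series: list[SubjectSeries], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series:
        p = directory / f"{s.id}.tsv"
        np.savetxt(p, s.M, delimiter="\t", fmt="%.10g")
        paths.append(p)
    return paths


def read_series(directory: str | Path) -> list[SubjectSeries]:
    directory = Path(directory)
    out = []
    for p in sorted(directory.glob("*.tsv")):
        out.append(SubjectSeries(id=p.stem, M=np.loadtxt(p, delimiter="\t", ndmin=2)))
    if not out:
        raise FileNotFoundError(f"no .tsv series found in {directory}")
    return out


# --- matrices & json -------------------------------------------------------

def write_matrix(M: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.atleast_2d(M), delimiter="\t", fmt="%.10g")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(model: TrueModel, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def read_truth(path: str | Path) -> TrueModel:
    d = read_json(path)
    return TrueModel(
        K=d["K"],
        R=d["R"],
        Gamma=np.asarray(d["Gamma"]),
        beta=np.asarray(d["beta"]),
        base_logvals=np.asarray(d["base_logvals"]),
        seed=d["seed"],
        base_logval_range=tuple(d["base_logval_range"]),
    )


# --- NIfTI (optional; requires nibabel) ------------------------------------

def read_nifti_series(
    img_path: str | Path, mask_path: str | Path, subject_id: str | None = None
) -> SubjectSeries:
    """Extract a T x V series from a 4-D NIfTI using a binary mask.

    Voxels are taken in x-fastest (Fortran) order of the mask's nonzero
    positions.
    """
    import nibabel as nib

    img = nib.load(str(img_path))
    mask = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    m = np.asarray(mask.dataobj) > 0
    idx = np.nonzero(m.ravel(order="F"))[0]
    flat = data.reshape(-1, data.shape[3], order="F")
    M = flat[idx].T
    return SubjectSeries(id=subject_id or Path(img_path).stem, M=M)


def write_maps_nifti(
    Omega: np.ndarray, mask_path: str | Path, out_prefix: str | Path
) -> list[Path]:
    """Write each map row back into mask geometry as a 3-D NIfTI."""
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    m = np.asarray(mask_img.dataobj) > 0
    idx = np.nonzero(m.ravel(order="F"))[0]
    paths = []
    for c, row in enumerate(np.atleast_2d(Omega)):
        vol = np.zeros(m.size)
        vol[idx] = row
        vol = vol.reshape(m.shape, order="F")
        img = nib.Nifti1Image(vol, mask_img.affine)
        p = Path(f"{out_prefix}_C{c + 1}.nii.gz")
        nib.save(img, str(p))
        paths.append(p)
    return paths
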