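"""Readers and writers for the standard on-disk formats.

NIfTI-1 for volumes and integer label maps (via nibabel), TSV for motion
traces and confound matrices (fMRIPrep column conventions), CSV for
connectivity matrices, JSON for manifests and reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import AcquisitionGrid, BoldVolume, MotionTrace, Parcellation


def write_bold(vol: BoldVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.grid.affine)
    img.header.set_zooms((*vol.grid.voxel_size, vol.grid.tr))
    nib.save(img, str(path))


def read_bold(path: str | Path, mask: np.ndarray | None = None) -> BoldVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D BOLD image")
    zooms = img.header.get_zooms()
    grid = AcquisitionGrid(
        dims=data.shape[:3],
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.5,
        n_volumes=data.shape[3],
    )
    if mask is None:
        mask = data.std(axis=-1) > 0
    return BoldVolume(data=data, grid=grid, mask=np.asarray(mask, dtype=bool))


def write_label_map(labels: np.ndarray, grid: AcquisitionGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), grid.affine)
    nib.save(img, str(path))


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_motion_tsv(motion: MotionTrace, path: str | Path) -> None:
    df = pd.DataFrame(motion.params, columns=list(MotionTrace.COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_motion_tsv(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MotionTrace.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV {path} missing columns {missing}")
    return MotionTrace(params=df[list(MotionTrace.COLUMNS)].to_numpy(dtype=float))


def write_parcellation_tables(parc: Parcellation, path: str | Path) -> None:
    payload = {
        "roi_names": {str(k): v for k, v in parc.roi_names.items()},
        "network_of": {str(k): parc.network_of.get(k) for k in parc.roi_names},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_parcellation(label_path: str | Path, table_path: str | Path) -> Parcellation:
    labels = read_label_map(label_path)
    with open(table_path) as fh:
        payload = json.load(fh)
    roi_names = {int(k): v for k, v in payload["roi_names"].items()}
    network_of = {int(k): v for k, v in payload["network_of"].items()}
    return Parcellation(labels=labels, roi_names=roi_names, network_of=network_of)


def write_matrix_csv(matrix: np.ndarray, names: list[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=names, columns=names).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)
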