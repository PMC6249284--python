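"""Readers/writers for the pipeline's on-disk formats.

Tables are TSV (pandas), volumes are NIfTI-1 (nibabel, RAS affine), motion
traces are 6-column TSV (translations mm, rotations degrees), censor masks
are one-column 0/1 TSV, and configs/models round-trip through YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_motion(trace: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(trace), delimiter="\t", fmt="%.6f")


def read_motion(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t").reshape(-1, 6)


def write_censor(keep: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(keep, int), fmt="%d")


def read_censor(path) -> np.ndarray:
    return np.loadtxt(path).astype(bool)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce))


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
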