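"""Volume censoring, retention-based exclusion, and nuisance regression.

Per-volume head movement is summarized as the Euclidean norm of the
point-to-point change in the six rigid-body parameters.  Volumes exceeding
0.3 mm movement and/or a 10% outlier-voxel fraction (strict inequalities)
are censored after dropping the first six volumes of each run; subjects
retaining less than 60% of volumes across their two runs are excluded.

The nuisance GLM removes, per voxel: the six motion parameters and their
first derivatives, a discrete-cosine drift basis below 0.01 Hz, the first
three principal components of the eroded ventricle mask, and the mean
eroded white-matter signal.  The fit uses retained volumes only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .simulate import BoldRun


@dataclass
class CensorThresholds:
    movement_mm: float = 0.3
    outlier_frac: float = 0.10
    retention_min: float = 0.60
    drop_initial: int = 6


@dataclass
class CensorMask:
    keep: List[np.ndarray]        # per run, boolean over post-drop volumes
    retention: float
    include_subject: bool
    n_censored: int


def euclidean_movement(trace: np.ndarray) -> np.ndarray:
    """Per-volume displacement: sqrt of summed squared parameter changes.

    The first volume has displacement 0 by convention.  Translations (mm)
    and rotations (degrees) enter on their native scales, matching the
    six-parameter point-to-point norm.
    """
    trace = np.asarray(trace, float)
    if trace.ndim != 2 or trace.shape[0] < 2 or trace.shape[1] != 6:
        raise ValueError("trace must be (T >= 2, 6)")
    d = np.zeros(trace.shape[0])
    d[1:] = np.sqrt((np.diff(trace, axis=0) ** 2).sum(axis=1))
    return d


def outlier_fraction(run: np.ndarray, mask: np.ndarray, k: float = 3.5) -> np.ndarray:
    """Fraction of in-mask voxels deviating > k robust SDs from their
    run median, after removing a per-voxel linear trend.

    Robust SD = 1.4826 * median absolute deviation.  Constant voxels never
    count as outliers.
    """
    if not mask.any():
        raise ValueError("empty mask")
    ts = np.asarray(run[mask], float)  # (V, T)
    T = ts.shape[1]
    t = np.arange(T) - (T - 1) / 2.0
    slope = (ts * t).sum(1) / (t ** 2).sum()
    ts = ts - slope[:, None] * t[None, :]
    med = np.median(ts, axis=1, keepdims=True)
    dev = np.abs(ts - med)
    mad = np.median(dev, axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dev > k * robust_sd
    out[robust_sd[:, 0] == 0] = False
    return out.mean(axis=0)


def censor(
    traces: Sequence[np.ndarray],
    runs: Sequence[np.ndarray],
    mask: np.ndarray,
    thresholds: CensorThresholds = CensorThresholds(),
    outlier_k: float = 3.5,
) -> CensorMask:
    """Censor volumes and decide subject inclusion.

    *traces* and *runs* are parallel per-run sequences (full runs; the
    first ``drop_initial`` volumes of each are discarded before any
    thresholding).  A volume is censored iff movement > 0.3 mm OR outlier
    fraction > 0.10, both strict.  Retention is pooled across runs.
    """
    if len(traces) != len(runs):
        raise ValueError("one motion trace per run required")
    keep_masks, kept, total = [], 0, 0
    d0 = thresholds.drop_initial
    for trace, run in zip(traces, runs):
        trace = np.asarray(trace, float)[d0:]
        data = run[..., d0:]
        move = euclidean_movement(trace)
        ofrac = outlier_fraction(data, mask, k=outlier_k)
        keep = ~((move > thresholds.movement_mm) |
                 (ofrac > thresholds.outlier_frac))
        keep_masks.append(keep)
        kept += int(keep.sum())
        total += keep.size
    retention = kept / total
    return CensorMask(
        keep=keep_masks,
        retention=retention,
        include_subject=retention >= thresholds.retention_min,
        n_censored=total - kept,
    )


def dct_drift_basis(T: int, tr_s: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Discrete-cosine regressors spanning frequencies below *cutoff_hz*."""
    duration = T * tr_s
    n_basis = int(np.floor(2 * duration * cutoff_hz))
    t = np.arange(T)
    cols = [np.cos(np.pi * (t + 0.5) * k / T) for k in range(1, n_basis + 1)]
    if not cols:
        return np.empty((T, 0))
    return np.column_stack(cols)


def _erode(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0:
        return mask
    eroded = ndimage.binary_erosion(mask, iterations=iterations)
    # a thin synthetic mask can vanish under erosion; fall back un-eroded
    return eroded if eroded.any() else mask


def nuisance_regress(
    run: np.ndarray,
    trace: np.ndarray,
    keep: np.ndarray,
    wm_mask: np.ndarray,
    vent_mask: np.ndarray,
    tr_s: float,
    drop_initial: int = 6,
    drift_cutoff_hz: float = 0.01,
    erode_iterations: int = 1,
    analysis_mask: Optional[np.ndarray] = None,
):
    """Project nuisance structure out of each voxel's retained time course.

    Returns ``(residuals, design)`` where residuals has shape
    (X, Y, Z, n_kept) over the analysis mask (zeros elsewhere) and design is
    the (n_kept, p) regressor matrix actually used.  Collinear regressors
    are dropped with a warning rather than inverted unstably.
    """
    data = np.asarray(run[..., drop_initial:], float)
    trace = np.asarray(trace, float)[drop_initial:]
    keep = np.asarray(keep, bool)
    T = data.shape[-1]
    if keep.size != T or trace.shape[0] != T:
        raise ValueError("censor mask / trace length mismatch with run")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(trace, axis=0)])
    drift = dct_drift_basis(T, tr_s, drift_cutoff_hz)
    wm_e = _erode(wm_mask, erode_iterations)
    vent_e = _erode(vent_mask, erode_iterations)
    wm_mean = data[wm_e].mean(axis=0)
    vent_ts = data[vent_e] - data[vent_e].mean(axis=1, keepdims=True)
    n_pc = min(3, vent_ts.shape[0])
    U, s, Vt = np.linalg.svd(vent_ts.T[keep], full_matrices=False)
    vent_pcs = np.zeros((T, n_pc))
    vent_pcs[keep] = U[:, :n_pc]
    X = np.column_stack([
        np.ones(T), trace, deriv, drift, vent_pcs, wm_mean,
    ])
    Xk = X[keep]
    # drop collinear columns (rank-revealing QR via pivoted lstsq check)
    keep_cols = _independent_columns(Xk)
    if len(keep_cols) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(keep_cols)} collinear nuisance "
            "regressors")
    Xk = Xk[:, keep_cols]
    mask = (wm_mask | vent_mask | np.ones_like(wm_mask)) if analysis_mask is None \
        else analysis_mask
    Y = data[mask][:, keep].T  # (n_kept, V)
    beta, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    resid = Y - Xk @ beta
    out = np.zeros(data.shape[:3] + (int(keep.sum()),), float)
    out[mask] = resid.T
    return out, Xk


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list:
    cols: list = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        v = X[:, j]
        if basis.shape[1]:
            v = v - basis @ (basis.T @ v)
        nv = np.linalg.norm(v)
        if nv > tol * max(1.0, np.linalg.norm(X[:, j])):
            cols.append(j)
            basis = np.column_stack([basis, v / nv])
    return cols
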