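"""Intrinsic connectivity distribution (ICD) mapping and voxelwise inference.

For each gray-matter voxel the distribution of its correlations to every
other gray-matter voxel is summarized by the positive-tail survival curve
S(tau) = fraction of other voxels with r > tau, which is well approximated
by a stretched exponential S(tau) ~ exp(-(alpha * tau)^beta).  Alpha scales
and beta shapes the curve; smaller alpha and larger beta both indicate a
heavier tail of strong correlations, i.e. a larger voxel degree at any
threshold.

Group inference regresses the (smoothed) per-subject parameter maps on a
continuous phenotype with covariates, voxel by voxel, and controls
familywise error by cluster extent: null Gaussian fields matched to the
residual maps' estimated per-axis smoothness are simulated in the mask, and
only clusters larger than the (1 - cluster_p) quantile of the null maximum
cluster size survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

DEFAULT_TAU_GRID = np.round(np.arange(0.0, 1.0, 0.01), 10)


def correlation_survival(ts: np.ndarray, tau_grid: np.ndarray = DEFAULT_TAU_GRID):
    """Positive-tail survival curves of voxel-to-voxel correlations.

    *ts* is (V, T): one time course per in-mask voxel.  Returns
    ``(curves, valid)`` where curves[v, g] = fraction of *other* valid
    voxels with corr(v, w) > tau_grid[g].  Zero-variance voxels are flagged
    invalid and excluded from both sides of every comparison.
    """
    ts = np.asarray(ts, float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("need (V, T) time courses with T >= 2")
    tau_grid = np.asarray(tau_grid, float)
    if tau_grid.min() < 0 or tau_grid.max() >= 1:
        raise ValueError("tau grid must lie in [0, 1)")
    sd = ts.std(axis=1)
    valid = sd > 0
    V = ts.shape[0]
    curves = np.full((V, tau_grid.size), np.nan)
    vidx = np.where(valid)[0]
    if vidx.size < 2:
        return curves, valid
    C = np.corrcoef(ts[vidx])
    n_other = vidx.size - 1
    for g, tau in enumerate(tau_grid):
        counts = (C > tau).sum(axis=1) - 1  # self-correlation 1 > tau always
        curves[vidx, g] = counts / n_other
    return curves, valid


def stretched_exponential(tau, alpha, beta):
    return np.exp(-np.power(np.maximum(alpha * tau, 0.0), beta))


def stretched_exponential_alt(tau, alpha, beta):
    """Alternative parameterization exp(-(tau/alpha)^beta)."""
    return np.exp(-np.power(np.maximum(tau / alpha, 0.0), beta))


def fit_stretched_exponential(
    tau_grid: np.ndarray,
    curve: np.ndarray,
    parameterization: str = "alpha_times_tau",
):
    """Nonlinear least squares of S(tau) ~ exp(-(alpha tau)^beta).

    Bounds alpha, beta in (0, 100], init (1, 1).  Returns
    ``(alpha, beta, diagnostics)``; on failure the parameters are NaN and
    the converged flag False.
    """
    tau = np.asarray(tau_grid, float)
    y = np.asarray(curve, float)
    ok = np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need at least 5 finite curve points")
    if y[ok].min() < -1e-9 or y[ok].max() > 1 + 1e-9:
        raise ValueError("survival curve must lie in [0, 1]")
    model = (stretched_exponential if parameterization == "alpha_times_tau"
             else stretched_exponential_alt)
    try:
        popt, _ = optimize.curve_fit(
            model, tau[ok], y[ok], p0=(1.0, 1.0),
            bounds=((1e-6, 1e-6), (100.0, 100.0)), maxfev=2000)
        resid = y[ok] - model(tau[ok], *popt)
        diag = {"converged": True, "resid_norm": float(np.linalg.norm(resid))}
        return float(popt[0]), float(popt[1]), diag
    except RuntimeError:
        return np.nan, np.nan, {"converged": False, "resid_norm": np.nan}


@dataclass
class IcdMaps:
    alpha: np.ndarray          # 3D, NaN outside mask / non-converged
    beta: np.ndarray
    gm_mask: np.ndarray
    converged: np.ndarray      # 3D bool
    resid_norm: np.ndarray


def icd_subject(
    resid: np.ndarray,
    gm_mask: np.ndarray,
    tau_grid: np.ndarray = DEFAULT_TAU_GRID,
    parameterization: str = "alpha_times_tau",
) -> IcdMaps:
    """Per-voxel ICD parameter maps from nuisance-regressed, censored data.

    *resid* is (X, Y, Z, T_kept).  Deterministic: depends only on the
    residual data, mask and grid.
    """
    ts = resid[gm_mask]
    curves, valid = correlation_survival(ts, tau_grid)
    shape = gm_mask.shape
    alpha = np.full(shape, np.nan)
    beta = np.full(shape, np.nan)
    conv = np.zeros(shape, bool)
    rnorm = np.full(shape, np.nan)
    coords = np.argwhere(gm_mask)
    for row, (i, j, k) in enumerate(coords):
        if not valid[row]:
            continue
        a, b, diag = fit_stretched_exponential(tau_grid, curves[row],
                                               parameterization)
        alpha[i, j, k], beta[i, j, k] = a, b
        conv[i, j, k] = diag["converged"]
        rnorm[i, j, k] = diag["resid_norm"]
    return IcdMaps(alpha, beta, gm_mask, conv, rnorm)


def smooth_map(map3d: np.ndarray, fwhm_mm: float, mask: np.ndarray,
               voxel_size_mm: float = 3.0) -> np.ndarray:
    """Gaussian smoothing restricted to the mask, kernel renormalized at
    edges so a constant map is unchanged.  fwhm=0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.where(mask, map3d, np.nan)
    sigma = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / voxel_size_mm
    filled = np.where(mask & np.isfinite(map3d), map3d, 0.0)
    weight = (mask & np.isfinite(map3d)).astype(float)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(weight, sigma)
    out = np.full(map3d.shape, np.nan)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def voxelwise_model(
    maps: Sequence[np.ndarray],
    covariates: pd.DataFrame,
    focal: str,
    mask: np.ndarray,
):
    """Per-voxel OLS of subject maps on phenotype + covariates.

    Returns ``(t_map, p_map, resid_maps, df)`` where t/p concern the focal
    slope and resid_maps (n_subjects long) feed smoothness estimation for
    cluster correction.  Voxels with any non-finite subject value are
    dropped from inference.
    """
    n = len(maps)
    X = np.column_stack([np.ones(n), covariates.to_numpy(float)])
    names = ["const", *covariates.columns]
    if focal not in names:
        raise ValueError(f"focal predictor {focal!r} not among covariates")
    if n <= X.shape[1]:
        raise ValueError("more predictors than subjects")
    Y = np.stack([m[mask] for m in maps])  # (n, V)
    good = np.isfinite(Y).all(axis=0)
    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y[:, good]
    resid = Y[:, good] - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    j = names.index(focal)
    se = np.sqrt(np.clip(sigma2 * XtX_inv[j, j], 1e-300, None))
    tvals = beta[j] / se
    coords = np.argwhere(mask)[good]
    t_map[tuple(coords.T)] = tvals
    p_map[tuple(coords.T)] = 2 * stats.t.sf(np.abs(tvals), dof)
    resid_maps = []
    for i in range(n):
        rm = np.full(mask.shape, np.nan)
        rm[tuple(coords.T)] = resid[i]
        resid_maps.append(rm)
    return t_map, p_map, resid_maps, dof


def estimate_fwhm(resid_maps: Sequence[np.ndarray], mask: np.ndarray,
                  voxel_size_mm: float = 3.0) -> np.ndarray:
    """Per-axis Gaussian FWHM (mm) from residual spatial autocorrelation.

    Uses the classic first-difference estimator: with neighbor correlation
    rho = 1 - var(diff) / (2 var), a Gaussian ACF gives
    FWHM = dx * sqrt(2 ln 2 / (-ln rho)).  Averaged across subjects.
    """
    fwhms = np.zeros((len(resid_maps), 3))
    for s, m in enumerate(resid_maps):
        for ax in range(3):
            a = m
            b = np.roll(m, -1, axis=ax)
            pair_mask = mask & np.roll(mask, -1, axis=ax)
            sl = [slice(None)] * 3
            sl[ax] = slice(0, -1)
            pair_mask = pair_mask.copy()
            end = [slice(None)] * 3
            end[ax] = slice(-1, None)
            pair_mask[tuple(end)] = False
            diffs = (b - a)[pair_mask]
            vals = m[mask & np.isfinite(m)]
            var = np.var(vals)
            if diffs.size < 2 or var <= 0:
                fwhms[s, ax] = np.nan
                continue
            rho = 1 - np.var(diffs) / (2 * var)
            if rho <= 0 or rho >= 1:
                fwhms[s, ax] = voxel_size_mm  # unsmoothed floor
                continue
            fwhms[s, ax] = voxel_size_mm * np.sqrt(2 * np.log(2) / (-np.log(rho)))
    return np.nanmean(fwhms, axis=0)


@dataclass
class ClusterResult:
    clusters: List[dict]
    cluster_size_threshold: int
    voxel_p: float
    cluster_p: float
    fwhm_mm: np.ndarray
    null_max_sizes: np.ndarray


def simulate_max_cluster_sizes(
    mask: np.ndarray,
    fwhm_mm: np.ndarray,
    voxel_p: float,
    iters: int,
    voxel_size_mm: float = 3.0,
    connectivity: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Monte-Carlo null distribution of the largest supra-threshold cluster.

    Each iterate smooths a white Gaussian field to the target per-axis
    FWHM, standardizes it within the mask, applies the two-sided voxel
    threshold, and records the largest connected component (positive or
    negative)."""
    if iters < 100:
        warnings.warn("fewer than 100 iterations gives an unstable threshold")
    if not mask.any():
        raise ValueError("empty mask")
    rng = np.random.default_rng() if rng is None else rng
    sigma_vox = np.asarray(fwhm_mm, float) / (2 * np.sqrt(2 * np.log(2))) \
        / voxel_size_mm
    sigma_vox = np.nan_to_num(sigma_vox, nan=0.0)
    zcrit = stats.norm.isf(voxel_p / 2)
    structure = ndimage.generate_binary_structure(3, connectivity)
    out = np.empty(iters, int)
    for i in range(iters):
        field = rng.standard_normal(mask.shape)
        if sigma_vox.max() > 0:
            field = ndimage.gaussian_filter(field, sigma_vox)
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        best = 0
        for sign in (1, -1):
            supra = mask & (sign * field > zcrit)
            if supra.any():
                lab, n = ndimage.label(supra, structure=structure)
                if n:
                    best = max(best, int(np.bincount(lab.ravel())[1:].max()))
        out[i] = best
    return out


def cluster_size_threshold(null_max_sizes: np.ndarray, cluster_p: float) -> int:
    """Smallest size s with P(null max cluster >= s) <= cluster_p."""
    sizes = np.asarray(null_max_sizes)
    for s in range(1, int(sizes.max()) + 2):
        if (sizes >= s).mean() <= cluster_p:
            return s
    return int(sizes.max()) + 1


def cluster_correct(
    t_map: np.ndarray,
    resid_maps: Sequence[np.ndarray],
    mask: np.ndarray,
    dof: int,
    affine: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    iters: int = 10000,
    voxel_size_mm: float = 3.0,
    connectivity: int = 1,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-extent familywise-error correction of a voxelwise t-map.

    Smoothness is estimated from the model residual maps; the null maximum
    cluster-size distribution is simulated in the analysis mask (the search
    space is exactly the masked voxel set); observed two-sided
    supra-threshold clusters at ``voxel_p`` survive if their extent meets
    the (1 - cluster_p) null quantile.
    """
    fwhm = estimate_fwhm(resid_maps, mask, voxel_size_mm)
    rng = np.random.default_rng(seed)
    null_sizes = simulate_max_cluster_sizes(
        mask, fwhm, voxel_p, iters, voxel_size_mm, connectivity, rng)
    thresh = cluster_size_threshold(null_sizes, cluster_p)
    tcrit = stats.t.isf(voxel_p / 2, dof)
    structure = ndimage.generate_binary_structure(3, connectivity)
    clusters = []
    for sign in (1, -1):
        supra = mask & np.isfinite(t_map) & (sign * t_map > tcrit)
        lab, n = ndimage.label(supra, structure=structure)
        for c in range(1, n + 1):
            vox = np.argwhere(lab == c)
            if len(vox) < thresh:
                continue
            tvals = t_map[tuple(vox.T)]
            peak_idx = vox[np.argmax(np.abs(tvals))]
            peak_mm = (affine @ np.append(peak_idx, 1.0))[:3]
            clusters.append({
                "size": int(len(vox)),
                "sign": sign,
                "peak_t": float(tvals[np.argmax(np.abs(tvals))]),
                "peak_ijk": tuple(int(v) for v in peak_idx),
                "peak_mm": tuple(float(v) for v in peak_mm),
                "voxels": vox,
            })
    clusters.sort(key=lambda c: -c["size"])
    return ClusterResult(clusters, thresh, voxel_p, cluster_p, fwhm, null_sizes)


def influence_check(
    values: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    cooks_cutoff: Optional[float] = None,
    dfbeta_cutoff: Optional[float] = None,
    restrict_abs: float = 20.0,
) -> dict:
    """Influence diagnostics for the focal phenotype slope.

    Fits values ~ phenotype (+ covariates); flags points by Cook's distance
    (default cutoff 4/n) or |DFBETA| of the focal slope (default 2/sqrt(n));
    refits without flagged points and on the |phenotype| <= restrict_abs
    subset, reporting the focal p-value for each fit.
    """
    import statsmodels.api as sm

    y = np.asarray(values, float)
    x = np.asarray(phenotype, float)
    n = y.size
    parts = {"phenotype": x}
    if covariates is not None:
        for c in covariates.columns:
            parts[c] = covariates[c].to_numpy(float)
    X = sm.add_constant(pd.DataFrame(parts))
    res = sm.OLS(y, X).fit()
    infl = res.get_influence()
    cooks = infl.cooks_distance[0]
    j = list(X.columns).index("phenotype")
    dfb = infl.dfbetas[:, j]
    cooks_cutoff = 4.0 / n if cooks_cutoff is None else cooks_cutoff
    dfbeta_cutoff = 2.0 / np.sqrt(n) if dfbeta_cutoff is None else dfbeta_cutoff
    flagged = np.where((cooks > cooks_cutoff) | (np.abs(dfb) > dfbeta_cutoff))[0]
    out = {
        "full_p": float(res.pvalues["phenotype"]),
        "full_slope": float(res.params["phenotype"]),
        "flagged": flagged,
        "cooks": cooks,
        "dfbetas_focal": dfb,
    }
    keep = np.setdiff1d(np.arange(n), flagged)
    if keep.size <= X.shape[1]:
        raise ValueError("too few points remain after excluding influential ones")
    res_ex = sm.OLS(y[keep], X.iloc[keep]).fit()
    out["excluded_p"] = float(res_ex.pvalues["phenotype"])
    out["excluded_slope"] = float(res_ex.params["phenotype"])
    inrange = np.abs(x) <= restrict_abs
    if inrange.sum() <= X.shape[1]:
        raise ValueError("too few points within the restricted phenotype range")
    res_r = sm.OLS(y[inrange], X.loc[inrange]).fit()
    out["restricted_p"] = float(res_r.pvalues["phenotype"])
    out["restricted_slope"] = float(res_r.params["phenotype"])
    return out
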