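"""Seed-based network definition and genotype-connectivity regressions.

From the seed region isolated by the ICD analysis, per-subject seed
correlation maps are computed (Pearson r of each voxel with the mean seed
time course, Fisher z transformed), combined in a one-sample group t-test,
and reduced to peak nodes with a minimum separation distance.  Sphere ROIs
around each peak yield per-subject mean connectivity values, which are
regressed on RU2Short carrier status with covariates pre-screened by
backward selection at alpha = .05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats

R_CLIP = 1.0 - 1e-7


def seed_corr_map(resid: np.ndarray, seed_mask: np.ndarray,
                  analysis_mask: np.ndarray) -> np.ndarray:
    """Fisher-z map of correlations with the mean seed time course.

    *resid* is censored, nuisance-regressed data (X, Y, Z, T_kept).
    Correlations with |r| = 1 (e.g. voxels inside a one-voxel seed) are
    clipped to +/-(1 - 1e-7) before arctanh.
    """
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    seed_ts = resid[seed_mask].mean(axis=0)
    if seed_ts.std() == 0:
        raise ValueError("seed time course has zero variance")
    ts = resid[analysis_mask]
    ts_c = ts - ts.mean(axis=1, keepdims=True)
    s_c = seed_ts - seed_ts.mean()
    denom = np.sqrt((ts_c ** 2).sum(axis=1) * (s_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ts_c @ s_c) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    out = np.full(resid.shape[:3], np.nan)
    out[analysis_mask] = z
    return out


def group_network(z_maps: Sequence[np.ndarray], mask: np.ndarray,
                  p_thresh: float = 1e-6, t_cap: float = 1e6):
    """One-sample t-test across subjects per voxel; positive network mask.

    Returns ``(t_map, network_mask)``.  Degenerate voxels with zero
    between-subject variance and nonzero mean get the capped t value.  The
    default threshold is far looser than the production-scale 1e-20 used
    with large real samples, which presumes very large t statistics.
    """
    Z = np.stack([m[mask] for m in z_maps])
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(mean) * t_cap, t)
    p = 2 * stats.t.sf(np.minimum(np.abs(t), t_cap), n - 1)
    t_map = np.full(mask.shape, np.nan)
    t_map[mask] = t
    net = np.zeros(mask.shape, bool)
    net[mask] = (p < p_thresh) & (t > 0)
    return t_map, net


def find_peaks(t_map: np.ndarray, mask: np.ndarray, affine: np.ndarray,
               min_sep_mm: float = 30.0) -> List[dict]:
    """Local maxima of the t-map within the mask, greedily thinned so that
    retained peaks are pairwise >= min_sep_mm apart (larger values win)."""
    if min_sep_mm < 0:
        raise ValueError("min_sep_mm must be >= 0")
    if not mask.any():
        return []
    vals = np.where(mask & np.isfinite(t_map), t_map, -np.inf)
    local_max = ndimage.maximum_filter(vals, size=3, mode="constant",
                                       cval=-np.inf) == vals
    cand = np.argwhere(local_max & mask & np.isfinite(t_map))
    order = np.argsort(-t_map[tuple(cand.T)])
    kept: List[dict] = []
    for idx in cand[order]:
        mm = (affine @ np.append(idx, 1.0))[:3]
        if all(np.linalg.norm(mm - np.asarray(k["mm"])) >= min_sep_mm
               for k in kept):
            kept.append({
                "ijk": tuple(int(v) for v in idx),
                "mm": tuple(float(v) for v in mm),
                "value": float(t_map[tuple(idx)]),
            })
    return kept


def sphere_roi(peak_mm: Sequence[float], grid_shape: Tuple[int, int, int],
               affine: np.ndarray, radius_mm: float = 6.0) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within radius of the peak
    voxel center.  The peak is snapped to its containing voxel first, so a
    6 mm radius on a 3 mm grid yields the canonical 33-voxel sphere
    (continuous volume 33.5 voxel volumes)."""
    inv = np.linalg.inv(affine)
    ijk = (inv @ np.append(np.asarray(peak_mm, float), 1.0))[:3]
    center_ijk = np.round(ijk).astype(int)
    if np.any(center_ijk < 0) or np.any(center_ijk >= np.asarray(grid_shape)):
        raise ValueError(f"peak {peak_mm} falls outside the grid")
    center_mm = (affine @ np.append(center_ijk, 1.0))[:3]
    idx = np.indices(grid_shape).astype(float)
    coords = np.stack([
        affine[d, d] * idx[d] + affine[d, 3] for d in range(3)], axis=-1)
    d = np.sqrt(((coords - center_mm) ** 2).sum(-1))
    mask = d <= radius_mm + 1e-9
    # flag (via warning) spheres clipped by the grid edge
    lo = center_ijk - int(np.ceil(radius_mm / np.abs(np.diag(affine)[:3]).min()))
    hi = center_ijk + int(np.ceil(radius_mm / np.abs(np.diag(affine)[:3]).min()))
    if np.any(lo < 0) or np.any(hi >= np.asarray(grid_shape)):
        import warnings
        warnings.warn(f"sphere at {peak_mm} clipped at the grid edge")
    return mask


@dataclass
class NodeSet:
    labels: List[str]
    peaks_mm: List[Tuple[float, float, float]]
    spheres: List[np.ndarray]
    radius_mm: float

    def __post_init__(self):
        if len({s.shape for s in self.spheres}) > 1:
            raise ValueError("sphere masks must share a grid")


def build_node_set(peaks: List[dict], grid_shape, affine,
                   radius_mm: float = 6.0, labels: Optional[List[str]] = None
                   ) -> NodeSet:
    labels = labels or [f"node{i + 1}" for i in range(len(peaks))]
    spheres = [sphere_roi(p["mm"], grid_shape, affine, radius_mm)
               for p in peaks]
    return NodeSet(labels, [p["mm"] for p in peaks], spheres, radius_mm)


def node_values(z_maps: Sequence[np.ndarray], nodes: NodeSet) -> pd.DataFrame:
    """Per-subject mean Fisher-z within each node sphere."""
    rows = []
    for m in z_maps:
        rows.append([float(np.nanmean(m[s])) for s in nodes.spheres])
    return pd.DataFrame(rows, columns=nodes.labels)


def backward_select(y: np.ndarray, covariates: pd.DataFrame,
                    alpha: float = 0.05) -> List[str]:
    """Stepwise backward elimination at the inclusion/exclusion criterion.

    Starting from the full OLS model, repeatedly drop the covariate with
    the largest p-value above alpha (ties broken by column order) and
    refit, until every retained covariate has p <= alpha.  May return an
    empty list.
    """
    if covariates.shape[1] == 0:
        raise ValueError("empty covariate pool")
    if len(y) <= covariates.shape[1] + 2:
        raise ValueError("too few observations for the covariate pool")
    retained = list(covariates.columns)
    y = np.asarray(y, float)
    while retained:
        X = sm.add_constant(covariates[retained].astype(float))
        res = sm.OLS(y, X).fit()
        pvals = res.pvalues.drop("const")
        worst = None
        worst_p = alpha
        for name in retained:  # column order breaks ties deterministically
            if pvals[name] > worst_p:
                worst, worst_p = name, pvals[name]
        if worst is None:
            break
        retained.remove(worst)
    return retained


@dataclass
class NodeModel:
    node: str
    results: pd.DataFrame     # term, B, SE, p
    retained_covariates: List[str]

    def term(self, name: str) -> pd.Series:
        return self.results.set_index("term").loc[name]


def node_regression(values: np.ndarray, carrier: np.ndarray,
                    covariates: Optional[pd.DataFrame] = None,
                    node: str = "node") -> NodeModel:
    """OLS of node connectivity on carrier status plus retained covariates.

    The carrier indicator is always included; covariates are whatever the
    selection step retained for this node.
    """
    carrier = np.asarray(carrier, float)
    if np.unique(carrier).size < 2:
        raise ValueError("carrier indicator is constant")
    parts = {"carrier": carrier}
    retained: List[str] = []
    if covariates is not None and covariates.shape[1]:
        for c in covariates.columns:
            parts[c] = covariates[c].to_numpy(float)
        retained = list(covariates.columns)
    X = sm.add_constant(pd.DataFrame(parts))
    res = sm.OLS(np.asarray(values, float), X).fit()
    rows = [{"term": t, "B": float(res.params[t]), "SE": float(res.bse[t]),
             "p": float(res.pvalues[t])} for t in X.columns]
    return NodeModel(node, pd.DataFrame(rows), retained)


def analyze_network_nodes(
    node_vals: pd.DataFrame,
    carrier: np.ndarray,
    covariate_pool: pd.DataFrame,
    alpha: float = 0.05,
) -> Dict[str, NodeModel]:
    """Backward selection then a final carrier model for every node."""
    out: Dict[str, NodeModel] = {}
    for node in node_vals.columns:
        y = node_vals[node].to_numpy(float)
        retained = backward_select(y, covariate_pool, alpha=alpha)
        covs = covariate_pool[retained] if retained else None
        out[node] = node_regression(y, carrier, covs, node=node)
    return out
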