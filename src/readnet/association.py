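"""Carrier-group association: contingency testing, multinomial logistic
regression, multiple imputation with Rubin pooling, and sensitivity modes.

The focal analysis asks whether RU2Short carrier status predicts
comprehension-group membership (UPC reference, contrasts EAC-vs-UPC and
UGC-vs-UPC) after adjustment for age, vocabulary, sex, maternal education,
home-language variables, SES and ancestry principal components.  Sporadic
missingness in covariates is handled by chained-equation multiple
imputation with m replications pooled by Rubin's rules; the relative
efficiency of each pooled estimate is (1 + gamma/m)^-1 with gamma the
fraction of missing information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .phenotype import EAC, UGC, UPC, classify_groups

GROUP_ORDER = (UPC, EAC, UGC)

#: Default Table-4-style predictor set (ancestry PCs appended separately).
DEFAULT_PREDICTORS = (
    "age_months", "sex_female", "ppvt_vocab", "ses_low", "spanish_home",
    "bilingual", "maternal_edu_years", "carrier",
)

CONTINUOUS = {"age_months", "ppvt_vocab", "maternal_edu_years"}


class SeparationError(RuntimeError):
    def __init__(self, predictor):
        self.predictor = predictor
        super().__init__(
            f"quasi-separation detected: coefficient for {predictor!r} diverged")


@dataclass
class ContingencyTable:
    counts: pd.DataFrame          # groups x (carrier, non_carrier)
    proportions: pd.Series        # per-group carrier proportion

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


def carrier_contingency(labels: Sequence[str], carrier: Sequence) -> ContingencyTable:
    """Carrier-by-group counts over classified subjects.

    EXCLUDED carrier markers (dual deletions) and missing flags are dropped;
    labels outside {UPC, EAC, UGC} are ignored.
    """
    df = pd.DataFrame({"group": list(labels), "carrier": list(carrier)})
    df = df[df["group"].isin(GROUP_ORDER)]
    df = df[df["carrier"].isin([True, False])]
    rows = []
    for g in GROUP_ORDER:
        sub = df[df["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no subjects with usable calls")
        n_car = int(sub["carrier"].sum())
        rows.append((n_car, len(sub) - n_car))
    counts = pd.DataFrame(rows, index=list(GROUP_ORDER),
                          columns=["carrier", "non_carrier"])
    props = counts["carrier"] / counts.sum(axis=1)
    return ContingencyTable(counts, props.rename("carrier_proportion"))


def chi_square_independence(table: np.ndarray):
    """Pearson chi-square of independence, no continuity correction.

    Returns (statistic, df, p).  df = (rows-1)(cols-1); any zero expected
    cell raises with a suggestion to collapse categories.
    """
    table = np.asarray(table, float)
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count; collapse sparse rows/columns before testing")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


@dataclass
class ModelConfig:
    outcome: str = "group"
    reference: str = UPC
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    n_pcs: int = 10
    pc_prefix: str = "PC"
    standardize: bool = True

    def columns(self, df: pd.DataFrame) -> List[str]:
        cols = list(self.predictors)
        cols += [f"{self.pc_prefix}{i + 1}" for i in range(self.n_pcs)
                 if f"{self.pc_prefix}{i + 1}" in df.columns]
        return cols


@dataclass
class MultinomialFit:
    reference: str
    results: pd.DataFrame  # contrast, predictor, coef, se, OR, ci, p
    nagelkerke_r2: float
    n: int
    loglik: float
    params: np.ndarray            # stacked coefficient vector (with intercepts)
    cov: np.ndarray
    param_names: List[str]


def _design(df: pd.DataFrame, config: ModelConfig):
    cols = config.columns(df)
    data = df[[config.outcome, *cols]].dropna().copy()
    X = data[cols].astype(float)
    if config.standardize:
        for c in cols:
            if c in CONTINUOUS:
                sd = X[c].std()
                X[c] = (X[c] - X[c].mean()) / (sd if sd > 0 else 1.0)
    X = sm.add_constant(X, has_constant="add")
    levels = [config.reference] + [g for g in GROUP_ORDER
                                   if g != config.reference]
    y = pd.Categorical(data[config.outcome], categories=levels).codes
    if (y < 0).any():
        raise ValueError("outcome contains labels outside the group set")
    if len(np.unique(y)) < 3:
        raise ValueError("outcome must have 3 observed levels")
    return X, y, levels, data


def _separating_predictor(X: pd.DataFrame, y: np.ndarray, coef: np.ndarray):
    """Best guess at the predictor causing quasi-separation: a binary column
    with an empty cell against some outcome level, else the largest finite
    coefficient's row."""
    for c in X.columns:
        col = X[c].to_numpy()
        if len(np.unique(col)) == 2:
            for level in np.unique(y):
                if len(np.unique(col[y == level])) == 1 and \
                        len(np.unique(col[y != level])) == 2:
                    return c
    if np.isfinite(coef).any():
        p_idx = int(np.unravel_index(np.nanargmax(np.abs(coef)), coef.shape)[0])
        return X.columns[p_idx]
    return "<undetermined>"


def fit_multinomial(df: pd.DataFrame, config: ModelConfig = ModelConfig()) -> MultinomialFit:
    """Maximum-likelihood multinomial logit with Wald 95% CIs on the OR scale.

    Nagelkerke pseudo-R^2 = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n)).
    """
    X, y, levels, data = _design(df, config)
    model = sm.MNLogit(y, X)
    with np.errstate(over="ignore", invalid="ignore"):
        res = model.fit(method="newton", maxiter=200, disp=False)
    coef = np.asarray(res.params)  # (p, J-1)
    bse = np.asarray(res.bse)
    if (not np.isfinite(coef).all() or not np.isfinite(bse).all()
            or np.abs(coef).max() > 15 or bse.max() > 50):
        raise SeparationError(_separating_predictor(X, y, coef))
    zcrit = stats.norm.ppf(0.975)
    rows = []
    for j, level in enumerate(levels[1:]):
        for i, name in enumerate(X.columns):
            b, se = coef[i, j], bse[i, j]
            pval = 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
            rows.append({
                "contrast": f"{level}_vs_{config.reference}",
                "predictor": name,
                "coef": b, "se": se,
                "OR": np.exp(b),
                "ci_low": np.exp(b - zcrit * se),
                "ci_high": np.exp(b + zcrit * se),
                "p": pval,
            })
    n = len(data)
    ll1, ll0 = res.llf, res.llnull
    r2_cs = 1 - np.exp(2 * (ll0 - ll1) / n)
    r2_max = 1 - np.exp(2 * ll0 / n)
    nagelkerke = float(r2_cs / r2_max) if r2_max > 0 else 0.0
    return MultinomialFit(
        reference=config.reference,
        results=pd.DataFrame(rows),
        nagelkerke_r2=nagelkerke,
        n=n,
        loglik=float(ll1),
        params=coef.T.ravel(),
        cov=np.asarray(res.cov_params()),
        param_names=[f"{lvl}_vs_{config.reference}:{c}"
                     for lvl in levels[1:] for c in X.columns],
    )


@dataclass
class PooledFit:
    m: int
    results: pd.DataFrame  # contrast, predictor, coef, se, OR, ci, p, gamma, RE
    relative_efficiency: Dict[str, float]  # per predictor (min over contrasts)
    nagelkerke_r2: float

    @property
    def min_relative_efficiency(self) -> float:
        return min(self.relative_efficiency.values())


def rubin_pool(params: np.ndarray, covs: np.ndarray, names: List[str],
               m: int) -> pd.DataFrame:
    """Pool m estimate vectors by Rubin's rules.

    W = mean within-imputation variance, B = between-imputation variance,
    T = W + (1 + 1/m) B; gamma = (1 + 1/m) B / T (large-sample fraction of
    missing information); relative efficiency = (1 + gamma/m)^-1.  p-values
    use the Barnard-Rubin small-sample t reference.
    """
    Q = np.asarray(params)               # (m, p)
    qbar = Q.mean(axis=0)
    W = np.stack([np.diag(c) for c in covs]).mean(axis=0)
    B = Q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1 + 1 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(T > 0, (1 + 1 / m) * B / T, 0.0)
        re = 1.0 / (1.0 + gamma / m)
        df = np.where(B > 0, (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2, np.inf)
    se = np.sqrt(T)
    tstat = np.where(se > 0, qbar / se, np.nan)
    p = np.array([
        2 * stats.t.sf(abs(t_), d_) if np.isfinite(d_) else 2 * stats.norm.sf(abs(t_))
        for t_, d_ in zip(tstat, df)
    ])
    tcrit = np.array([
        stats.t.ppf(0.975, d_) if np.isfinite(d_) else stats.norm.ppf(0.975)
        for d_ in df
    ])
    return pd.DataFrame({
        "name": names, "coef": qbar, "se": se,
        "OR": np.exp(qbar),
        "ci_low": np.exp(qbar - tcrit * se),
        "ci_high": np.exp(qbar + tcrit * se),
        "p": p, "gamma": gamma, "relative_efficiency": re,
    })


def impute_and_pool(
    df: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    m: int = 15,
    burn: int = 10,
    seed: int = 0,
) -> PooledFit:
    """Chained-equation imputation (predictive mean matching), m multinomial
    fits, Rubin pooling.

    With no missing data the result reduces to the complete-data fit with
    relative efficiency 1 for every predictor.
    """
    cols = config.columns(df)
    for c in cols:
        frac = df[c].isna().mean()
        if frac >= 0.5:
            raise ValueError(f"column {c!r} is {frac:.0%} missing; refuse to impute")
    work = df[[config.outcome, *cols]].copy()
    has_missing = work[cols].isna().any().any()
    if not has_missing:
        fit = fit_multinomial(df, config)
        results = fit.results.copy()
        results["gamma"] = 0.0
        results["relative_efficiency"] = 1.0
        re = {p: 1.0 for p in cols}
        return PooledFit(m=1, results=results, relative_efficiency=re,
                         nagelkerke_r2=fit.nagelkerke_r2)

    from statsmodels.imputation.mice import MICEData

    levels = [config.reference] + [g for g in GROUP_ORDER
                                   if g != config.reference]
    work["_outcome_code"] = pd.Categorical(
        work[config.outcome], categories=levels).codes.astype(float)
    imp_df = work[["_outcome_code", *cols]].astype(float)
    np.random.seed(seed % (2 ** 31))  # MICEData draws from the global RNG
    imp = MICEData(imp_df, perturbation_method="gaussian")
    for c in cols:
        imp.set_imputer(c)  # default: OLS + predictive mean matching
    fits, params, covs, names = [], [], [], None
    for i in range(m):
        imp.update_all(burn if i == 0 else 2)
        completed = imp.data.copy()
        completed[config.outcome] = work[config.outcome].to_numpy()
        fit = fit_multinomial(completed, config)
        fits.append(fit)
        params.append(fit.params)
        covs.append(fit.cov)
        names = fit.param_names
    pooled = rubin_pool(np.asarray(params), np.asarray(covs), names, m)
    pooled[["contrast", "predictor"]] = pooled["name"].str.split(
        ":", n=1, expand=True)
    re: Dict[str, float] = {}
    for pred in cols:
        rows = pooled[pooled["predictor"] == pred]
        re[pred] = float(rows["relative_efficiency"].min())
    return PooledFit(
        m=m, results=pooled.drop(columns=["name"]),
        relative_efficiency=re,
        nagelkerke_r2=float(np.mean([f.nagelkerke_r2 for f in fits])),
    )


def sensitivity_suite(
    df: pd.DataFrame,
    mode: str,
    config: ModelConfig = ModelConfig(),
    z_column: str = "z",
    residual_column: str = "residual",
    focal: str = "carrier",
    seed: int = 0,
):
    """Re-run the focal model under one of the pre-registered variations.

    mode="reclassify":            contiguous banding (the 0.5-1 SD shell
                                  joins EAC) before the multinomial refit.
    mode="linear":                OLS of the raw comprehension residual on
                                  the same predictors.
    mode="exclude_bilingual" /
    mode="exclude_spanish_home":  drop the subgroup, refit the multinomial.

    Returns a dict with the focal estimate and p-value plus the fit object.
    """
    df = df.copy()
    if mode == "reclassify":
        df[config.outcome] = classify_groups(df[z_column].to_numpy(),
                                             mode="contiguous")
        fit = impute_and_pool(df, config, seed=seed)
        rows = fit.results[fit.results["predictor"] == focal]
        return {"mode": mode, "fit": fit,
                "focal_estimates": dict(zip(rows["contrast"], rows["coef"])),
                "focal_p": float(rows["p"].min())}
    if mode == "linear":
        cols = config.columns(df)
        data = df[[residual_column, *cols]].dropna()
        X = sm.add_constant(data[cols].astype(float))
        res = sm.OLS(data[residual_column].astype(float), X).fit()
        return {"mode": mode, "fit": res,
                "focal_estimates": {"slope": float(res.params[focal])},
                "focal_p": float(res.pvalues[focal])}
    if mode in ("exclude_bilingual", "exclude_spanish_home"):
        col = "bilingual" if mode == "exclude_bilingual" else "spanish_home"
        sub = df[(df[col].fillna(0) == 0)
                 & df[config.outcome].isin(GROUP_ORDER)]
        if len(sub) == 0:
            raise ValueError(f"no subjects remain after excluding on {col!r}")
        cfg = ModelConfig(
            outcome=config.outcome, reference=config.reference,
            predictors=tuple(p for p in config.predictors if p != col),
            n_pcs=config.n_pcs, pc_prefix=config.pc_prefix,
            standardize=config.standardize)
        fit = impute_and_pool(sub, cfg, seed=seed)
        rows = fit.results[fit.results["predictor"] == focal]
        return {"mode": mode, "fit": fit,
                "focal_estimates": dict(zip(rows["contrast"], rows["coef"])),
                "focal_p": float(rows["p"].min())}
    raise ValueError(f"unknown sensitivity mode {mode!r}")
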