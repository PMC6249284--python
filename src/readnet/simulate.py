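"""Synthetic cohorts, genotype matrices, and resting-state BOLD runs.

Every downstream stage of the pipeline is exercised on data from this
module, which plants the statistical structure the analysis assumes:

* a ~1,000-subject cohort in which comprehension-residual group labels are
  drawn first and RU2Short carrier status is then drawn per group at the
  configured frequencies (UPC 0.47, EAC 0.37, UGC 0.32 by default), with
  group-dependent covariates and MCAR missingness;
* a two-population Balding-Nichols SNP matrix for stratification PCA;
* small-grid 4D BOLD runs containing a planted bilateral frontal-parietal
  network of spherical nodes whose latent time courses realize a target
  correlation matrix, with one designated node pair strengthened for
  RU2Short carriers, plus slow nuisance drifts in tissue masks and motion
  traces with super-threshold spikes.

All generators are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .popstruct import GenotypeMatrix
from .read1 import DELETION

GROUPS = ("UPC", "EAC", "UGC", "UNCLASSIFIED")

# Classified-group sizes 216 / 530 / 223 out of 1432; the remainder sits in
# the 0.5-1 SD shell and is unclassified under the standard banding.
_GROUP_PROBS = {
    "UPC": 216 / 1432,
    "EAC": 530 / 1432,
    "UGC": 223 / 1432,
    "UNCLASSIFIED": 1 - (216 + 530 + 223) / 1432,
}

# Per-group covariate summaries (mean, sd) or proportions used as generator
# defaults; UNCLASSIFIED uses values intermediate between EAC and the tails.
_AGE = {"UPC": (143.75, 25.12), "EAC": (131.19, 24.30), "UGC": (148.17, 23.59),
        "UNCLASSIFIED": (138.0, 25.0)}
_MALE = {"UPC": 0.516, "EAC": 0.55, "UGC": 0.551, "UNCLASSIFIED": 0.54}
_MAT_EDU = {"UPC": (13.30, 2.51), "EAC": (13.24, 2.94), "UGC": (14.44, 3.02),
            "UNCLASSIFIED": (13.5, 2.9)}
_SES_LOW = {"UPC": 0.599, "EAC": 0.535, "UGC": 0.338, "UNCLASSIFIED": 0.50}
_VOCAB = {"UPC": (87.2, 12.7), "EAC": (93.0, 13.9), "UGC": (105.0, 16.2),
          "UNCLASSIFIED": (96.0, 14.0)}
_WJ = {"UPC": 96.6, "EAC": 92.1, "UGC": 98.7, "UNCLASSIFIED": 95.0}
_TOWRE = {"UPC": 94.8, "EAC": 90.1, "UGC": 96.8, "UNCLASSIFIED": 93.5}

_DEFAULT_CARRIER_FREQ = {"UPC": 0.47, "EAC": 0.37, "UGC": 0.32,
                         "UNCLASSIFIED": 0.37}

# True comprehension model: sri_comprehension = b0 + X b + z * residual_sd.
_DEFAULT_COMP_COEFS = {
    "age_months": 0.01,
    "piq": 0.15,
    "wj_word_attack": 0.04,
    "towre_pde": 0.04,
    "wj_lwid": 0.04,
    "towre_swe": 0.04,
    "sri_word_recognition": 0.30,
}

#: Covariate columns subject to MCAR missingness (the Table-4 predictor set
#: minus age/sex, which are assumed complete in intake data).
MISSINGNESS_COLUMNS = (
    "ppvt_vocab", "maternal_edu_years", "ses_low", "spanish_home", "bilingual",
)


@dataclass
class CohortSpec:
    n_subjects: int = 1000
    carrier_freq_by_group: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CARRIER_FREQ))
    effect_sizes: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMP_COEFS))
    missing_rate: float = 0.015
    residual_sd: float = 2.9
    spanish_home_rate: float = 0.30
    bilingual_rate: float = 0.35
    deletion_freq: float = 0.03
    dual_deletion_rate: float = 0.002
    genotype_missing_rate: float = 0.013
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for g, p in self.carrier_freq_by_group.items():
            if not 0 <= p <= 1:
                raise ValueError(f"carrier frequency for {g} outside [0,1]: {p}")


def _truncnorm(rng, lo, hi, size):
    return stats.truncnorm.rvs(lo, hi, size=size, random_state=rng)


def _draw_z(rng: np.random.Generator, groups: np.ndarray) -> np.ndarray:
    """Standardized residuals drawn from a unit normal truncated to each
    group's band (tails for UPC/UGC, |z|<=0.5 for EAC, the 0.5-1 shell for
    unclassified with side chosen by relative band mass)."""
    z = np.empty(len(groups))
    for g, lo, hi in [("UPC", -np.inf, -1.0), ("EAC", -0.5, 0.5),
                      ("UGC", 1.0, np.inf)]:
        idx = groups == g
        z[idx] = _truncnorm(rng, lo, hi, int(idx.sum()))
    idx = groups == "UNCLASSIFIED"
    n_u = int(idx.sum())
    side = rng.random(n_u) < 0.5
    shell = _truncnorm(rng, 0.5, 1.0, n_u)
    z[idx] = np.where(side, shell, -shell)
    return z


_RU2SHORT_POOL = {4: 0.55, 10: 0.25, 15: 0.05, 16: 0.05, 17: 0.04, 21: 0.03,
                  24: 0.03}
_OTHER_POOL = {2: 0.20, 3: 0.15, 8: 0.05, 12: 0.05,       # RU1-1
               5: 0.30, 6: 0.15, 13: 0.05, 14: 0.05}       # RU2Long


def _sample_pool(rng, pool: dict, size: int) -> np.ndarray:
    ids = np.array(list(pool))
    p = np.array(list(pool.values()), float)
    return rng.choice(ids, size=size, p=p / p.sum())


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Column semantics follow the intake format the pipeline consumes: reading
    measures are age-normed standard scores, SES/bilingual/Spanish-home are
    0/1 indicators, and READ1 alleles are integer IDs with "DEL" for the
    microdeletion.  ``group_true`` / ``z_true`` record the planted labels so
    that recovery can be tested; the analysis never reads them.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    probs = np.array([_GROUP_PROBS[g] for g in GROUPS])
    groups = rng.choice(np.array(GROUPS, object), size=n, p=probs / probs.sum())
    z = _draw_z(rng, groups)

    def per_group(table, draw):
        out = np.empty(n)
        for g in GROUPS:
            idx = groups == g
            out[idx] = draw(table[g], int(idx.sum()))
        return out

    age = per_group(_AGE, lambda ms, k: rng.normal(ms[0], ms[1], k))
    sex_female = per_group(_MALE, lambda p, k: rng.random(k) >= p).astype(int)
    mat_edu = per_group(_MAT_EDU, lambda ms, k: rng.normal(ms[0], ms[1], k))
    ses_low = per_group(_SES_LOW, lambda p, k: rng.random(k) < p).astype(int)
    vocab = per_group(_VOCAB, lambda ms, k: rng.normal(ms[0], ms[1], k))

    # Reading measures share a latent decoding ability within subject so the
    # residualization design has realistic collinearity.
    ability = rng.normal(0, 1, n)
    def measure(center, sd, load=0.7):
        return center + sd * (load * ability + np.sqrt(1 - load ** 2)
                              * rng.normal(0, 1, n))
    wj_center = per_group(_WJ, lambda m_, k: np.full(k, m_))
    towre_center = per_group(_TOWRE, lambda m_, k: np.full(k, m_))
    piq = rng.normal(9.3, 2.8, n)
    wj_wa = measure(wj_center, 11.0)
    wj_lwid = measure(wj_center, 12.0)
    towre_pde = measure(towre_center, 15.0)
    towre_swe = measure(towre_center, 16.0)
    sri_wr = measure(10.0, 3.0)

    coefs = dict(_DEFAULT_COMP_COEFS)
    coefs.update(spec.effect_sizes or {})
    X = {
        "age_months": age, "piq": piq, "wj_word_attack": wj_wa,
        "towre_pde": towre_pde, "wj_lwid": wj_lwid, "towre_swe": towre_swe,
        "sri_word_recognition": sri_wr,
    }
    lin = sum(coefs.get(k, 0.0) * v for k, v in X.items())
    comprehension = lin - float(np.mean(lin)) + 7.0 + z * spec.residual_sd

    spanish = (rng.random(n) < spec.spanish_home_rate).astype(int)
    bilingual = (rng.random(n) < spec.bilingual_rate).astype(int)

    carrier_p = np.array([spec.carrier_freq_by_group.get(g, 0.37)
                          for g in groups])
    carrier = rng.random(n) < carrier_p

    allele_a = np.empty(n, dtype=object)
    allele_b = np.empty(n, dtype=object)
    n_car = int(carrier.sum())
    allele_a[carrier] = _sample_pool(rng, _RU2SHORT_POOL, n_car)
    # second allele of a carrier may come from any pool
    full_pool = {**_RU2SHORT_POOL, **_OTHER_POOL}
    allele_b[carrier] = _sample_pool(rng, full_pool, n_car)
    n_non = n - n_car
    allele_a[~carrier] = _sample_pool(rng, _OTHER_POOL, n_non)
    allele_b[~carrier] = _sample_pool(rng, _OTHER_POOL, n_non)
    # hemizygous deletion replaces allele_b (never the carrier-defining
    # allele, so planted carrier frequencies are preserved under the
    # homozygous-substitution coding rule)
    del_mask = rng.random(n) < spec.deletion_freq
    allele_b[del_mask] = DELETION
    dual = rng.random(n) < spec.dual_deletion_rate
    allele_a[dual] = DELETION
    allele_b[dual] = DELETION
    missing_call = rng.random(n) < spec.genotype_missing_rate
    allele_a[missing_call] = None
    allele_b[missing_call] = None

    df = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "group_true": groups,
        "z_true": z,
        "carrier_true": carrier,
        "age_months": age,
        "sex_female": sex_female,
        "piq": piq,
        "wj_word_attack": wj_wa,
        "towre_pde": towre_pde,
        "wj_lwid": wj_lwid,
        "towre_swe": towre_swe,
        "sri_word_recognition": sri_wr,
        "sri_comprehension": comprehension,
        "ppvt_vocab": vocab,
        "maternal_edu_years": mat_edu,
        "ses_low": ses_low,
        "spanish_home": spanish,
        "bilingual": bilingual,
        "allele_a": allele_a,
        "allele_b": allele_b,
    })

    if spec.missing_rate > 0:
        for col in MISSINGNESS_COLUMNS:
            mask = rng.random(n) < spec.missing_rate
            df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------

@dataclass
class SnpSpec:
    n_snps: int = 5000
    n_per_population: Tuple[int, int] = (100, 100)
    fst: float = 0.1
    ancestral_freq_range: Tuple[float, float] = (0.1, 0.9)
    n_x_snps: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral frequencies must lie in (0, 1)")


def generate_snp_matrix(spec: SnpSpec) -> GenotypeMatrix:
    """Two-population Balding-Nichols genotype matrix.

    Each SNP has an ancestral frequency p drawn uniformly from the
    configured range; population-specific frequencies are Beta distributed
    with mean p and variance fst * p(1-p); genotypes are Binomial(2, p_pop).
    Optional X SNPs model male hemizygosity (coded 0/2) for sex-check QC.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, spec.n_snps)
    a = p_anc * (1 - spec.fst) / spec.fst
    b = (1 - p_anc) * (1 - spec.fst) / spec.fst
    n1, n2 = spec.n_per_population
    n = n1 + n2
    dosage = np.empty((n, spec.n_snps + spec.n_x_snps))
    for rows, shape in [(slice(0, n1), (a, b)), (slice(n1, n), (a, b))]:
        p_pop = rng.beta(*shape)
        dosage[rows, : spec.n_snps] = rng.binomial(
            2, p_pop[None, :], size=(rows.stop - rows.start, spec.n_snps))
    chroms = [str(1 + (j % 22)) for j in range(spec.n_snps)]
    sex = np.array(["M" if i % 2 == 0 else "F" for i in range(n)], object)
    if spec.n_x_snps:
        p_x = rng.uniform(lo, hi, spec.n_x_snps)
        female = sex == "F"
        x_dos = np.empty((n, spec.n_x_snps))
        x_dos[female] = rng.binomial(2, p_x[None, :], size=(int(female.sum()),
                                                           spec.n_x_snps))
        x_dos[~female] = 2 * rng.binomial(1, p_x[None, :],
                                          size=(int((~female).sum()),
                                                spec.n_x_snps))
        dosage[:, spec.n_snps:] = x_dos
        chroms += ["X"] * spec.n_x_snps
    if spec.missing_rate > 0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = np.nan
    subjects = [f"P1_{i}" for i in range(n1)] + [f"P2_{i}" for i in range(n2)]
    snps = [f"rs{j}" for j in range(dosage.shape[1])]
    return GenotypeMatrix(dosage, subjects, snps, chroms, reported_sex=sex)


# ---------------------------------------------------------------------------
# BOLD runs
# ---------------------------------------------------------------------------

#: Planted network node centers (mm, RAS), loosely mirroring the bilateral
#: insula/IFG - supramarginal - anterior cingulate layout: index 0 is the
#: right insula/IFG seed, index 2 the right SMG.
DEFAULT_NODE_CENTERS = (
    (18.0, 6.0, 0.0),     # right insula/IFG (seed)
    (-18.0, 6.0, 0.0),    # left insula/IFG
    (21.0, -18.0, 9.0),   # right SMG
    (-21.0, -18.0, 9.0),  # left SMG
    (0.0, 12.0, 15.0),    # ACC
)

DEFAULT_NODE_LABELS = ("R_insula_IFG", "L_insula_IFG", "R_SMG", "L_SMG", "ACC")


def _default_base_corr(k: int = 5) -> np.ndarray:
    C = np.full((k, k), 0.3)
    C[0, :] = C[:, 0] = 0.5
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class BoldSpec:
    grid_shape: Tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 3.0
    tr_s: float = 1.55
    n_volumes_per_run: int = 240
    n_runs: int = 2
    node_centers_mm: Tuple = DEFAULT_NODE_CENTERS
    node_radius_mm: float = 6.0
    base_corr: Optional[np.ndarray] = None
    carrier_corr_increment: float = 0.2
    carrier_edge: Tuple[int, int] = (0, 2)
    noise_sd: float = 1.0
    motion_spike_rate: float = 0.02
    drift_amplitude: float = 0.5
    lowpass_hz: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        k = len(self.node_centers_mm)
        C = _default_base_corr(k) if self.base_corr is None else np.asarray(
            self.base_corr, float)
        if C.shape != (k, k) or not np.allclose(C, C.T):
            raise ValueError("base_corr must be a symmetric k x k matrix")
        if not np.allclose(np.diag(C), 1.0) or np.abs(C).max() > 1 + 1e-12:
            raise ValueError("base_corr must have unit diagonal, |entries|<=1")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("base_corr must be positive semidefinite")
        i, j = self.carrier_edge
        if (i != j or self.carrier_corr_increment != 0) and not (
                -1 < C[i, j] + self.carrier_corr_increment < 1):
            raise ValueError("carrier increment pushes correlation out of (-1,1)")
        self.base_corr = C
        # node spheres must sit fully inside the grid
        half = np.array(self.grid_shape) * self.voxel_size_mm / 2.0
        for c in self.node_centers_mm:
            if np.any(np.abs(np.asarray(c)) + self.node_radius_mm > half):
                raise ValueError(f"node at {c} overlaps the grid boundary")

    @property
    def affine(self) -> np.ndarray:
        A = np.diag([self.voxel_size_mm] * 3 + [1.0])
        A[:3, 3] = -(np.array(self.grid_shape) - 1) * self.voxel_size_mm / 2.0
        return A


@dataclass
class BoldRun:
    data: np.ndarray  # (X, Y, Z, T)
    affine: np.ndarray
    tr_s: float
    label: str


@dataclass
class SubjectBold:
    subject_id: str
    carrier: bool
    runs: List[BoldRun]
    motion: List[np.ndarray]  # (T, 6) per run
    masks: Dict[str, np.ndarray]


def voxel_coords_mm(spec: BoldSpec) -> np.ndarray:
    """(X, Y, Z, 3) array of voxel-center world coordinates."""
    idx = np.indices(spec.grid_shape).astype(float)
    A = spec.affine
    return np.stack([A[d, d] * idx[d] + A[d, 3] for d in range(3)], axis=-1)


def make_masks(spec: BoldSpec) -> Dict[str, np.ndarray]:
    """Brain ellipsoid split into gray matter, a deep white-matter ball and
    a small central ventricle; planted node spheres are carved into gray
    matter so the analysis mask always contains the full network."""
    coords = voxel_coords_mm(spec)
    half = np.array(spec.grid_shape) * spec.voxel_size_mm / 2.0
    r = np.sqrt(((coords / (0.95 * half)) ** 2).sum(-1))
    brain = r <= 1.0
    d_center = np.sqrt((coords ** 2).sum(-1))
    vent_r = 0.15 * half.min()
    wm_r = 0.35 * half.min()
    vent = d_center <= vent_r
    wm = (d_center <= wm_r) & ~vent
    nodes = np.zeros(spec.grid_shape, bool)
    for m in node_masks(spec):
        nodes |= m
    gm = (brain & ~wm & ~vent) | nodes
    return {"gm": gm, "wm": wm & brain & ~nodes, "vent": vent & ~nodes}


def node_masks(spec: BoldSpec) -> List[np.ndarray]:
    coords = voxel_coords_mm(spec)
    out = []
    for c in spec.node_centers_mm:
        d = np.sqrt(((coords - np.asarray(c)) ** 2).sum(-1))
        out.append(d <= spec.node_radius_mm)
    return out


def _lowpass(rng: np.random.Generator, T: int, k: int, tr: float,
             cutoff_hz: float) -> np.ndarray:
    """Band-limited unit-variance noise: white Gaussian low-pass filtered."""
    x = rng.standard_normal((T, k))
    nyq = 0.5 / tr
    b, a = sp_signal.butter(4, min(cutoff_hz / nyq, 0.99))
    y = sp_signal.filtfilt(b, a, x, axis=0)
    y -= y.mean(0)
    sd = y.std(0)
    return y / np.where(sd > 0, sd, 1.0)


def _corr_transform(latent: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Impose the target correlation exactly on orthonormalized columns."""
    # orthonormalize so empirical correlation equals the target Cholesky mix
    Q, _ = np.linalg.qr(latent - latent.mean(0))
    Q = Q * np.sqrt(latent.shape[0])
    w, V = np.linalg.eigh(target)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    return Q @ L.T


def _drift_bank(rng, T, tr, k=3):
    t = np.arange(T) * tr
    bank = np.column_stack(
        [np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
         for f in (0.003, 0.005, 0.008)[:k]])
    bank -= bank.mean(0)
    return bank / bank.std(0)


def simulate_motion(rng, T: int, spike_rate: float) -> np.ndarray:
    """Random-walk motion trace with isolated super-threshold spikes."""
    steps = rng.normal(0, 0.02, (T, 6))
    trace = np.cumsum(steps, axis=0)
    spikes = rng.random(T) < spike_rate
    spikes[0] = False
    for t in np.where(spikes)[0]:
        trace[t, rng.integers(0, 3)] += rng.uniform(0.35, 1.0)
    return trace


def simulate_subject_bold(spec: BoldSpec, carrier: bool,
                          rng: np.random.Generator,
                          subject_id: str = "sub") -> SubjectBold:
    masks = make_masks(spec)
    nodes = node_masks(spec)
    k = len(nodes)
    corr = spec.base_corr.copy()
    if carrier:
        i, j = spec.carrier_edge
        corr[i, j] = corr[j, i] = corr[i, j] + spec.carrier_corr_increment
    gm = masks["gm"]
    runs, motions = [], []
    for r in range(spec.n_runs):
        T = spec.n_volumes_per_run
        latent = _lowpass(rng, T, k, spec.tr_s, spec.lowpass_hz)
        node_sig = _corr_transform(latent, corr)
        drift = _drift_bank(rng, T, spec.tr_s)
        data = np.zeros(spec.grid_shape + (T,), np.float32)
        # gray matter background: independent band-limited noise
        n_gm = int(gm.sum())
        bg = _lowpass(rng, T, n_gm, spec.tr_s, spec.lowpass_hz)
        data[gm] = bg.T
        for sig, mask in zip(node_sig.T, nodes):
            data[mask] = sig[None, :]
        # white noise everywhere in brain + shared drift
        brain = masks["gm"] | masks["wm"] | masks["vent"]
        nb = int(brain.sum())
        data[brain] += (spec.noise_sd * rng.standard_normal((nb, T))
                        ).astype(np.float32)
        data[brain] += (spec.drift_amplitude * drift[:, 0])[None, :].astype(
            np.float32)
        wm, vent = masks["wm"], masks["vent"]
        data[wm] += (1.0 * drift[:, 1])[None, :].astype(np.float32)
        mix = rng.normal(0, 1, (int(vent.sum()), 3)).astype(np.float32)
        data[vent] += (mix @ drift.T.astype(np.float32))
        runs.append(BoldRun(data, spec.affine, spec.tr_s, f"run{r + 1}"))
        motions.append(simulate_motion(rng, T, spec.motion_spike_rate))
    return SubjectBold(subject_id, bool(carrier), runs, motions, masks)


def generate_bold(spec: BoldSpec, carriers: Sequence[bool]) -> List[SubjectBold]:
    """Generate one :class:`SubjectBold` per entry in *carriers*."""
    rng = np.random.default_rng(spec.seed)
    return [
        simulate_subject_bold(spec, c, rng, subject_id=f"S{i:04d}")
        for i, c in enumerate(carriers)
    ]
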