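"""Synthetic cohort generator.

Emulates the baseline population the risk model was designed for: a Chinese
urban adult cohort with per-sex covariate moments, correlated anthropometric
and blood-chemistry measurements, a latent three-cluster structure
(a reference metabolic group, an older group, and an elevated-risk group),
~6.2% prevalent diabetes, and a six-year incident-diabetes process with an
overall rate near 4.5 cases per 1000 person-years.

Covariates are drawn per sex from a truncated multivariate normal: rows with
any measurement below its physiologic floor are redrawn, and the latent
per-variable locations are moment-matched (one-dimensional truncated-normal
inversion) so that the post-truncation marginal means equal the specified
means.  Latent-cluster displacement vectors are mean-centred across the
cluster mixture, so they reshape the joint distribution without moving the
marginal means.

Prevalent diabetes is ``Bernoulli(sigmoid(b0 + b.z))`` on per-spec
standardized covariates, OR-ed with fasting glucose >= 7.0 mmol/L; the
intercept ``b0`` is recalibrated at generation time so the marginal
prevalence matches the spec.  The incident process is the same linear
predictor with its own intercept calibrated to the target cumulative
six-year risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .cohort import (
    COVARIATES,
    DIABETES_GLU_THRESHOLD,
    FLOORS,
    SEX_FEMALE,
    SEX_MALE,
)


class ConfigurationError(ValueError):
    """The cohort specification is internally inconsistent."""


# Per-sex covariate moments of the emulated baseline population (means, SDs).
# LDL is not reported for that population; values are typical of urban
# Chinese adults and LDL does not enter the nine-variable risk model.
# GLU uses the internally consistent per-sex values of the same survey's
# follow-up subcohort (the baseline GLU row's printed per-sex SDs exceed
# the total-column SD twofold and its per-sex means both exceed the total
# mean, which is arithmetically impossible for a two-group mixture).
DEFAULT_MEANS = {
    SEX_MALE: {
        "age": 46.52, "bmi": 24.19, "waist": 84.87, "sbp": 121.0, "dbp": 78.8,
        "glu": 4.74, "chol": 4.82, "tg": 1.61, "hdl": 1.26, "ldl": 2.90,
    },
    SEX_FEMALE: {
        "age": 47.47, "bmi": 23.31, "waist": 76.57, "sbp": 115.6, "dbp": 74.58,
        "glu": 4.76, "chol": 4.97, "tg": 1.39, "hdl": 1.47, "ldl": 3.00,
    },
}
DEFAULT_SDS = {
    SEX_MALE: {
        "age": 16.2, "bmi": 3.60, "waist": 9.50, "sbp": 16.0, "dbp": 10.20,
        "glu": 0.62, "chol": 0.95, "tg": 1.26, "hdl": 0.30, "ldl": 0.80,
    },
    SEX_FEMALE: {
        "age": 14.8, "bmi": 4.10, "waist": 9.80, "sbp": 18.0, "dbp": 10.30,
        "glu": 0.61, "chol": 1.10, "tg": 1.00, "hdl": 0.34, "ldl": 0.85,
    },
}

DEFAULT_PSH_PREVALENCE = {SEX_MALE: 0.1373, SEX_FEMALE: 0.178}

# 8624 men / 15237 subjects in the emulated baseline.
DEFAULT_SEX_FRACTION_MALE = 8624 / 15237

# 1009 prevalent diabetics of 16246 enrolled.
DEFAULT_PREVALENCE = 1009 / 16246

# 62 incident cases among 2288 six-year completers.
DEFAULT_FOLLOWUP_RISK = 62 / 2288
DEFAULT_FOLLOWUP_YEARS = 6.0

_CORR_PAIRS = {
    ("age", "bmi"): 0.10, ("age", "waist"): 0.20, ("age", "sbp"): 0.35,
    ("age", "dbp"): 0.20, ("age", "glu"): 0.25, ("age", "chol"): 0.20,
    ("age", "tg"): 0.10, ("age", "hdl"): -0.05, ("age", "ldl"): 0.20,
    ("bmi", "waist"): 0.80, ("bmi", "sbp"): 0.25, ("bmi", "dbp"): 0.25,
    ("bmi", "glu"): 0.30, ("bmi", "chol"): 0.25, ("bmi", "tg"): 0.40,
    ("bmi", "hdl"): -0.25, ("bmi", "ldl"): 0.15,
    ("waist", "sbp"): 0.25, ("waist", "dbp"): 0.25, ("waist", "glu"): 0.30,
    ("waist", "chol"): 0.25, ("waist", "tg"): 0.40, ("waist", "hdl"): -0.25,
    ("waist", "ldl"): 0.15,
    ("sbp", "dbp"): 0.70, ("sbp", "glu"): 0.20, ("sbp", "chol"): 0.10,
    ("sbp", "tg"): 0.10, ("sbp", "hdl"): -0.05, ("sbp", "ldl"): 0.10,
    ("dbp", "glu"): 0.15, ("dbp", "chol"): 0.10, ("dbp", "tg"): 0.10,
    ("dbp", "hdl"): -0.05, ("dbp", "ldl"): 0.10,
    ("glu", "chol"): 0.15, ("glu", "tg"): 0.35, ("glu", "hdl"): -0.15,
    ("glu", "ldl"): 0.10,
    ("chol", "tg"): 0.30, ("chol", "hdl"): 0.15, ("chol", "ldl"): 0.85,
    ("tg", "hdl"): -0.40, ("tg", "ldl"): 0.20,
    ("hdl", "ldl"): -0.05,
}


def default_correlation() -> np.ndarray:
    """Default covariate correlation matrix (order :data:`COVARIATES`).

    The population the generator emulates is described only by marginal
    moments, so the joint structure is an editable modelling assumption:
    strong BMI-waist and SBP-DBP coupling, the usual negative TG-HDL
    association, CHOL-LDL near-collinearity, and modest age/adiposity/
    glycemia links.
    """
    p = len(COVARIATES)
    r = np.eye(p)
    idx = {v: i for i, v in enumerate(COVARIATES)}
    for (a, b), v in _CORR_PAIRS.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


def default_cluster_displacements() -> np.ndarray:
    """Latent-cluster displacement vectors in standardized units.

    Cluster 0 is the reference metabolic group, cluster 1 an older group,
    cluster 2 a group with elevated risk-variable levels.  Vectors are
    mean-centred at generation time, so marginal means are unaffected.
    """
    d = np.zeros((3, len(COVARIATES)))
    idx = {v: i for i, v in enumerate(COVARIATES)}
    # older cluster
    d[1, idx["age"]] = 1.0
    d[1, idx["sbp"]] = 0.3
    d[1, idx["chol"]] = 0.2
    d[1, idx["glu"]] = 0.1
    # elevated-risk cluster
    for v, shift in [("bmi", 0.8), ("waist", 0.8), ("tg", 0.8), ("glu", 0.4),
                     ("sbp", 0.4), ("dbp", 0.4), ("chol", 0.4), ("hdl", -0.5),
                     ("age", 0.2)]:
        d[2, idx[v]] = shift
    return d


# True per-SD log-odds of the generating risk process (shared by the
# prevalence and incidence models; intercepts are calibrated separately).
DEFAULT_RISK_COEFFICIENTS = {
    "age": 0.9, "bmi": 0.25, "waist": 0.35, "sbp": 0.15, "dbp": 0.10,
    "glu": 1.10, "chol": 0.15, "tg": 0.30, "hdl": -0.30, "ldl": 0.0,
    "sex": 0.15, "psh": 0.70,
}


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic study population."""

    n_subjects: int = 5000
    sex_fraction_male: float = DEFAULT_SEX_FRACTION_MALE
    means: dict = field(default_factory=lambda: {s: dict(m) for s, m in DEFAULT_MEANS.items()})
    sds: dict = field(default_factory=lambda: {s: dict(m) for s, m in DEFAULT_SDS.items()})
    psh_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PSH_PREVALENCE))
    correlation: np.ndarray = field(default_factory=default_correlation)
    n_latent_clusters: int = 3
    cluster_weights: tuple = (0.55, 0.27, 0.18)
    cluster_displacements: np.ndarray = field(default_factory=default_cluster_displacements)
    baseline_prevalence: float = DEFAULT_PREVALENCE
    risk_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS))
    followup_risk: float = DEFAULT_FOLLOWUP_RISK
    followup_coefficients: dict | None = None  # None -> risk_coefficients
    followup_years: float = DEFAULT_FOLLOWUP_YEARS
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for prop in (self.sex_fraction_male, self.baseline_prevalence, self.followup_risk):
            if not 0.0 <= prop <= 1.0:
                raise ConfigurationError(f"proportion out of [0,1]: {prop}")
        for sex in (SEX_MALE, SEX_FEMALE):
            for v in COVARIATES:
                if self.sds[sex][v] <= 0:
                    raise ConfigurationError(f"SD must be > 0 for {v} (sex={sex})")
            if not 0.0 <= self.psh_prevalence[sex] <= 1.0:
                raise ConfigurationError("psh prevalence out of [0,1]")
        r = np.asarray(self.correlation, dtype=float)
        if r.shape != (len(COVARIATES),) * 2:
            raise ConfigurationError("correlation matrix has wrong shape")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ConfigurationError("correlation matrix not symmetric")
        if np.linalg.eigvalsh(r).min() <= 1e-10:
            raise ConfigurationError("correlation matrix not positive-definite")
        w = np.asarray(self.cluster_weights, dtype=float)
        d = np.asarray(self.cluster_displacements, dtype=float)
        if len(w) != self.n_latent_clusters or d.shape != (self.n_latent_clusters, len(COVARIATES)):
            raise ConfigurationError("cluster weights/displacements inconsistent with n_latent_clusters")
        if not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("cluster weights must sum to 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one documented generator; sub-streams by fixed offset
    return np.random.default_rng([int(seed) % (2**31), stream])


def _latent_location(target_mean: float, sd: float, floor: float) -> float:
    """Location ``m`` such that a N(m, sd) lower-truncated at ``floor`` has
    mean ``target_mean``.  Falls back to ``target_mean`` when truncation is
    negligible (> 6 SD below the mean)."""
    if floor < target_mean - 6 * sd:
        return target_mean

    def trunc_mean(m: float) -> float:
        a = (floor - m) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=m, scale=sd))

    lo = target_mean - 8 * sd
    hi = target_mean + sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-10))


_CALIBRATION_CACHE: dict = {}
_CALIBRATION_DRAWS = 100_000
_CALIBRATION_ROUNDS = 4


def _calibrated_locs(spec: CohortSpec, sex: int, chol_corr: np.ndarray,
                     disp: np.ndarray) -> np.ndarray:
    """Latent locations such that the post-truncation cluster mixture for
    one sex recovers the spec means.

    Row-wise redrawing below the floors conditions the joint distribution,
    which biases not only the truncated variable but everything correlated
    with it.  One-dimensional truncated-normal inversion seeds the search;
    a fixed-seed Monte-Carlo loop then removes the residual multivariate
    bias.  The result depends only on the spec's distributional structure,
    so it is cached and independent of ``spec.seed`` and ``n_subjects``.
    """
    weights = np.asarray(spec.cluster_weights, dtype=float)
    targets = np.array([spec.means[sex][v] for v in COVARIATES])
    sds = np.array([spec.sds[sex][v] for v in COVARIATES])
    key = (sex, targets.tobytes(), sds.tobytes(), weights.tobytes(),
           disp.tobytes(), chol_corr.tobytes())
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    floors = np.array([FLOORS[v] for v in COVARIATES])
    locs = np.array([
        _latent_location(spec.means[sex][v], spec.sds[sex][v], FLOORS[v])
        for v in COVARIATES
    ])
    rng = np.random.default_rng(20010301)  # internal calibration stream
    n_cal = _CALIBRATION_DRAWS
    labels = rng.choice(len(weights), size=n_cal, p=weights)
    for _ in range(_CALIBRATION_ROUNDS):
        x = np.empty((n_cal, len(COVARIATES)))
        for c in range(len(weights)):
            m = labels == c
            x[m] = _sample_truncated(rng, int(m.sum()), locs, sds, chol_corr,
                                     floors, disp[c])
        locs = locs - (x.mean(axis=0) - targets)
    _CALIBRATION_CACHE[key] = locs
    return locs


def _sample_truncated(rng, n, locs, sds, chol_corr, floors, displacement):
    """Draw ``n`` rows of correlated covariates, redrawing rows that violate
    any floor.  ``displacement`` is already in standardized units."""
    p = len(locs)
    out = np.empty((n, p))
    need = np.arange(n)
    for _ in range(1000):
        if len(need) == 0:
            break
        z = rng.standard_normal((len(need), p)) @ chol_corr.T + displacement
        x = locs + sds * z
        out[need] = x
        ok = (x >= floors).all(axis=1)
        need = need[~ok]
    if len(need):  # pathological spec; clamp the stragglers
        out[need] = np.maximum(out[need], floors)
    return out


def _linear_predictor(df: pd.DataFrame, spec: CohortSpec, coefficients: dict) -> np.ndarray:
    """Risk linear predictor (without intercept) on spec-standardized scales."""
    eta = np.zeros(len(df))
    sex = df["sex"].to_numpy()
    for v, beta in coefficients.items():
        if beta == 0.0:
            continue
        if v == "sex":
            eta += beta * sex
        elif v == "psh":
            eta += beta * df["psh"].to_numpy()
        else:
            z = np.where(
                sex == SEX_MALE,
                (df[v] - spec.means[SEX_MALE][v]) / spec.sds[SEX_MALE][v],
                (df[v] - spec.means[SEX_FEMALE][v]) / spec.sds[SEX_FEMALE][v],
            )
            eta += beta * z
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float, forced: np.ndarray | None = None) -> float:
    """Intercept b0 with mean(sigmoid(b0 + eta) or forced) == target."""
    forced_arr = np.zeros(len(eta), dtype=bool) if forced is None else forced

    def mean_prob(b0: float) -> float:
        p = expit(b0 + eta)
        return float(np.where(forced_arr, 1.0, p).mean())

    if mean_prob(-40.0) >= target:  # forced fraction alone exceeds the target
        return -40.0
    return float(optimize.brentq(lambda b: mean_prob(b) - target, -40.0, 40.0, xtol=1e-12))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a baseline cohort as a DataFrame with the canonical columns.

    Deterministic given ``spec.seed``; byte-identical output for identical
    specs.
    """
    spec.validate()
    n = spec.n_subjects
    cols = ["id", "age", "sex"] + [c for c in COVARIATES if c != "age"] + ["psh", "diabetes"]
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    rng_sex = _rng(spec.seed, 1)
    rng_cluster = _rng(spec.seed, 2)
    rng_cov = _rng(spec.seed, 3)
    rng_psh = _rng(spec.seed, 4)
    rng_label = _rng(spec.seed, 5)

    sex = (rng_sex.random(n) < spec.sex_fraction_male).astype(int)
    weights = np.asarray(spec.cluster_weights, dtype=float)
    disp = np.asarray(spec.cluster_displacements, dtype=float)
    disp = disp - weights @ disp  # centre across the mixture
    cluster = rng_cluster.choice(spec.n_latent_clusters, size=n, p=weights)

    chol_corr = np.linalg.cholesky(np.asarray(spec.correlation, dtype=float))
    floors = np.array([FLOORS[v] for v in COVARIATES])
    x = np.empty((n, len(COVARIATES)))
    for s in (SEX_MALE, SEX_FEMALE):
        sds = np.array([spec.sds[s][v] for v in COVARIATES])
        locs = _calibrated_locs(spec, s, chol_corr, disp)
        for c in range(spec.n_latent_clusters):
            mask = (sex == s) & (cluster == c)
            if mask.sum() == 0:
                continue
            x[mask] = _sample_truncated(
                rng_cov, int(mask.sum()), locs, sds, chol_corr, floors, disp[c]
            )

    psh_p = np.where(sex == SEX_MALE,
                     spec.psh_prevalence[SEX_MALE], spec.psh_prevalence[SEX_FEMALE])
    psh = (rng_psh.random(n) < psh_p).astype(int)

    df = pd.DataFrame(x, columns=COVARIATES)
    df.insert(0, "sex", sex)
    df.insert(0, "id", np.arange(n))
    df["psh"] = psh

    eta = _linear_predictor(df, spec, spec.risk_coefficients)
    high_glu = df["glu"].to_numpy() >= DIABETES_GLU_THRESHOLD
    b0 = _calibrate_intercept(eta, spec.baseline_prevalence, forced=high_glu)
    p_diab = expit(b0 + eta)
    drawn = rng_label.random(n) < p_diab
    df["diabetes"] = (drawn | high_glu).astype(int)
    df["latent_cluster"] = cluster  # ground truth, not part of the CSV schema
    return df[cols + ["latent_cluster"]]


def generate_followup(cohort: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Six-year follow-up outcomes for the baseline non-diabetics.

    One row per baseline non-diabetic; ``incident_diabetes`` is Bernoulli in
    the true logistic cumulative risk evaluated at baseline covariates.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    at_risk = cohort[cohort["diabetes"] == 0]
    if len(at_risk) == 0:
        return pd.DataFrame({
            "id": pd.Series(dtype=int),
            "incident_diabetes": pd.Series(dtype=int),
            "years_observed": pd.Series(dtype=float),
        })
    coeffs = spec.followup_coefficients
    if coeffs is None:
        coeffs = spec.risk_coefficients
    eta = _linear_predictor(at_risk, spec, coeffs)
    b0 = _calibrate_intercept(eta, spec.followup_risk)
    p = expit(b0 + eta)
    rng = _rng(spec.seed, 11)
    incident = (rng.random(len(at_risk)) < p).astype(int)
    return pd.DataFrame({
        "id": at_risk["id"].to_numpy(),
        "incident_diabetes": incident,
        "years_observed": np.full(len(at_risk), float(spec.followup_years)),
    })


def small_spec(n: int = 2000, seed: int = 0, **overrides) -> CohortSpec:
    """Convenience constructor for test-scale cohorts with default structure."""
    return replace(CohortSpec(n_subjects=n, seed=seed), **overrides)
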