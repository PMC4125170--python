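"""Cluster-conditional risk model: per-cluster logits, the age-sex reference
grid of average onset probabilities, and individual relative risk.

For every cluster a multivariate logistic model of diabetes on the nine
risk variables is fitted by maximum likelihood, its calibration summarized
by the Hosmer-Lemeshow decile-of-risk test.  The non-diabetic subjects of
each cluster are then split into 24 groups (twelve 5-year age bins from
[20,25) to [75,inf) crossed with sex), and the cluster's logit is evaluated
at each group's mean covariate vector to give the group's average onset
probability P_0.  A subject's relative risk is

    RR = P_k / P_0,

where P_k is the subject's own fitted probability under their cluster's
logit and P_0 is the average probability of their age-sex matching group in
that cluster.  RR is a within-cohort relative score, not an epidemiological
cohort relative risk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .cohort import SEX_FEMALE, SEX_MALE, nondiabetic_mask
from .selection import SeparationError, fit_multivariate_logit

logger = logging.getLogger(__name__)

#: Lower edges of the twelve 5-year age bins; the last bin is [75, inf).
AGE_BIN_EDGES = np.arange(20, 80, 5)
N_AGE_BINS = 12


def age_bin(age) -> np.ndarray:
    """Half-open 5-year bin index: [20,25) -> 0 ... [75,inf) -> 11.

    Ages below 20 are a domain error.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 20):
        raise ValueError("age below 20 is outside the model's domain")
    return np.minimum(((age - 20) // 5).astype(int), N_AGE_BINS - 1)


@dataclass
class ClusterLogit:
    """One cluster's fitted logistic model plus its calibration summary."""

    cluster: int
    variables: list[str]
    params: pd.Series          # 'const' + variables, logit scale
    bse: pd.Series
    hl_statistic: float | None = None
    hl_dof: int | None = None
    hl_pvalue: float | None = None

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.variables].to_numpy(dtype=float)
        beta = self.params[self.variables].to_numpy(dtype=float)
        return self.params["const"] + x @ beta

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(df))

    def to_dict(self) -> dict:
        return {
            "cluster": int(self.cluster),
            "variables": self.variables,
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "hosmer_lemeshow": {
                "statistic": self.hl_statistic,
                "dof": self.hl_dof,
                "pvalue": self.hl_pvalue,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterLogit":
        hl = d.get("hosmer_lemeshow", {})
        return cls(
            cluster=int(d["cluster"]), variables=list(d["variables"]),
            params=pd.Series(d["params"]), bse=pd.Series(d["bse"]),
            hl_statistic=hl.get("statistic"), hl_dof=hl.get("dof"),
            hl_pvalue=hl.get("pvalue"),
        )


def hosmer_lemeshow(probabilities, outcomes, groups: int = 10):
    """Decile-of-risk calibration test.

    Subjects are sorted by predicted probability and split into ``groups``
    near-equal groups; the statistic sums (O - E)^2 / (E (1 - E/n_g)) over
    groups and is referred to chi-square with ``groups - 2`` degrees of
    freedom.  Degenerate groups (expected count 0 or n_g) are merged into a
    neighbour and logged.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if groups < 3:
        raise ValueError("need at least 3 groups")
    order = np.argsort(p, kind="mergesort")
    chunks = np.array_split(order, groups)
    segments = [(float(p[c].sum()), int(y[c].sum()), len(c)) for c in chunks if len(c)]
    # merge degenerate groups into their left neighbour
    merged: list[list[float]] = []
    for e, o, n in segments:
        if merged and (e < 1e-9 or n - e < 1e-9):
            merged[-1][0] += e
            merged[-1][1] += o
            merged[-1][2] += n
            logger.info("merged a degenerate Hosmer-Lemeshow group")
        else:
            merged.append([e, o, n])
    if len(merged) < 3:
        raise ValueError("too few usable groups after merging")
    stat = 0.0
    for e, o, n in merged:
        stat += (o - e) ** 2 / (e * (1 - e / n))
    dof = len(merged) - 2
    return float(stat), int(dof), float(chi2.sf(stat, dof))


def fit_cluster_logits(cohort: pd.DataFrame, assignments: np.ndarray,
                       variables: list[str], *, outcome: str = "diabetes",
                       hl_groups: int = 10) -> dict[int, ClusterLogit]:
    """One maximum-likelihood logistic fit per cluster, HL test attached.

    Raises if any cluster has a single outcome class or is separable.
    """
    assignments = np.asarray(assignments)
    logits: dict[int, ClusterLogit] = {}
    for c in sorted(np.unique(assignments)):
        sub = cohort[assignments == c]
        if sub[outcome].nunique() < 2:
            raise ValueError(
                f"cluster {c} has a single outcome class ({len(sub)} subjects); "
                "cannot fit a logistic model")
        # a cluster may be constant in a binary variable (k-means happily
        # splits on standardized 0/1 columns); such terms are unidentified
        # within the cluster and are dropped from its model
        vars_c = [v for v in variables if sub[v].nunique() > 1]
        dropped = sorted(set(variables) - set(vars_c))
        if dropped:
            logger.warning("cluster %d: dropped cluster-constant variables %s",
                           c, dropped)
        try:
            table = fit_multivariate_logit(sub, vars_c, outcome=outcome)
        except SeparationError as exc:
            raise SeparationError(f"cluster {c}: {exc}") from exc
        logit = ClusterLogit(
            cluster=int(c), variables=vars_c,
            params=table["beta"], bse=table["se"],
        )
        p = logit.predict_proba(sub)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        try:
            stat, dof, pval = hosmer_lemeshow(p, sub[outcome].to_numpy(), hl_groups)
            logit.hl_statistic, logit.hl_dof, logit.hl_pvalue = stat, dof, pval
        except ValueError:
            logger.warning("Hosmer-Lemeshow not computable for cluster %d", c)
        logits[int(c)] = logit
    return logits


class ReferenceGrid:
    """Average onset probability P_0 per (cluster, sex, age bin).

    Each cluster holds 24 cells (12 age bins x 2 sexes).  A cell stores the
    group's mean covariate vector and the cluster logit evaluated *at that
    mean vector* — deliberately not the mean of individual probabilities
    (the two differ by a Jensen gap for dispersed groups).
    Empty cells fall back at lookup time to the nearest populated age bin of
    the same cluster and sex (bin-index distance, ties toward younger).
    """

    def __init__(self, cells: dict[int, pd.DataFrame], variables: list[str]):
        self.cells = cells        # cluster -> DataFrame indexed (sex, bin)
        self.variables = variables

    @property
    def clusters(self) -> list[int]:
        return sorted(self.cells)

    def n_cells(self, cluster: int) -> int:
        return len(self.cells[cluster])

    def p0(self, cluster: int, sex: int, bin_idx: int) -> float:
        """P_0 of the matched cell, with nearest-bin fallback."""
        tab = self.cells[cluster]
        val = tab.loc[(sex, bin_idx), "p0"]
        if np.isfinite(val):
            return float(val)
        row = tab.loc[sex]
        populated = row.index[np.isfinite(row["p0"])]
        if len(populated) == 0:
            raise ValueError(
                f"no populated age bin for cluster {cluster}, sex {sex}")
        # nearest populated bin, ties toward younger
        b = min(populated, key=lambda j: (abs(j - bin_idx), j))
        logger.info("empty grid cell (cluster=%d, sex=%d, bin=%d): "
                    "fell back to bin %d", cluster, sex, bin_idx, b)
        return float(row.loc[b, "p0"])

    def p0_lookup(self, clusters, sexes, bins) -> np.ndarray:
        return np.array([
            self.p0(int(c), int(s), int(b))
            for c, s, b in zip(clusters, sexes, bins)
        ])

    def to_dict(self) -> dict:
        out = {"variables": self.variables, "clusters": {}}
        for c, tab in self.cells.items():
            out["clusters"][str(c)] = {
                f"{int(sex)}:{int(b)}": {
                    "n": int(row["n"]),
                    "p0": None if not np.isfinite(row["p0"]) else float(row["p0"]),
                    "means": [None if not np.isfinite(row[v]) else float(row[v])
                              for v in self.variables],
                }
                for (sex, b), row in tab.iterrows()
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceGrid":
        variables = list(d["variables"])
        cells = {}
        for c, entries in d["clusters"].items():
            idx = pd.MultiIndex.from_product(
                [[SEX_FEMALE, SEX_MALE], range(N_AGE_BINS)], names=["sex", "bin"])
            tab = pd.DataFrame(index=idx, columns=["n", "p0"] + variables, dtype=float)
            for key, cell in entries.items():
                sex, b = (int(t) for t in key.split(":"))
                tab.loc[(sex, b), "n"] = cell["n"]
                tab.loc[(sex, b), "p0"] = np.nan if cell["p0"] is None else cell["p0"]
                for v, m in zip(variables, cell["means"]):
                    tab.loc[(sex, b), v] = np.nan if m is None else m
            cells[int(c)] = tab
        return cls(cells, variables)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def build_reference_grid(cohort: pd.DataFrame, assignments: np.ndarray,
                         cluster_logits: dict[int, ClusterLogit],
                         *, restrict_nondiabetic: bool = True) -> ReferenceGrid:
    """Average-probability grid from the non-diabetic subjects.

    For every (cluster, sex, age-bin) cell the mean covariate vector of its
    members is fed through the cluster's logit to give P_0.  Cells with no
    members hold NaN and resolve through the fallback rule at lookup.
    """
    assignments = np.asarray(assignments)
    df = cohort
    if restrict_nondiabetic:
        keep = nondiabetic_mask(cohort).to_numpy()
        df = cohort[keep]
        assignments = assignments[keep]
    if len(df) == 0:
        raise ValueError("no non-diabetic subjects to build the grid from")
    variables = sorted(set().union(*[lg.variables for lg in cluster_logits.values()]))
    bins = age_bin(df["age"])
    cells: dict[int, pd.DataFrame] = {}
    for c, logit in cluster_logits.items():
        sub = df[assignments == c]
        sub_bins = bins[assignments == c]
        idx = pd.MultiIndex.from_product(
            [[SEX_FEMALE, SEX_MALE], range(N_AGE_BINS)], names=["sex", "bin"])
        tab = pd.DataFrame(index=idx, columns=["n", "p0"] + variables, dtype=float)
        tab["n"] = 0.0
        if len(sub):
            grouped = sub.assign(_bin=sub_bins).groupby(["sex", "_bin"])
            means = grouped[variables].mean()
            sizes = grouped.size()
            for key in means.index:
                mean_vec = means.loc[key]
                p0 = float(expit(
                    logit.params["const"]
                    + mean_vec[logit.variables].to_numpy(dtype=float)
                    @ logit.params[logit.variables].to_numpy(dtype=float)))
                tab.loc[key, "n"] = float(sizes.loc[key])
                tab.loc[key, "p0"] = p0
                tab.loc[key, variables] = mean_vec[variables].to_numpy(dtype=float)
        if not np.isfinite(tab["p0"]).any():
            raise ValueError(f"cluster {c}: every grid cell is empty")
        cells[int(c)] = tab
    return ReferenceGrid(cells, list(variables))


@dataclass
class RiskScore:
    subject_id: object
    cluster: int
    p_individual: float
    p_reference: float
    rr: float
    prevalent_diabetes: bool = False


def compute_rr_cohort(cohort: pd.DataFrame, cluster_model,
                      cluster_logits: dict[int, ClusterLogit],
                      grid: ReferenceGrid) -> pd.DataFrame:
    """Vectorized RR for every subject.

    Returns a DataFrame (id, cluster, p_individual, p_reference, rr,
    prevalent_diabetes) aligned with ``cohort``.  Prevalent diabetics are
    scored too, with their flag set.
    """
    clusters = cluster_model.assign(cohort)
    bins = age_bin(cohort["age"])
    p_k = np.empty(len(cohort))
    for c, logit in cluster_logits.items():
        mask = clusters == c
        if mask.any():
            p_k[mask] = logit.predict_proba(cohort[mask])
    p_0 = grid.p0_lookup(clusters, cohort["sex"].to_numpy(), bins)
    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "cluster": clusters,
        "p_individual": p_k,
        "p_reference": p_0,
        "rr": p_k / p_0,
        "prevalent_diabetes": ~nondiabetic_mask(cohort).to_numpy(),
    })


def compute_rr(subject: pd.Series, cluster_model,
               cluster_logits: dict[int, ClusterLogit],
               grid: ReferenceGrid) -> RiskScore:
    """RR for a single subject (see :func:`compute_rr_cohort`)."""
    row = compute_rr_cohort(subject.to_frame().T, cluster_model,
                            cluster_logits, grid).iloc[0]
    return RiskScore(
        subject_id=row["id"], cluster=int(row["cluster"]),
        p_individual=float(row["p_individual"]),
        p_reference=float(row["p_reference"]), rr=float(row["rr"]),
        prevalent_diabetes=bool(row["prevalent_diabetes"]),
    )
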