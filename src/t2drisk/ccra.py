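"""Comprehensive risk assessment (CCRA): the three-step decision cascade.

Every non-diabetic subject is assigned one of four categories:

1. absolute criterion — fasting glucose above the glycemia cut-point
   (default 5.85 mmol/L) means **high** risk outright;
2. relative criterion — otherwise, relative risk at or below the RR cutoff
   (default 2.2) means **non** risk;
3. cluster criteria — otherwise the subject's cluster-specific threshold
   rules are counted: satisfying all three (degree 3) means high, any two
   (degree 2) medium, any one (degree 1) low.  All comparators are strict
   (``>``).  Degree 0 with RR above the cutoff is assigned **low** (the RR
   alone already signals elevated risk); this choice is configurable.

Prevalent diabetics are flagged and excluded from category counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import nondiabetic_mask
from .roc import DEFAULT_RR_CUTOFF
from .trees import DEFAULT_GLU_CUTOFF

logger = logging.getLogger(__name__)

CATEGORIES = ["non", "low", "medium", "high"]


@dataclass(frozen=True)
class Criterion:
    """One threshold rule, e.g. ``bmi > 26.8`` (strict comparison)."""

    variable: str
    threshold: float
    comparator: str = ">"

    def satisfied(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.comparator == ">":
            return v > self.threshold
        if self.comparator == "<":
            return v < self.threshold
        raise ValueError(f"unsupported comparator {self.comparator!r}")


#: Published criteria of the reference cluster (cluster 1 of the original
#: model): BMI > 26.8 kg/m^2, CHOL > 5.18 mmol/L, TG > 1.7 mmol/L.
CLUSTER1_CRITERIA = (
    Criterion("bmi", 26.8),
    Criterion("chol", 5.18),
    Criterion("tg", 1.7),
)

DEGREE_CATEGORY = {3: "high", 2: "medium", 1: "low", 0: "low"}


@dataclass
class RuleSet:
    """Per-cluster criteria plus the two global cutoffs."""

    rules: dict[int, tuple[Criterion, ...]]
    glu_cutoff: float = DEFAULT_GLU_CUTOFF
    rr_cutoff: float = DEFAULT_RR_CUTOFF
    degree_category: dict[int, str] = field(
        default_factory=lambda: dict(DEGREE_CATEGORY))
    reconstructed: bool = False  # True when criteria were derived from data

    def criteria_for(self, cluster: int):
        if cluster in self.rules:
            return self.rules[cluster]
        if self.rules:
            # inherit the lowest-indexed cluster's rules
            return self.rules[min(self.rules)]
        raise ValueError("rule set is empty")

    def to_dict(self) -> dict:
        return {
            "glu_cutoff": float(self.glu_cutoff),
            "rr_cutoff": float(self.rr_cutoff),
            "degree_category": {int(k): v for k, v in self.degree_category.items()},
            "reconstructed": bool(self.reconstructed),
            "rules": {
                int(c): [
                    {"variable": r.variable, "comparator": r.comparator,
                     "threshold": float(r.threshold)}
                    for r in crits
                ]
                for c, crits in self.rules.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        return cls(
            rules={
                int(c): tuple(
                    Criterion(r["variable"], float(r["threshold"]),
                              r.get("comparator", ">"))
                    for r in crits
                )
                for c, crits in d["rules"].items()
            },
            glu_cutoff=float(d.get("glu_cutoff", DEFAULT_GLU_CUTOFF)),
            rr_cutoff=float(d.get("rr_cutoff", DEFAULT_RR_CUTOFF)),
            degree_category={int(k): v for k, v in d.get(
                "degree_category", DEGREE_CATEGORY).items()},
            reconstructed=bool(d.get("reconstructed", False)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RuleSet":
        return cls.from_dict(yaml.safe_load(text))


def derive_default_rules(cohort: pd.DataFrame, assignments,
                         *, variables=("bmi", "chol", "tg"),
                         quantile: float = 0.75,
                         glu_cutoff: float = DEFAULT_GLU_CUTOFF,
                         rr_cutoff: float = DEFAULT_RR_CUTOFF) -> RuleSet:
    """Reconstruct per-cluster criteria as upper-quartile thresholds.

    Only the reference cluster's criteria were ever published; the other
    clusters' rules are data-derived stand-ins (the cluster's 75th
    percentile of BMI, CHOL and TG on the training cohort), shipped in the
    model file, clearly flagged ``reconstructed`` and fully overridable.
    """
    assignments = np.asarray(assignments)
    rules: dict[int, tuple[Criterion, ...]] = {}
    for c in sorted(np.unique(assignments)):
        sub = cohort[assignments == c]
        rules[int(c)] = tuple(
            Criterion(v, float(sub[v].quantile(quantile))) for v in variables
        )
    logger.warning("cluster criteria reconstructed as %.0fth percentiles of %s "
                   "(only the reference cluster's rules are published)",
                   100 * quantile, list(variables))
    return RuleSet(rules=rules, glu_cutoff=glu_cutoff, rr_cutoff=rr_cutoff,
                   reconstructed=True)


def evaluate_degree(subject, criteria) -> int:
    """Number of satisfied criteria for one subject (a Series or mapping)."""
    degree = 0
    for crit in criteria:
        try:
            value = subject[crit.variable]
        except KeyError as exc:
            raise KeyError(f"subject is missing rule variable {crit.variable!r}") from exc
        degree += int(bool(crit.satisfied(value)))
    return degree


@dataclass
class RiskAssessment:
    subject_id: object
    glu_flag: bool
    rr: float
    degree: int
    category: str
    prevalent_diabetes: bool


def assess_cohort(cohort: pd.DataFrame, rr_table: pd.DataFrame,
                  ruleset: RuleSet) -> pd.DataFrame:
    """Vectorized CCRA over a cohort.

    ``rr_table`` is the output of
    :func:`t2drisk.riskmodel.compute_rr_cohort` aligned with ``cohort``.
    Returns a DataFrame (id, cluster, rr, glu_flag, degree, category,
    prevalent_diabetes).
    """
    n = len(cohort)
    if len(rr_table) != n:
        raise ValueError("rr_table must align with the cohort")
    clusters = rr_table["cluster"].to_numpy()
    rr = rr_table["rr"].to_numpy(dtype=float)
    glu_flag = cohort["glu"].to_numpy(dtype=float) > ruleset.glu_cutoff
    degree = np.zeros(n, dtype=int)
    for c in np.unique(clusters):
        mask = clusters == c
        crits = ruleset.criteria_for(int(c))
        for crit in crits:
            if crit.variable not in cohort.columns:
                raise KeyError(f"cohort is missing rule variable {crit.variable!r}")
            degree[mask] += crit.satisfied(cohort.loc[mask, crit.variable])
    category = np.where(
        glu_flag, "high",
        np.where(rr <= ruleset.rr_cutoff, "non",
                 pd.Series(degree).map(ruleset.degree_category).to_numpy()))
    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "cluster": clusters,
        "rr": rr,
        "glu_flag": glu_flag,
        "degree": degree,
        "category": category,
        "prevalent_diabetes": ~nondiabetic_mask(cohort).to_numpy(),
    })


def assess(subject: pd.Series, rr: float, ruleset: RuleSet,
           cluster: int, prevalent_diabetes: bool = False) -> RiskAssessment:
    """CCRA for one subject given their RR and resolved cluster."""
    glu_flag = float(subject["glu"]) > ruleset.glu_cutoff
    degree = evaluate_degree(subject, ruleset.criteria_for(cluster))
    if glu_flag:
        category = "high"
    elif rr <= ruleset.rr_cutoff:
        category = "non"
    else:
        category = ruleset.degree_category[degree]
    return RiskAssessment(
        subject_id=subject.get("id"), glu_flag=bool(glu_flag), rr=float(rr),
        degree=int(degree), category=category,
        prevalent_diabetes=bool(prevalent_diabetes),
    )


def stratify_cohort(cohort: pd.DataFrame, rr_table: pd.DataFrame,
                    ruleset: RuleSet,
                    summary_variables=("age", "bmi", "waist", "glu", "chol",
                                       "tg", "hdl", "sbp", "dbp")):
    """Category counts and per-category covariate summaries.

    Prevalent diabetics are excluded from the counts and summaries.
    Returns ``(counts, summary, assessments)`` where ``counts`` is a Series
    over the four categories (summing to the number of non-diabetics),
    ``summary`` a DataFrame of mean and SD per category.
    """
    assessments = assess_cohort(cohort, rr_table, ruleset)
    eligible = ~assessments["prevalent_diabetes"]
    sub = cohort[eligible.to_numpy()]
    cats = assessments.loc[eligible, "category"]
    counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)
    summary_variables = [v for v in summary_variables if v in cohort.columns]
    rows = {}
    for cat in CATEGORIES:
        grp = sub[(cats == cat).to_numpy()]
        row = {"n": len(grp)}
        for v in summary_variables:
            row[f"{v}_mean"] = grp[v].mean() if len(grp) else np.nan
            row[f"{v}_sd"] = grp[v].std(ddof=1) if len(grp) > 1 else np.nan
        if "psh" in sub.columns:
            row["psh_pct"] = 100 * grp["psh"].mean() if len(grp) else np.nan
        rows[cat] = row
    summary = pd.DataFrame(rows).T
    return counts, summary, assessments
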