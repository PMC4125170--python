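"""Model validation: leave-one-out accuracy and follow-up incidence rates.

Jackknife: every subject is classified by a model trained without them and
the resulting category is collapsed to a three-way label — non-risk,
different-risk (low/medium/high), or diabetes (prevalent) — and compared
with the subject's label under the full-data model.  The default mode
refits only the per-cluster logistic models and the reference grid per
fold (variable selection, clustering, rules and cutoffs frozen: these are
the cheap-to-freeze, slow-to-vary components); ``mode="full"`` retrains the
whole pipeline per fold and is practical for small cohorts.

Follow-up: incidence per 1000 person-years by baseline risk category, with
person-years taken as n_baseline x years (complete follow-up — the
convention the printed rates of the original study follow exactly) and
exact Poisson (Garwood) 95% confidence intervals on the case counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .ccra import CATEGORIES

logger = logging.getLogger(__name__)

THREE_WAY = ["non", "different", "diabetes"]


def collapse_category(category: str, prevalent: bool) -> str:
    """Four-tier category + prevalence flag -> the three-way validation label."""
    if prevalent:
        return "diabetes"
    return "non" if category == "non" else "different"


@dataclass
class JackknifeResult:
    n_evaluations: int
    n_correct: int
    accuracy: float
    confusion: pd.DataFrame  # rows: full-model label, cols: LOO label
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "n_evaluations": int(self.n_evaluations),
            "n_correct": int(self.n_correct),
            "accuracy": float(self.accuracy),
            "n_failures": int(self.n_failures),
            "confusion": {r: {c: int(self.confusion.loc[r, c])
                              for c in self.confusion.columns}
                          for r in self.confusion.index},
        }


def jackknife_accuracy(cohort: pd.DataFrame, settings=None, *,
                       mode: str = "logits") -> JackknifeResult:
    """Leave-one-out accuracy of the three-way categorization.

    ``settings`` is a :class:`t2drisk.pipeline.TrainSettings` (defaults
    used when ``None``).  A fold whose retraining fails is scored incorrect
    and logged; the run continues.
    """
    from .pipeline import TrainSettings, train_model

    if len(cohort) < 10:
        raise ValueError("jackknife needs at least 10 subjects")
    if mode not in ("logits", "full"):
        raise ValueError(f"unknown jackknife mode {mode!r}")
    settings = settings if settings is not None else TrainSettings()

    full_model = train_model(cohort, settings)
    full_out = full_model.assess(cohort)
    manual = [
        collapse_category(cat, prev)
        for cat, prev in zip(full_out["category"], full_out["prevalent_diabetes"])
    ]

    loo: list[str] = []
    n_failures = 0
    positions = np.arange(len(cohort))
    for i in positions:
        rest = cohort.iloc[np.delete(positions, i)]
        held = cohort.iloc[[i]]
        try:
            if mode == "full":
                model_i = train_model(rest, settings)
            else:
                model_i = full_model.refit_logits(rest)
            out = model_i.assess(held)
            loo.append(collapse_category(out["category"].iloc[0],
                                         out["prevalent_diabetes"].iloc[0]))
        except Exception as exc:  # noqa: BLE001 - fold failures are recorded
            logger.warning("jackknife fold %d failed: %s", i, exc)
            loo.append("__failed__")
            n_failures += 1

    confusion = pd.DataFrame(0, index=THREE_WAY, columns=THREE_WAY, dtype=int)
    n_correct = 0
    for m, l in zip(manual, loo):
        if l in THREE_WAY:
            confusion.loc[m, l] += 1
            n_correct += int(m == l)
    n_eval = len(cohort)
    return JackknifeResult(
        n_evaluations=n_eval, n_correct=n_correct,
        accuracy=n_correct / n_eval, confusion=confusion,
        n_failures=n_failures,
    )


@dataclass
class IncidenceEstimate:
    category: str
    n_baseline: int
    cases: int
    person_years: float
    rate: float       # cases per 1000 person-years
    ci_low: float
    ci_high: float


def _garwood_ci(cases: int, person_years: float, level: float = 0.95):
    """Exact Poisson CI on a rate per 1000 person-years."""
    alpha = 1.0 - level
    lo = 0.0 if cases == 0 else chi2.ppf(alpha / 2, 2 * cases) / 2
    hi = chi2.ppf(1 - alpha / 2, 2 * cases + 2) / 2
    return lo / person_years * 1000, hi / person_years * 1000


def incidence_from_counts(n_baseline: int, cases: int, years: float = 6.0,
                          category: str = "") -> IncidenceEstimate:
    """Incidence per 1000 person-years from a baseline count and case count.

    Person-years assume complete follow-up (n_baseline x years).
    """
    if years <= 0:
        raise ValueError("years must be > 0")
    if cases > n_baseline:
        raise ValueError("cases cannot exceed the baseline count")
    py = n_baseline * years
    if py == 0:  # empty category: no person-time observed
        return IncidenceEstimate(category=category, n_baseline=0, cases=0,
                                 person_years=0.0, rate=float("nan"),
                                 ci_low=float("nan"), ci_high=float("nan"))
    rate = cases / py * 1000
    lo, hi = _garwood_ci(cases, py)
    return IncidenceEstimate(category=category, n_baseline=int(n_baseline),
                             cases=int(cases), person_years=float(py),
                             rate=float(rate), ci_low=float(lo), ci_high=float(hi))


def incidence_table(baseline_categories: pd.Series, followup: pd.DataFrame,
                    years: float = 6.0) -> pd.DataFrame:
    """Per-category and total incidence from a follow-up table.

    ``baseline_categories`` maps subject id to one of the four risk
    categories; every follow-up id must be present in it.  Returns a
    DataFrame with one row per category plus ``total``, with columns
    n_baseline, cases, person_years, rate, ci_low, ci_high (rate per 1000
    person-years; display rounding is left to callers).
    """
    cats = baseline_categories
    missing = set(followup["id"]) - set(cats.index)
    if missing:
        raise ValueError(
            f"{len(missing)} follow-up ids lack a baseline category "
            f"(e.g. {sorted(missing)[:3]})")
    merged = followup.assign(category=cats.loc[followup["id"]].to_numpy())
    rows = []
    for cat in CATEGORIES:
        grp = merged[merged["category"] == cat]
        rows.append(incidence_from_counts(
            len(grp), int(grp["incident_diabetes"].sum()), years, category=cat))
    rows.append(incidence_from_counts(
        len(merged), int(merged["incident_diabetes"].sum()), years,
        category="total"))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("category")
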