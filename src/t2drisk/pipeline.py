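"""End-to-end orchestration: selection -> clustering -> per-cluster logits
-> reference grid -> RR cutoff -> rule derivation, and assessment runs on
a trained model bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ccra import RuleSet, derive_default_rules, stratify_cohort
from .clustering import DEFAULT_K, ClusterModel, fit_cluster_model
from .cohort import RISK_VARIABLES, validate_cohort
from .riskmodel import ClusterLogit, ReferenceGrid, build_reference_grid, compute_rr_cohort, fit_cluster_logits
from .roc import DEFAULT_RR_CUTOFF, RocResult, choose_rr_cutoff
from .selection import run_selection
from .trees import DEFAULT_GLU_CUTOFF

logger = logging.getLogger(__name__)


@dataclass
class TrainSettings:
    """Everything the training stage needs besides the cohort itself."""

    # variable selection
    run_variable_selection: bool = False   # False -> use `variables` as-is
    candidate_variables: list[str] | None = None
    variables: list[str] = field(default_factory=lambda: list(RISK_VARIABLES))
    frequency_threshold: int = 4
    p_threshold: float = 0.05
    tree_min_leaf: int = 25
    tree_max_depth: int = 12
    cv_folds: int = 10
    # clustering
    k_fixed: int | None = DEFAULT_K
    k_range: tuple[int, int] = (2, 7)
    cluster_all_subjects: bool = True      # include prevalent diabetics
    # cutoffs
    glu_cutoff: float = DEFAULT_GLU_CUTOFF
    rr_cutoff: float | None = None         # None -> train by ROC
    rule_quantile: float = 0.75
    hl_groups: int = 10
    seed: int = 0


@dataclass
class TrainedModel:
    """The full trained bundle; three JSON files plus the rule YAML define it."""

    cluster_model: ClusterModel
    logits: dict[int, ClusterLogit]
    grid: ReferenceGrid
    ruleset: RuleSet
    variables: list[str]
    roc: RocResult | None = None
    selection_report: object | None = None
    settings: TrainSettings | None = None

    def score(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """RR table (id, cluster, p_individual, p_reference, rr, flag)."""
        return compute_rr_cohort(cohort, self.cluster_model, self.logits, self.grid)

    def assess(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """CCRA categories for every subject of ``cohort``."""
        from .ccra import assess_cohort
        return assess_cohort(cohort, self.score(cohort), self.ruleset)

    def stratify(self, cohort: pd.DataFrame):
        return stratify_cohort(cohort, self.score(cohort), self.ruleset)

    def refit_logits(self, cohort: pd.DataFrame) -> "TrainedModel":
        """New bundle with per-cluster logits and the grid refitted on
        ``cohort``; clustering, rules and cutoffs are kept frozen."""
        assignments = self.cluster_model.assign(cohort)
        settings = self.settings or TrainSettings()
        logits = fit_cluster_logits(cohort, assignments, self.variables,
                                    hl_groups=settings.hl_groups)
        grid = build_reference_grid(cohort, assignments, logits)
        return TrainedModel(
            cluster_model=self.cluster_model, logits=logits, grid=grid,
            ruleset=self.ruleset, variables=self.variables,
            settings=self.settings,
        )

    # --- persistence -----------------------------------------------------
    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        (d / "clustermodel.json").write_text(self.cluster_model.to_json(indent=1))
        logits = {str(c): lg.to_dict() for c, lg in self.logits.items()}
        (d / "logits.json").write_text(json.dumps(
            {"variables": self.variables, "clusters": logits},
            sort_keys=True, indent=1))
        (d / "grid.json").write_text(self.grid.to_json(indent=1))
        (d / "ruleset.yaml").write_text(self.ruleset.to_yaml())
        manifest = {
            "package_version": __version__,
            "variables": self.variables,
            "k": int(self.cluster_model.k),
            "glu_cutoff": self.ruleset.glu_cutoff,
            "rr_cutoff": self.ruleset.rr_cutoff,
            "settings": asdict(self.settings) if self.settings else None,
            "roc": self.roc.to_dict() if self.roc else None,
        }
        if manifest["settings"]:
            payload = json.dumps(manifest["settings"], sort_keys=True, default=str)
            manifest["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()
        (d / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))

    @classmethod
    def load(cls, model_dir) -> "TrainedModel":
        d = Path(model_dir)
        cluster_model = ClusterModel.from_dict(
            json.loads((d / "clustermodel.json").read_text()))
        logit_doc = json.loads((d / "logits.json").read_text())
        logits = {int(c): ClusterLogit.from_dict(v)
                  for c, v in logit_doc["clusters"].items()}
        grid = ReferenceGrid.from_dict(json.loads((d / "grid.json").read_text()))
        ruleset = RuleSet.from_yaml((d / "ruleset.yaml").read_text())
        return cls(cluster_model=cluster_model, logits=logits, grid=grid,
                   ruleset=ruleset, variables=list(logit_doc["variables"]))


def train_model(cohort: pd.DataFrame, settings: TrainSettings | None = None) -> TrainedModel:
    """Run the full construction pipeline on one cohort.

    Stages: (optional) dual variable selection; standardization and k-means
    with CCC-guided (or fixed) k; per-cluster logistic fits with HL tests;
    the 24-cell reference grid from non-diabetics; RR scoring of the whole
    cohort and ROC-trained RR cutoff (unless fixed); upper-quartile rule
    reconstruction per cluster.
    """
    settings = settings or TrainSettings()
    validate_cohort(cohort)

    variables = list(settings.variables)
    selection_report = None
    glu_cutoff = settings.glu_cutoff
    if settings.run_variable_selection:
        candidates = settings.candidate_variables
        if candidates is None:
            from .cohort import COVARIATES
            candidates = [c for c in COVARIATES] + ["sex", "psh"]
        selection_report = run_selection(
            cohort, candidates, folds=settings.cv_folds, seed=settings.seed,
            min_leaf=settings.tree_min_leaf, max_depth=settings.tree_max_depth,
            frequency_threshold=settings.frequency_threshold,
            p_threshold=settings.p_threshold)
        variables = list(selection_report.final_variables)
        if selection_report.glycemia_cutoff is not None:
            glu_cutoff = selection_report.glycemia_cutoff
        logger.info("selected variables: %s (glycemia cutoff %.2f)",
                    variables, glu_cutoff)

    cluster_df = cohort if settings.cluster_all_subjects else cohort[cohort["diabetes"] == 0]
    cluster_model = fit_cluster_model(
        cluster_df, variables, seed=settings.seed,
        k_range=range(settings.k_range[0], settings.k_range[1] + 1),
        k_fixed=settings.k_fixed)
    assignments = cluster_model.assign(cohort)

    logits = fit_cluster_logits(cohort, assignments, variables,
                                hl_groups=settings.hl_groups)
    grid = build_reference_grid(cohort, assignments, logits)

    model = TrainedModel(
        cluster_model=cluster_model, logits=logits, grid=grid,
        ruleset=RuleSet(rules={}), variables=variables,
        selection_report=selection_report, settings=settings,
    )
    rr_table = model.score(cohort)

    roc = None
    if settings.rr_cutoff is None:
        roc = choose_rr_cutoff(rr_table["rr"], cohort["diabetes"].to_numpy())
        rr_cutoff = roc.cutoff if np.isfinite(roc.cutoff) else DEFAULT_RR_CUTOFF
        logger.info("trained RR cutoff %.3f (AUC %.3f, sens %.3f, spec %.3f)",
                    rr_cutoff, roc.auc, roc.sensitivity, roc.specificity)
    else:
        rr_cutoff = settings.rr_cutoff

    model.ruleset = derive_default_rules(
        cohort, assignments, quantile=settings.rule_quantile,
        glu_cutoff=glu_cutoff, rr_cutoff=rr_cutoff)
    model.roc = roc
    return model
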