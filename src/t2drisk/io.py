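"""Cohort readers/writers and run configuration.

Cohort tables travel as RFC-4180 CSV (UTF-8, ``.`` decimal separator) with
the documented header ``id, age, sex, bmi, waist, sbp, dbp, glu, chol, tg,
hdl, ldl, psh, diabetes``; ``sex`` is 1 = male / 0 = female, ``psh`` and
``diabetes`` are 0/1.  Readers validate rows against the subject-record
invariants and either fail loudly or (tolerant mode) drop offending rows
with row-numbered messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, FOLLOWUP_COLUMNS, SchemaError, row_violations, validate_cohort
from .pipeline import TrainSettings

logger = logging.getLogger(__name__)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in COHORT_COLUMNS if c in df.columns])


def write_followup(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=FOLLOWUP_COLUMNS)


def read_cohort(path, *, tolerant: bool = False) -> pd.DataFrame:
    """Load and validate a cohort CSV.

    Strict mode raises :class:`SchemaError` on any invalid row; tolerant
    mode drops invalid rows (reported with their 1-based data row numbers)
    and returns the remainder.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing columns: {missing}")
    numeric = [c for c in COHORT_COLUMNS if c != "id"]
    parsed = df.copy()
    for c in numeric:
        parsed[c] = pd.to_numeric(df[c], errors="coerce")
    # unparseable cells (raw value present, numeric coercion failed)
    bad_parse = (parsed[numeric].isna() & df[numeric].notna()).any(axis=1)
    # record invariants, checked on complete rows only (missingness is
    # allowed on covariates and handled downstream)
    complete = ~parsed[numeric].isna().any(axis=1)
    bad_invariant = pd.Series(False, index=parsed.index)
    if complete.any():
        bad_invariant.loc[complete] = row_violations(parsed[complete])
    bad_code = ~parsed["sex"].isin([0, 1]) | ~parsed["psh"].isin([0, 1]) \
        | ~parsed["diabetes"].isin([0, 1])
    bad = (bad_parse | bad_invariant | bad_code).to_numpy()
    if bad.any():
        rows = [int(i) + 1 for i in parsed.index[bad]]
        msg = f"{len(rows)} invalid rows (data rows {rows[:10]}{'...' if len(rows) > 10 else ''})"
        if not tolerant:
            raise SchemaError(msg)
        logger.warning("read_cohort: dropping %s", msg)
        parsed = parsed[~bad]
    parsed = parsed.astype({"sex": int, "psh": int, "diabetes": int})
    n_missing = int(parsed[numeric].isna().sum().sum())
    if n_missing:
        logger.info("read_cohort: %d missing values remain", n_missing)
    return parsed.reset_index(drop=True)


def read_followup(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FOLLOWUP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"follow-up file {path} missing columns: {missing}")
    if (df["years_observed"] <= 0).any():
        raise SchemaError("years_observed must be > 0")
    return df


@dataclass
class PipelineConfig:
    """One-file configuration for end-to-end runs (YAML on disk)."""

    cohort_path: str | None = None
    followup_path: str | None = None
    model_dir: str = "model"
    mode: str = "train"                       # train | assess | validate
    out_dir: str = "out"
    train: TrainSettings = field(default_factory=TrainSettings)
    run_jackknife: bool = False
    jackknife_mode: str = "logits"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        train_doc = doc.pop("train", {})
        cfg = cls(**{k: v for k, v in doc.items() if k in cls.__dataclass_fields__})
        settings = TrainSettings(**train_doc)
        settings.seed = cfg.seed
        cfg.train = settings
        return cfg

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def run_pipeline(config: PipelineConfig):
    """Execute the configured stages end to end.

    ``train`` mode trains on the cohort and persists the model bundle plus
    reports under ``out_dir``; ``assess`` mode loads a persisted bundle and
    only writes assessments (model files are never touched); ``validate``
    additionally runs the jackknife and, when a follow-up table is given,
    the incidence table.  Any stage failure is re-raised with the stage
    name.
    """
    from .pipeline import TrainedModel, train_model
    from .validation import incidence_table, jackknife_accuracy

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_cohort"
    try:
        cohort = read_cohort(config.cohort_path)
        if config.mode == "assess":
            stage = "load_model"
            model = TrainedModel.load(config.model_dir)
        else:
            stage = "train"
            config.train.seed = config.seed
            model = train_model(cohort, config.train)
            model.save(config.model_dir)
        stage = "stratify"
        counts, summary, assessments = model.stratify(cohort)
        assessments.to_csv(out / "assessments.csv", index=False)
        summary.to_csv(out / "category_summary.csv")
        results = {"counts": {k: int(v) for k, v in counts.items()}}
        if config.mode == "validate" or config.run_jackknife:
            stage = "jackknife"
            jk = jackknife_accuracy(cohort, config.train, mode=config.jackknife_mode)
            results["jackknife"] = jk.to_dict()
        if config.followup_path:
            stage = "incidence"
            followup = read_followup(config.followup_path)
            cats = assessments.set_index("id")["category"]
            table = incidence_table(cats, followup)
            table.to_csv(out / "incidence.csv")
            results["incidence"] = {
                str(k): float(v) for k, v in table["rate"].items()}
        import json as _json
        (out / "results.json").write_text(_json.dumps(results, sort_keys=True, indent=1))
        return model, results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
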