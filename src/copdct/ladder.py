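"""The eight-model diagnostic ladder with validation, cutoffs and NRI.

Runs the full comparison a reader expects from a diagnostic-model study:
a demographics-only baseline, each CT biomarker added alone, every pair,
and the full model — each internally validated by the optimism bootstrap,
classified at its own optimal-accuracy cutoff, and compared by NRI to the
baseline and (for models containing the expiratory air-trapping index) to
its inspiratory-only counterpart.  Optionally the discrimination analysis is
repeated inside the symptomatic and asymptomatic strata (per-stratum refits
with apparent C and DeLong CI; no per-stratum bootstrap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .models import (
    EXPIRATORY_COUNTERPART,
    MODEL_LADDER,
    ClassificationTable,
    FittedModel,
    ModelSpec,
    NRIResult,
    ValidationReport,
    bootstrap_validate,
    build_design_frame,
    c_statistic,
    c_statistic_ci,
    classify_at,
    compute_nri,
    fit_logistic,
    optimal_cutoff,
)

SCHEMA_VERSION = 1


@dataclass
class ModelReport:
    spec: ModelSpec
    shrunk_model: FittedModel
    validation: ValidationReport
    cutoff: float
    table: ClassificationTable
    nri_vs_baseline: NRIResult | None
    nri_vs_inspiratory: NRIResult | None

    def to_dict(self) -> dict:
        return {
            "id": self.spec.id,
            "name": self.spec.name,
            "covariates": list(self.spec.covariates),
            "intercept": self.shrunk_model.intercept,
            "coefficients": self.shrunk_model.coefficients,
            "shrinkage_factor": self.shrunk_model.shrinkage_factor,
            "validation": self.validation.to_dict(),
            "cutoff": self.cutoff,
            "classification": self.table.to_dict(),
            "nri_vs_baseline": self.nri_vs_baseline.to_dict() if self.nri_vs_baseline else None,
            "nri_vs_inspiratory": (
                self.nri_vs_inspiratory.to_dict() if self.nri_vs_inspiratory else None
            ),
        }


@dataclass
class StratumReport:
    """Per-stratum discrimination (Table-3 analog): apparent C with CI."""

    stratum: str
    n: int
    n_copd: int
    c_by_model: dict  # model id -> (c, ci_low, ci_high)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "n_copd": self.n_copd,
            "c_by_model": {
                str(k): {"c": v[0], "ci_95": [v[1], v[2]]}
                for k, v in self.c_by_model.items()
            },
        }


@dataclass
class LadderReport:
    models: list[ModelReport]
    strata: list[StratumReport] = field(default_factory=list)
    n_subjects: int = 0
    n_copd: int = 0
    seed: int | None = None
    n_bootstrap: int = 0

    def model(self, model_id: int) -> ModelReport:
        for m in self.models:
            if m.spec.id == model_id:
                return m
        raise KeyError(model_id)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "n_subjects": self.n_subjects,
            "n_copd": self.n_copd,
            "seed": self.seed,
            "n_bootstrap": self.n_bootstrap,
            "models": [m.to_dict() for m in self.models],
            "strata": [s.to_dict() for s in self.strata],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def table2_frame(self) -> pd.DataFrame:
        """Confusion-metric table across models (performance-table analog)."""
        rows = []
        for m in self.models:
            d = m.table.to_dict()
            d.update(
                {
                    "model": m.spec.id,
                    "name": m.spec.name,
                    "cutoff": m.cutoff,
                    "apparent_c": m.validation.apparent_c,
                    "corrected_c": m.validation.corrected_c,
                }
            )
            rows.append(d)
        cols = [
            "model", "name", "tp", "fn", "tn", "fp",
            "acc", "sens", "spec", "ppv", "npv",
            "cutoff", "apparent_c", "corrected_c",
        ]
        return pd.DataFrame(rows)[cols]


def run_model_ladder(
    records,
    B: int = 500,
    seed: int | None = 0,
    stratify_symptoms: bool = True,
) -> LadderReport:
    """Fit, validate and compare all eight models on one cohort.

    ``records`` is a list of SubjectRecord or a flat cohort DataFrame with
    the documented columns.  The same ``seed`` always yields an identical
    report.  Classifications use each shrunk model's own optimal-accuracy
    cutoff on the full cohort.
    """
    X = build_design_frame(records)
    y = X["copd"].to_numpy(dtype=float)
    n = len(X)

    reports: list[ModelReport] = []
    classifications: dict[int, np.ndarray] = {}
    for k, spec in enumerate(MODEL_LADDER):
        sub_seed = None if seed is None else (seed * 131 + spec.id) % (2**31 - 1)
        validation, shrunk = bootstrap_validate(X, spec, B=B, seed=sub_seed)
        risks = shrunk.predict(X)
        cutoff, table = optimal_cutoff(risks, y)
        classifications[spec.id] = classify_at(risks, cutoff)
        reports.append(
            ModelReport(
                spec=spec,
                shrunk_model=shrunk,
                validation=validation,
                cutoff=cutoff,
                table=table,
                nri_vs_baseline=None,
                nri_vs_inspiratory=None,
            )
        )

    for rep in reports:
        mid = rep.spec.id
        if mid != 1:
            rep.nri_vs_baseline = compute_nri(classifications[1], classifications[mid], y)
        if mid in EXPIRATORY_COUNTERPART:
            ref = EXPIRATORY_COUNTERPART[mid]
            rep.nri_vs_inspiratory = compute_nri(
                classifications[ref], classifications[mid], y
            )

    strata: list[StratumReport] = []
    if stratify_symptoms and "symptomatic" in X.columns:
        for label, sel in (
            ("symptomatic", X["symptomatic"].to_numpy()),
            ("asymptomatic", ~X["symptomatic"].to_numpy()),
        ):
            Xs = X.loc[sel]
            ys = Xs["copd"].to_numpy(dtype=float)
            c_by_model = {}
            for spec in MODEL_LADDER:
                try:
                    fit_s = fit_logistic(Xs, spec)
                    risks_s = fit_s.predict(Xs)
                    c = c_statistic(risks_s, ys)
                    lo, hi = c_statistic_ci(risks_s, ys)
                except DegenerateInputError:
                    c, lo, hi = float("nan"), float("nan"), float("nan")
                c_by_model[spec.id] = (c, lo, hi)
            strata.append(
                StratumReport(
                    stratum=label,
                    n=len(Xs),
                    n_copd=int(ys.sum()),
                    c_by_model=c_by_model,
                )
            )

    return LadderReport(
        models=reports,
        strata=strata,
        n_subjects=n,
        n_copd=int(y.sum()),
        seed=seed,
        n_bootstrap=B,
    )
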