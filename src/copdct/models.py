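"""Diagnostic logistic models for COPD with bootstrap internal validation.

Core statistical machinery:

* spirometric COPD labelling (FEV1/FVC < 0.70, strict) and severity grading
  by FEV1 %predicted bands;
* maximum-likelihood logistic fits (covariates standardized internally,
  coefficients reported on the original scale);
* the C-statistic as a concordance probability, with a DeLong
  normal-approximation confidence interval;
* Harrell's optimism bootstrap: refit on each resample, score on resample
  and original data, average the difference; corrected C = apparent C
  minus optimism.  Uniform shrinkage of the slope coefficients by the mean
  bootstrap calibration slope, with the intercept re-estimated afterwards;
* the optimal-accuracy cutoff (maximal TP+TN over candidate thresholds),
  confusion-table metrics, the binary Net Reclassification Index, and an
  equal-frequency calibration curve.

Classification convention: predicted risk >= threshold is called positive
(ties at the cutoff classify positive).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    MissingDataError,
    SeparationError,
)
from .synthetic_cohort import SpirometryRecord, SubjectRecord, cohort_to_frame

#: Covariates a ModelSpec may use, in canonical order.
ALL_COVARIATES = (
    "age",
    "bmi",
    "packyears",
    "current_smoker",
    "log_in950",
    "ei_ratio",
    "pi10",
)

DEMOGRAPHICS = ("age", "bmi", "packyears", "current_smoker")


# ---------------------------------------------------------------------------
# COPD labelling
# ---------------------------------------------------------------------------

def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n rounded to the reporting precision (default 1 decimal)."""
    if n <= 0:
        raise DegenerateInputError("denominator must be positive")
    return round(100.0 * k / n, decimals)


def classify_copd(spiro: SpirometryRecord) -> tuple[bool, str]:
    """Spirometric COPD label and severity grade.

    COPD iff FEV1/FVC < 0.70 (strictly below; a ratio of exactly 0.70 is not
    COPD).  Severity from FEV1 %predicted: mild >= 80, moderate in [50, 80),
    severe < 50 (the < 30% range is mapped to severe as well).
    """
    if spiro.fev1_fvc_ratio >= 0.70:
        return False, "none"
    if spiro.fev1_pct_pred >= 80.0:
        return True, "mild"
    if spiro.fev1_pct_pred >= 50.0:
        return True, "moderate"
    return True, "severe"


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design_frame(records) -> pd.DataFrame:
    """Covariate frame (one row per subject) plus the ``copd`` outcome.

    Accepts a list of SubjectRecord or an already-flat cohort DataFrame.
    The emphysema index enters as ``log_in950 = ln(IN-950)`` (the raw index
    is heavily right-skewed); smoking status as ``current_smoker`` in {0,1}
    with "former" as reference.  Rejects missing or non-finite covariates
    explicitly — imputation is out of scope.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = cohort_to_frame(list(records))
    required = ["age", "bmi", "packyears", "smoking_status", "in950", "ei_ratio", "pi10", "copd"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise MissingDataError(f"cohort is missing columns: {missing_cols}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        raise MissingDataError(
            f"{int(bad.sum())} records have missing covariates "
            f"(rows {df.index[bad][:10].tolist()}...); imputation is not supported"
        )
    if (df["in950"] <= 0).any():
        raise ConfigurationError(
            "in950 must be > 0 for the log transform (ln IN-950 undefined at 0)"
        )
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"].astype(float)
    out["bmi"] = df["bmi"].astype(float)
    out["packyears"] = df["packyears"].astype(float)
    out["current_smoker"] = (df["smoking_status"] == "current").astype(float)
    out["log_in950"] = np.log(df["in950"].astype(float))
    out["ei_ratio"] = df["ei_ratio"].astype(float)
    out["pi10"] = df["pi10"].astype(float)
    out["copd"] = df["copd"].astype(int)
    if "symptomatic" in df.columns:
        out["symptomatic"] = df["symptomatic"].astype(bool)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A logistic model specification: a covariate subset with an id.

    The eight ladder rungs use the canonical covariates in
    :data:`ALL_COVARIATES`; ad-hoc specs may reference any columns present
    in the design frame (checked at fit time).
    """

    id: int
    name: str
    covariates: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.covariates)) != len(self.covariates):
            raise ConfigurationError("duplicate covariates in ModelSpec")


#: The eight-model ladder: demographics alone, then each biomarker and each
#: combination added stepwise (BWT = bronchial wall thickness Pi10,
#: AT = air trapping E/I, EMPH = log emphysema index).
MODEL_LADDER: tuple[ModelSpec, ...] = (
    ModelSpec(1, "baseline", DEMOGRAPHICS),
    ModelSpec(2, "baseline+BWT", DEMOGRAPHICS + ("pi10",)),
    ModelSpec(3, "baseline+AT", DEMOGRAPHICS + ("ei_ratio",)),
    ModelSpec(4, "baseline+EMPH", DEMOGRAPHICS + ("log_in950",)),
    ModelSpec(5, "baseline+BWT+AT", DEMOGRAPHICS + ("pi10", "ei_ratio")),
    ModelSpec(6, "baseline+EMPH+AT", DEMOGRAPHICS + ("log_in950", "ei_ratio")),
    ModelSpec(7, "baseline+EMPH+BWT", DEMOGRAPHICS + ("log_in950", "pi10")),
    ModelSpec(
        8, "baseline+EMPH+BWT+AT", DEMOGRAPHICS + ("log_in950", "pi10", "ei_ratio")
    ),
)

#: NRI comparisons quantifying the expiratory (air-trapping) contribution:
#: each model containing E/I vs its inspiratory-only counterpart.
EXPIRATORY_COUNTERPART = {3: 1, 5: 2, 6: 4, 8: 7}


@dataclass
class FittedModel:
    """A logistic fit on the original covariate scale, optionally shrunk."""

    spec: ModelSpec
    intercept: float
    coefficients: dict  # covariate -> log-odds per original unit
    standard_errors: dict
    shrinkage_factor: float = 1.0
    n_obs: int = 0
    log_likelihood: float = float("nan")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept, dtype=float)
        for cov, beta in self.coefficients.items():
            lp += beta * X[cov].to_numpy(dtype=float)
        return lp

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def fit_logistic(
    X: pd.DataFrame, spec: ModelSpec, min_records: int = 25
) -> FittedModel:
    """ML logistic fit of ``copd`` on the spec's covariates.

    Covariates are standardized internally for numerical stability and the
    coefficients returned on the original scale.  Complete separation raises
    :class:`SeparationError`; non-convergence raises
    :class:`ConvergenceError`.
    """
    if len(X) < min_records:
        raise DegenerateInputError(f"need >= {min_records} records, got {len(X)}")
    absent = [c for c in spec.covariates if c not in X.columns]
    if absent:
        raise ConfigurationError(f"design frame lacks covariates: {absent}")
    y = X["copd"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateInputError("outcome has a single class; cannot fit")
    Z = X[list(spec.covariates)].to_numpy(dtype=float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Zs = (Z - mu) / sd
    design = sm.add_constant(Zs, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"complete separation in model {spec.id}: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular information matrix in model {spec.id}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"model {spec.id} did not converge in 100 iterations "
            f"(iterations: {res.mle_retvals})"
        )
    params = res.params
    bse = res.bse
    # unscale: beta_orig = beta_std / sd ; intercept adjusted accordingly
    betas = params[1:] / sd
    intercept = params[0] - float(np.sum(params[1:] * mu / sd))
    ses = bse[1:] / sd
    return FittedModel(
        spec=spec,
        intercept=float(intercept),
        coefficients={c: float(b) for c, b in zip(spec.covariates, betas)},
        standard_errors={c: float(s) for c, s in zip(spec.covariates, ses)},
        n_obs=len(X),
        log_likelihood=float(res.llf),
    )


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def _check_two_class(outcomes: np.ndarray) -> np.ndarray:
    y = np.asarray(outcomes).astype(int)
    if y.min() == y.max():
        raise DegenerateInputError("both outcome classes are required")
    return y


def c_statistic(predicted: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance probability (ROC AUC): over all case-control pairs, the
    fraction where the case's risk is higher, counting ties as 1/2."""
    y = _check_two_class(outcomes)
    p = np.asarray(predicted, dtype=float)
    if p.shape != y.shape:
        raise ConfigurationError("predicted and outcomes must have equal length")
    # rank-based Mann-Whitney formulation (ties handled by midranks)
    ranks = stats.rankdata(p)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(predicted: np.ndarray, outcomes: np.ndarray) -> float:
    """DeLong variance of the AUC estimator via placement values."""
    y = np.asarray(outcomes).astype(int)
    p = np.asarray(predicted, dtype=float)
    cases = p[y == 1]
    controls = p[y == 0]
    m, n = cases.size, controls.size
    # placement of each case among controls and vice versa (midrank for ties)
    v10 = np.array(
        [
            (np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n
            for c in cases
        ]
    )
    v01 = np.array(
        [
            (np.sum(cases > c) + 0.5 * np.sum(cases == c)) / m
            for c in controls
        ]
    )
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def c_statistic_ci(
    predicted: np.ndarray, outcomes: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """DeLong normal-approximation CI for the C-statistic, truncated to [0,1]."""
    y = _check_two_class(outcomes)
    n1 = int(np.asarray(outcomes).astype(int).sum())
    n0 = y.size - n1
    if min(n0, n1) < 10:
        raise DegenerateInputError("need >= 10 subjects per class for the CI")
    auc = c_statistic(predicted, outcomes)
    var = _delong_variance(predicted, outcomes)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


# ---------------------------------------------------------------------------
# cutoffs & confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassificationTable:
    """Confusion counts and derived percentages (1-decimal convention)."""

    tp: int
    fn: int
    tn: int
    fp: int
    acc: float = field(init=False)
    sens: float = field(init=False)
    spec: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)

    def __post_init__(self):
        def pct(num, den):
            return 100.0 * num / den if den > 0 else float("nan")

        total = self.tp + self.fn + self.tn + self.fp
        self.acc = pct(self.tp + self.tn, total)
        self.sens = pct(self.tp, self.tp + self.fn)
        self.spec = pct(self.tn, self.tn + self.fp)
        self.ppv = pct(self.tp, self.tp + self.fp)
        self.npv = pct(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "acc": round(self.acc, 1) if np.isfinite(self.acc) else None,
            "sens": round(self.sens, 1) if np.isfinite(self.sens) else None,
            "spec": round(self.spec, 1) if np.isfinite(self.spec) else None,
            "ppv": round(self.ppv, 1) if np.isfinite(self.ppv) else None,
            "npv": round(self.npv, 1) if np.isfinite(self.npv) else None,
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ClassificationTable:
    """Derived accuracy/sensitivity/specificity/PPV/NPV from raw counts.

    A zero denominator (e.g. PPV with no positive calls) yields NaN rather
    than an exception.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ConfigurationError("confusion counts must be nonnegative")
    return ClassificationTable(tp=tp, fn=fn, tn=tn, fp=fp)


def classify_at(predicted: np.ndarray, threshold: float) -> np.ndarray:
    """Binary call at a risk threshold; ties classify positive (>=)."""
    return np.asarray(predicted, float) >= threshold


def optimal_cutoff(
    predicted: np.ndarray, outcomes: np.ndarray
) -> tuple[float, ClassificationTable]:
    """Threshold maximizing TP+TN (optimal accuracy).

    Candidate thresholds are the midpoints between consecutive sorted unique
    risks, plus one below the minimum and one above the maximum (classify
    all / none).  Ties in TP+TN break toward the lowest threshold, which
    maximizes sensitivity.
    """
    y = _check_two_class(outcomes)
    p = np.asarray(predicted, dtype=float)
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_t, best_correct, best_table = None, -1, None
    for t in candidates:
        calls = p >= t
        tp = int(np.sum(calls & (y == 1)))
        fp = int(np.sum(calls & (y == 0)))
        fn = int(np.sum(~calls & (y == 1)))
        tn = int(np.sum(~calls & (y == 0)))
        if tp + tn > best_correct:
            best_correct = tp + tn
            best_t = float(t)
            best_table = confusion_metrics(tp, fn, tn, fp)
    return best_t, best_table


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------

@dataclass
class NRIResult:
    """Binary net reclassification: event + nonevent components, in %."""

    event_nri: float
    nonevent_nri: float

    @property
    def total_nri(self) -> float:
        return self.event_nri + self.nonevent_nri

    def to_dict(self) -> dict:
        return {
            "event_nri_pct": self.event_nri,
            "nonevent_nri_pct": self.nonevent_nri,
            "total_nri_pct": self.total_nri,
        }


def compute_nri(
    classifications_old: np.ndarray,
    classifications_new: np.ndarray,
    outcomes: np.ndarray,
) -> NRIResult:
    """Net shift toward correct classification from the old to the new model.

    Among events: % moving false-negative -> true-positive minus % moving
    TP -> FN.  Among nonevents: % moving FP -> TN minus % moving TN -> FP.
    Total NRI is their sum.
    """
    old = np.asarray(classifications_old, bool)
    new = np.asarray(classifications_new, bool)
    y = np.asarray(outcomes).astype(bool)
    if not (old.shape == new.shape == y.shape):
        raise ConfigurationError("classification vectors must have equal length")
    n_events = int(y.sum())
    n_nonevents = int((~y).sum())
    if n_events == 0 or n_nonevents == 0:
        raise DegenerateInputError("both outcome classes are required for NRI")
    up_events = int(np.sum(y & new & ~old))  # FN -> TP
    down_events = int(np.sum(y & ~new & old))  # TP -> FN
    up_nonevents = int(np.sum(~y & ~new & old))  # FP -> TN
    down_nonevents = int(np.sum(~y & new & ~old))  # TN -> FP
    return NRIResult(
        event_nri=100.0 * (up_events - down_events) / n_events,
        nonevent_nri=100.0 * (up_nonevents - down_nonevents) / n_nonevents,
    )


def nri_from_marginals(
    tp_old: int, tn_old: int, tp_new: int, tn_new: int, n_events: int, n_nonevents: int
) -> NRIResult:
    """NRI reconstructed from marginal confusion counts of the two models.

    Valid when reclassification flows are one-directional (net flow equals
    the marginal difference); this is the arithmetic a reader can do from a
    published performance table.
    """
    return NRIResult(
        event_nri=100.0 * (tp_new - tp_old) / n_events,
        nonevent_nri=100.0 * (tn_new - tn_old) / n_nonevents,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_curve(
    predicted: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency calibration table: per-bin mean risk vs observed rate.

    Bin sizes differ by at most one subject.  Constant predictions collapse
    to a single effective bin.
    """
    y = _check_two_class(outcomes)
    p = np.asarray(predicted, dtype=float)
    if n_bins > p.size / 2:
        raise ConfigurationError("n_bins may not exceed n/2")
    order = np.argsort(p, kind="mergesort")
    splits = np.array_split(order, n_bins)
    if np.unique(p).size == 1:
        splits = [order]
    rows = []
    for s in splits:
        rows.append(
            {
                "mean_predicted": float(p[s].mean()),
                "observed_fraction": float(y[s].mean()),
                "n": int(s.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap internal validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    apparent_c: float
    optimism: float
    corrected_c: float
    calibration_slope: float
    c_ci_low: float
    c_ci_high: float
    n_bootstrap: int
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "apparent_c": self.apparent_c,
            "optimism": self.optimism,
            "corrected_c": self.corrected_c,
            "calibration_slope": self.calibration_slope,
            "c_ci_95": [self.c_ci_low, self.c_ci_high],
            "n_bootstrap": self.n_bootstrap,
            "n_redraws": self.n_redraws,
        }


def _reestimate_intercept(y: np.ndarray, offset: np.ndarray) -> float:
    """Intercept correction for a fixed (shrunk) linear predictor offset."""
    model = sm.GLM(
        y, np.ones((y.size, 1)), family=sm.families.Binomial(), offset=offset
    )
    return float(model.fit().params[0])


def bootstrap_validate(
    X: pd.DataFrame,
    spec: ModelSpec,
    B: int = 500,
    seed: int | None = 0,
) -> tuple[ValidationReport, FittedModel]:
    """Harrell's optimism bootstrap with calibration-slope shrinkage.

    For each of ``B`` resamples (redrawn up to 10x if single-class): refit
    the model, score C on the resample (bootstrap performance) and on the
    original data (test performance); optimism is the mean difference.  The
    calibration slope is the logistic slope of the original outcomes on the
    resample model's linear predictor; its mean (clipped to (0, 1]) is the
    uniform shrinkage factor applied to the apparent model's slopes, after
    which the intercept is re-estimated on the original data.
    """
    rng = np.random.default_rng(seed)
    apparent = fit_logistic(X, spec)
    y = X["copd"].to_numpy(dtype=float)
    p_app = apparent.predict(X)
    c_app = c_statistic(p_app, y)
    ci = c_statistic_ci(p_app, y)

    optimisms = np.empty(B)
    slopes = np.empty(B)
    n = len(X)
    n_redraws = 0
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, n)
            Xb = X.iloc[idx]
            if 0 < Xb["copd"].sum() < n:
                break
            n_redraws += 1
        try:
            fit_b = fit_logistic(Xb, spec)
        except (SeparationError, ConvergenceError):
            # pathological resample: redraw once more, then give up softly
            idx = rng.integers(0, n, n)
            Xb = X.iloc[idx]
            fit_b = fit_logistic(Xb, spec)
        c_boot = c_statistic(fit_b.predict(Xb), Xb["copd"].to_numpy(dtype=float))
        lp_orig = fit_b.linear_predictor(X)
        c_orig = c_statistic(lp_orig, y)
        optimisms[b] = c_boot - c_orig
        # calibration slope: logistic of original outcomes on the bootstrap LP
        design = sm.add_constant(lp_orig[:, None], has_constant="add")
        try:
            slope_fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100)
            slopes[b] = float(slope_fit.params[1])
        except Exception:
            slopes[b] = np.nan

    optimism = float(np.mean(optimisms))
    slope = float(np.nanmean(slopes))
    shrinkage = float(np.clip(slope, 1e-6, 1.0))

    shrunk_coefs = {c: shrinkage * b for c, b in apparent.coefficients.items()}
    lp_shrunk_noint = np.zeros(n)
    for cov, beta in shrunk_coefs.items():
        lp_shrunk_noint += beta * X[cov].to_numpy(dtype=float)
    new_intercept = _reestimate_intercept(y, lp_shrunk_noint)
    shrunk = FittedModel(
        spec=spec,
        intercept=new_intercept,
        coefficients=shrunk_coefs,
        standard_errors=dict(apparent.standard_errors),
        shrinkage_factor=shrinkage,
        n_obs=n,
        log_likelihood=apparent.log_likelihood,
    )
    report = ValidationReport(
        apparent_c=c_app,
        optimism=optimism,
        corrected_c=c_app - optimism,
        calibration_slope=slope,
        c_ci_low=ci[0],
        c_ci_high=ci[1],
        n_bootstrap=B,
        n_redraws=n_redraws,
    )
    return report, shrunk
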