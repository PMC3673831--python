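"""Logistic models, concordance, cutoffs, NRI, calibration, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from copdct import (
    SpirometryRecord,
    c_statistic,
    c_statistic_ci,
    calibration_curve,
    classify_copd,
    compute_nri,
    confusion_metrics,
    nri_from_marginals,
    optimal_cutoff,
)
from copdct.errors import (
    ConfigurationError,
    DegenerateInputError,
    MissingDataError,
    SeparationError,
)
from copdct.models import ModelSpec, bootstrap_validate, build_design_frame, fit_logistic


# ---------------------------------------------------------------------------
# COPD labelling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ratio,fev1,copd,severity",
    [
        (0.65, 85.0, True, "mild"),
        (0.70, 85.0, False, "none"),   # "below 0.70" is strict
        (0.699, 85.0, True, "mild"),
        (0.60, 79.9, True, "moderate"),
        (0.60, 50.0, True, "moderate"),
        (0.60, 45.0, True, "severe"),
        (0.60, 25.0, True, "severe"),  # below the lowest band maps to severe
        (0.80, 120.0, False, "none"),
    ],
)
def test_classify_copd_bands(ratio, fev1, copd, severity):
    assert classify_copd(SpirometryRecord(fev1, ratio)) == (copd, severity)


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

def _noise_frame(n, p, seed, signal=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(p)})
    lp = np.zeros(n) if signal is None else X.to_numpy() @ signal
    X["copd"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return X


def test_null_covariate_coefficient_near_zero():
    X = _noise_frame(5000, 3, seed=0, signal=np.array([1.0, 0.0, -0.5]))
    fit = fit_logistic(X, ModelSpec(90, "t", ("x0", "x1", "x2")))
    assert abs(fit.coefficients["x1"]) < 3 * fit.standard_errors["x1"]


def test_separation_detected():
    X = pd.DataFrame({"x0": np.r_[np.zeros(25), np.ones(25)],
                      "copd": np.r_[np.zeros(25), np.ones(25)].astype(int)})
    with pytest.raises(SeparationError):
        fit_logistic(X, ModelSpec(91, "sep", ("x0",)))


def test_log_emphysema_requires_positive_index(cohort_1140):
    from copdct import cohort_to_frame

    df = cohort_to_frame(cohort_1140)
    df.loc[df.index[0], "in950"] = 0.0
    with pytest.raises(ConfigurationError):
        build_design_frame(df)


def test_missing_covariates_rejected(cohort_1140):
    from copdct import cohort_to_frame

    df = cohort_to_frame(cohort_1140)
    df.loc[df.index[:3], "pi10"] = np.nan
    with pytest.raises(MissingDataError, match="3 records"):
        build_design_frame(df)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_c_statistic_examples():
    assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert c_statistic([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert c_statistic([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5
    with pytest.raises(DegenerateInputError):
        c_statistic([0.5, 0.6], [1, 1])


def _c_bruteforce(p, y):
    p, y = np.asarray(p, float), np.asarray(y, int)
    cases, controls = p[y == 1], p[y == 0]
    wins = ties = 0
    for c in cases:
        wins += np.sum(c > controls)
        ties += np.sum(c == controls)
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.data())
def test_c_statistic_equals_pair_enumeration(data):
    n = data.draw(st.integers(4, 200))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    p = np.round(rng.random(n), 2)  # rounding forces ties
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    assert c_statistic(p, y) == pytest.approx(_c_bruteforce(p, y), abs=1e-12)


def test_c_statistic_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    p = rng.random(500)
    y = (rng.random(500) < p).astype(int)
    assert c_statistic(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


def test_c_ci_contains_point_and_truncates():
    rng = np.random.default_rng(0)
    y = np.r_[np.zeros(50), np.ones(50)]
    p = np.r_[rng.uniform(0, 0.4, 50), rng.uniform(0.6, 1.0, 50)]  # separating
    lo, hi = c_statistic_ci(p, y)
    assert hi == 1.0  # truncated
    p2 = rng.random(100)
    lo2, hi2 = c_statistic_ci(p2, y)
    assert lo2 <= c_statistic(p2, y) <= hi2


def test_c_ci_coverage_under_known_auc():
    """Normal-approximation DeLong interval covers the true AUC ~95%."""
    rng = np.random.default_rng(3)
    mu = np.sqrt(2) * 0.8416212  # binormal separation giving AUC = Phi(mu/sqrt2) = 0.8
    true_auc = 0.8
    n_rep, covered = 400, 0
    for _ in range(n_rep):
        cases = rng.normal(mu, 1, 100)
        controls = rng.normal(0, 1, 100)
        p = np.r_[cases, controls]
        y = np.r_[np.ones(100), np.zeros(100)]
        lo, hi = c_statistic_ci(p, y)
        covered += lo <= true_auc <= hi
    assert abs(covered / n_rep - 0.95) < 0.03


# ---------------------------------------------------------------------------
# cutoffs & confusion
# ---------------------------------------------------------------------------

def test_optimal_cutoff_separable():
    y = np.r_[np.zeros(10), np.ones(10)]
    p = np.r_[np.linspace(0.0, 0.4, 10), np.linspace(0.6, 1.0, 10)]
    t, table = optimal_cutoff(p, y)
    assert table.acc == 100.0
    assert 0.4 < t < 0.6


def test_optimal_cutoff_all_tied_risks():
    y = np.r_[np.zeros(7), np.ones(3)]
    p = np.full(10, 0.5)
    _, table = optimal_cutoff(p, y)
    assert table.acc == pytest.approx(70.0)  # classify everything one class


def test_optimal_cutoff_enumerable():
    t, table = optimal_cutoff(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    assert table.tp + table.tn == 3  # brute-force maximum over thresholds


def test_optimal_cutoff_ties_break_low():
    # two thresholds reach tp+tn = 3; the lower one has higher sensitivity
    y = np.array([1, 0, 1, 0])
    p = np.array([0.9, 0.6, 0.5, 0.2])
    t, table = optimal_cutoff(p, y)
    assert table.tp + table.tn == 3
    assert t < 0.55  # lowest optimal threshold wins
    assert table.sens == 100.0


TABLE2_ROWS = {
    1: ((125, 312, 630, 73), (66.2, 28.6, 89.6, 63.1, 66.9)),
    2: ((185, 252, 637, 66), (72.1, 42.3, 90.6, 73.7, 71.7)),
    3: ((317, 120, 495, 208), (71.2, 72.5, 70.4, 60.4, 80.5)),
    4: ((229, 208, 619, 84), (74.4, 52.4, 88.1, 73.2, 74.8)),
    5: ((237, 200, 624, 79), (75.5, 54.2, 88.8, 75.0, 75.7)),
    6: ((274, 163, 618, 85), (78.2, 62.7, 87.9, 76.3, 79.1)),
    7: ((309, 128, 610, 93), (80.6, 70.7, 86.8, 76.9, 82.7)),
    8: ((320, 117, 624, 79), (82.8, 73.2, 88.8, 80.2, 84.2)),
}


@pytest.mark.parametrize("model_id", sorted(TABLE2_ROWS))
def test_confusion_metrics_reproduce_published_rows(model_id):
    """Every derived column follows from the counts, to the printed decimal."""
    (tp, fn, tn, fp), (acc, sens, spec, ppv, npv) = TABLE2_ROWS[model_id]
    t = confusion_metrics(tp, fn, tn, fp)
    assert round(t.acc, 1) == acc
    assert round(t.sens, 1) == sens
    assert round(t.spec, 1) == spec
    assert round(t.ppv, 1) == ppv
    assert round(t.npv, 1) == npv


def test_confusion_zero_denominators_flagged():
    t = confusion_metrics(0, 0, 50, 0)
    assert np.isnan(t.sens)  # no events: sensitivity undefined
    assert np.isnan(t.ppv)
    assert t.spec == 100.0
    assert t.acc == 100.0


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------

def test_nri_identity_is_zero():
    y = np.array([1, 1, 0, 0, 1])
    c = np.array([1, 0, 0, 1, 1], bool)
    r = compute_nri(c, c, y)
    assert r.event_nri == 0 and r.nonevent_nri == 0 and r.total_nri == 0


def test_nri_single_shift():
    y = np.r_[np.ones(10), np.zeros(10)].astype(bool)
    old = np.r_[np.zeros(10), np.zeros(10)].astype(bool)
    new = old.copy()
    new[0] = True  # one event moves FN -> TP
    r = compute_nri(old, new, y)
    assert r.event_nri == pytest.approx(10.0)
    assert r.total_nri == pytest.approx(10.0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_nri_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    n = 60
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    a = rng.random(n) < 0.5
    b = rng.random(n) < 0.5
    fwd, bwd = compute_nri(a, b, y), compute_nri(b, a, y)
    assert fwd.event_nri == pytest.approx(-bwd.event_nri)
    assert fwd.nonevent_nri == pytest.approx(-bwd.nonevent_nri)


def test_nri_from_published_marginal_counts():
    """Baseline -> full-model marginals give event +44.6%, nonevent -0.9%."""
    r = nri_from_marginals(tp_old=125, tn_old=630, tp_new=320, tn_new=624,
                           n_events=437, n_nonevents=703)
    assert round(r.event_nri, 1) == 44.6
    assert round(r.nonevent_nri, 1) == -0.9
    assert r.total_nri == pytest.approx(43.8, abs=0.05)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_well_calibrated_simulator():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.05, 0.95, 10000)
    y = (rng.random(10000) < p).astype(int)
    curve = calibration_curve(p, y, n_bins=10)
    assert len(curve) == 10
    assert (curve["n"].max() - curve["n"].min()) <= 1
    # per-bin binomial sd at n=1000 is <= 0.0158; 3.5 sd bounds the max gap
    assert (curve["mean_predicted"] - curve["observed_fraction"]).abs().max() <= 0.055


def test_calibration_constant_predictions_single_bin():
    y = np.r_[np.ones(30), np.zeros(70)].astype(int)
    p = np.full(100, 0.4)
    curve = calibration_curve(p, y, n_bins=5)
    assert len(curve) == 1
    assert curve.loc[0, "observed_fraction"] == pytest.approx(0.30)


def test_calibration_too_many_bins_rejected():
    with pytest.raises(ConfigurationError):
        calibration_curve(np.linspace(0, 1, 20), np.r_[np.zeros(10), np.ones(10)], n_bins=11)


# ---------------------------------------------------------------------------
# bootstrap validation
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_shrinks():
    X = _noise_frame(150, 4, seed=2, signal=np.array([0.8, -0.5, 0.3, 0.0]))
    spec = ModelSpec(92, "b", ("x0", "x1", "x2", "x3"))
    rep1, shrunk1 = bootstrap_validate(X, spec, B=40, seed=11)
    rep2, shrunk2 = bootstrap_validate(X, spec, B=40, seed=11)
    assert rep1.to_dict() == rep2.to_dict()
    assert shrunk1.coefficients == shrunk2.coefficients
    raw = fit_logistic(X, spec)
    assert 0 < shrunk1.shrinkage_factor <= 1.0
    for cov in spec.covariates:
        assert abs(shrunk1.coefficients[cov]) <= abs(raw.coefficients[cov]) + 1e-12


def test_bootstrap_optimism_nonnegative_mostly():
    """Refitting on resamples looks better on the resample than on fresh data."""
    spec = ModelSpec(93, "b", tuple(f"x{i}" for i in range(4)))
    n_ok = 0
    for seed in range(8):
        X = _noise_frame(200, 4, seed=100 + seed, signal=np.array([0.6, 0.4, -0.3, 0.2]))
        rep, _ = bootstrap_validate(X, spec, B=40, seed=seed)
        n_ok += rep.optimism >= -0.01
    assert n_ok >= 7


def test_bootstrap_corrects_noise_overfit():
    """Optimism correction pulls pure-noise fits back to chance.

    A single noise dataset's corrected C inherits that dataset's chance
    association (sd ~0.03), so the behavior is asserted on the mean over
    replicate datasets.
    """
    spec = ModelSpec(94, "noise", tuple(f"x{i}" for i in range(10)))
    apparents, correcteds = [], []
    for seed in range(3):
        X = _noise_frame(200, 10, seed=seed)
        rep, _ = bootstrap_validate(X, spec, B=200, seed=seed + 1)
        apparents.append(rep.apparent_c)
        correcteds.append(rep.corrected_c)
    assert np.mean(apparents) > 0.55
    assert abs(np.mean(correcteds) - 0.5) < 0.03
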