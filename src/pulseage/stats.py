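"""Device-agreement and age-prediction statistics.

Covers the evaluation suite of the analysis: prediction-performance
metrics (MAE, RMSE, R², Pearson r), the corrected resampled t-test for
comparing cross-validated metrics across paired folds, Fisher's z-test
for comparing correlation coefficients, Bland–Altman agreement with
proportional-bias regression, age-adjustment of the vascular age gap
(ΔAge), the ΔAge-tertile blood-pressure models with covariate-adjusted
marginal means, and lag-searched waveform cross-correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats


@dataclass
class MetricSet:
    mae: float
    rmse: float
    r2: float
    r: float | None
    fold: int | None = None


@dataclass
class AgreementResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    slope: float | None = None
    slope_ci: tuple[float, float] | None = None


@dataclass
class TestResult:
    statistic: float
    p_value: float
    name: str
    correction: str | None = None


def metrics(y_true: np.ndarray, y_pred: np.ndarray,
            fold: int | None = None) -> MetricSet:
    """MAE, RMSE, R² (1 − SSE/SST) and Pearson r.

    r is reported as ``None`` when either vector is constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    d = y_pred - y_true
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(d**2)) / sst if sst > 0 else float("nan")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        r = None
    else:
        r = float(spstats.pearsonr(y_true, y_pred)[0])
    return MetricSet(mae=mae, rmse=rmse, r2=r2, r=r, fold=fold)


def fold_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-fold MetricSets from a predictions frame
    (columns participant, fold, age, predicted)."""
    rows = []
    for fold, grp in predictions.groupby("fold", sort=True):
        if len(grp) < 2:  # metrics undefined for singleton folds
            continue
        m = metrics(grp["age"].to_numpy(), grp["predicted"].to_numpy(),
                    fold=int(fold))
        rows.append({"fold": m.fold, "mae": m.mae, "rmse": m.rmse,
                     "r2": m.r2, "r": m.r})
    return pd.DataFrame(rows)


def corrected_resampled_ttest(
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    n_train: int,
    n_test: int,
) -> TestResult:
    """Paired t-test across CV folds with resampling-corrected variance.

    The fold-to-fold variance of the paired differences is inflated by
    the factor (1/k + n_test/n_train) to account for overlapping
    training sets; two-sided p on k−1 degrees of freedom.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired per-fold metrics, k >= 2")
    d = a - b
    k = len(d)
    var = float(np.var(d, ddof=1))
    mean = float(d.mean())
    if var == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        t = 0.0 if mean == 0.0 else math.inf * np.sign(mean)
        return TestResult(t, p, "corrected resampled t-test")
    t = mean / math.sqrt(var * (1.0 / k + n_test / n_train))
    p = 2.0 * float(spstats.t.sf(abs(t), df=k - 1))
    return TestResult(float(t), p, "corrected resampled t-test")


def metric_panel_ttest(
    folds_a: pd.DataFrame, folds_b: pd.DataFrame, n_train: int, n_test: int,
    columns: tuple[str, ...] = ("mae", "rmse", "r2", "r"),
) -> pd.DataFrame:
    """Corrected resampled t-tests for the four-metric panel, with a
    Bonferroni-adjusted p-value across the panel."""
    rows = []
    m = len(columns)
    for c in columns:
        res = corrected_resampled_ttest(
            folds_a[c].to_numpy(), folds_b[c].to_numpy(), n_train, n_test
        )
        rows.append({
            "metric": c, "t": res.statistic, "p": res.p_value,
            "p_bonferroni": min(res.p_value * m, 1.0),
        })
    return pd.DataFrame(rows)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Compare two independent Pearson correlations via Fisher's z."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("need n > 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * float(spstats.norm.sf(abs(z)))
    return TestResult(float(z), p, "Fisher z")


def bland_altman(
    differences: np.ndarray,
    pair_means: np.ndarray | None = None,
    x_for_slope: np.ndarray | None = None,
) -> AgreementResult:
    """Bland–Altman agreement: bias, sample-SD limits of agreement, and
    an optional proportional-bias slope.

    LoA = bias ± 1.96 × SD (n−1 divisor). The slope regresses the
    differences on ``pair_means`` (device-agreement mode) or on
    ``x_for_slope`` (e.g., chronological age for ΔAge plots), with a
    95 % confidence interval.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        raise ValueError("need >= 3 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    res = AgreementResult(
        bias=bias, sd=sd, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd
    )
    x = x_for_slope if x_for_slope is not None else pair_means
    if x is not None:
        X = sm.add_constant(np.asarray(x, dtype=float))
        ols = sm.OLS(d, X).fit()
        ci = ols.conf_int()[1]
        res.slope = float(ols.params[1])
        res.slope_ci = (float(ci[0]), float(ci[1]))
    return res


def loa_from_bias(bias: float, sd: float) -> tuple[float, float]:
    """Limits of agreement implied by a printed bias mean and SD."""
    return bias - 1.96 * sd, bias + 1.96 * sd


def adjust_delta_age(
    raw_delta: np.ndarray, ages: np.ndarray
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Age-adjusted ΔAge: residuals of raw ΔAge regressed on age.

    Returns (adjusted ΔAge, slope, 95 % CI of the slope). The residuals
    are exactly orthogonal to age by OLS construction, removing the
    regression-to-the-mean proportional bias.
    """
    raw_delta = np.asarray(raw_delta, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(raw_delta) < 3:
        raise ValueError("need >= 3 participants")
    X = sm.add_constant(ages)
    ols = sm.OLS(raw_delta, X).fit()
    ci = ols.conf_int()[1]
    return ols.resid, float(ols.params[1]), (float(ci[0]), float(ci[1]))


def tertile_bp_analysis(
    adjusted_delta: np.ndarray,
    bp: np.ndarray,
    ages: np.ndarray,
    sex: np.ndarray,
    bmi: np.ndarray,
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Blood pressure across ΔAge tertiles, covariate-adjusted.

    Tertile cut points sit at the empirical 33.3/66.7 percentiles (rank
    order with a stable sort breaks ties). The model is
    BP ~ tertile + age + sex + BMI with sex as a binary indicator;
    adjusted (marginal) means are evaluated at the covariate sample
    means, and the three pairwise tertile contrasts are
    Bonferroni-corrected.
    """
    adjusted_delta = np.asarray(adjusted_delta, dtype=float)
    bp = np.asarray(bp, dtype=float)
    ages = np.asarray(ages, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    sex = np.asarray(sex)
    male = (
        (sex == "male").astype(float)
        if sex.dtype.kind in "UO"
        else sex.astype(float)
    )
    n = len(bp)
    order = np.argsort(adjusted_delta, kind="stable")
    tert = np.empty(n, dtype=int)
    cut1, cut2 = (n + 2) // 3, (2 * n + 1) // 3
    tert[order[:cut1]] = 0
    tert[order[cut1:cut2]] = 1
    tert[order[cut2:]] = 2
    counts = np.bincount(tert, minlength=3)
    if counts.min() < 3:
        raise ValueError("each tertile needs >= 3 participants")

    if np.ptp(bp) == 0.0:
        # constant outcome: all contrasts are exactly zero
        table = pd.DataFrame({
            "tertile": [1, 2, 3], "n": counts.tolist(),
            "adjusted_mean": [float(bp[0])] * 3, "se": [0.0] * 3,
            "ci_lower": [float(bp[0])] * 3, "ci_upper": [float(bp[0])] * 3,
        })
        results = [
            TestResult(0.0, 1.0, f"tertile {c}", correction="bonferroni x3")
            for c in ("T2-T1", "T3-T1", "T3-T2")
        ]
        return table, results

    t1 = (tert == 1).astype(float)
    t2 = (tert == 2).astype(float)
    X = np.column_stack([np.ones(n), t1, t2, ages, male, bmi])
    ols = sm.OLS(bp, X).fit()

    cov_means = [1.0, 0.0, 0.0, ages.mean(), male.mean(), bmi.mean()]
    rows = []
    for t in range(3):
        xv = list(cov_means)
        xv[1] = 1.0 if t == 1 else 0.0
        xv[2] = 1.0 if t == 2 else 0.0
        xv = np.array(xv)
        mean = float(xv @ ols.params)
        se = float(np.sqrt(xv @ ols.cov_params() @ xv))
        tcrit = spstats.t.ppf(0.975, df=ols.df_resid)
        rows.append({
            "tertile": t + 1, "n": int(counts[t]), "adjusted_mean": mean,
            "se": se, "ci_lower": mean - tcrit * se,
            "ci_upper": mean + tcrit * se,
        })
    table = pd.DataFrame(rows)

    contrasts = {
        "T2-T1": np.array([0, 1, 0, 0, 0, 0.0]),
        "T3-T1": np.array([0, 0, 1, 0, 0, 0.0]),
        "T3-T2": np.array([0, -1, 1, 0, 0, 0.0]),
    }
    results = []
    for name, c in contrasts.items():
        est = float(c @ ols.params)
        se = float(np.sqrt(c @ ols.cov_params() @ c))
        if se == 0.0:
            tval, p = 0.0, 1.0
        else:
            tval = est / se
            p = 2.0 * float(spstats.t.sf(abs(tval), df=ols.df_resid))
        results.append(
            TestResult(float(tval), min(p * 3.0, 1.0), f"tertile {name}",
                       correction="bonferroni x3")
        )
    return table, results


def waveform_similarity(
    pulse_a: np.ndarray, pulse_b: np.ndarray, max_lag: int = 20
) -> float:
    """Maximum normalized cross-correlation over lags within ±max_lag.

    Each lagged overlap is compared by Pearson correlation; the maximum
    over lags is returned. NaN for zero-variance input.
    """
    a = np.asarray(pulse_a, dtype=float)
    b = np.asarray(pulse_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("pulses must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    best = -np.inf
    n = len(a)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            s1, s2 = a[lag:], b[: n - lag]
        else:
            s1, s2 = a[: n + lag], b[-lag:]
        if len(s1) < 3 or np.std(s1) == 0 or np.std(s2) == 0:
            continue
        r = float(np.corrcoef(s1, s2)[0, 1])
        best = max(best, r)
    return best
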