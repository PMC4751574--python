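"""Reliability and cohort-association statistics for CVI studies.

Covers the statistical apparatus around the imaging metrics:

* grader reliability — two-way random-effects, absolute-agreement,
  single-measurement intraclass correlation (McGraw–Wong ICC(A,1)) with an
  F-distribution confidence interval, and Bland–Altman limits of agreement;
* variability — the coefficient of variation, used to compare CVI (percent
  scale) against choroidal thickness (µm scale);
* derived covariates — mean arterial pressure, ocular perfusion pressure,
  spherical equivalent, body-mass index, and the repeated-blood-pressure
  selection rule;
* cohort screening — ordered exclusion filters with a first-failure tally;
* the association workflow — univariate least-squares screen at p < 0.10
  followed by a multivariable ordinary-least-squares fit, reporting
  unstandardized and standardized coefficients.

Cohorts are plain pandas DataFrames; the column dictionary is documented in
``COHORT_COLUMNS``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist

__all__ = [
    "COHORT_COLUMNS",
    "EXCLUSION_CRITERIA",
    "ICCResult",
    "BlandAltmanResult",
    "RegressionRow",
    "coefficient_of_variation",
    "sample_cov",
    "icc_absolute",
    "bland_altman",
    "derive_covariates",
    "select_bp",
    "apply_exclusions",
    "univariate_screen",
    "multivariate_fit",
    "cohort_summary",
    "validate_measurement_table",
]

#: Column dictionary for cohort tables. Binary covariates are coded 0/1 with
#: the reference level second: sex_female (female = 1 vs male = 0),
#: smoking_current (yes = 1 vs no = 0), alcohol (yes = 1 vs no = 0).
COHORT_COLUMNS = {
    "id": "subject identifier",
    "age_years": "age in years",
    "sex_female": "1 = female, 0 = male",
    "axial_length_mm": "axial length, mm",
    "iop_mmhg": "intraocular pressure, mmHg",
    "sbp_mmhg": "systolic blood pressure, mmHg",
    "dbp_mmhg": "diastolic blood pressure, mmHg",
    "weight_kg": "body weight, kg",
    "height_m": "body height, m",
    "sphere_d": "spherical refraction, dioptres",
    "cylinder_d": "cylindrical refraction, dioptres",
    "logmar_va": "best-corrected visual acuity, logMAR",
    "glaucoma_flag": "1 = glaucoma or prior ocular surgery",
    "retinal_disease_flag": "1 = macular / vitreo-retinal disease",
    "scan_quality_db": "OCT quality index, dB",
    "glucose_mmol": "serum glucose, mmol/L",
    "hba1c_pct": "HbA1c, %",
    "cholesterol_mmol": "total cholesterol, mmol/L",
    "triglycerides_mmol": "triglycerides, mmol/L",
    "creatinine_umol": "blood creatinine, µmol/L",
    "smoking_current": "1 = current smoker",
    "alcohol": "1 = consumes alcohol",
    # derived by derive_covariates
    "map_mmhg": "mean arterial pressure, mmHg",
    "opp_mmhg": "mean ocular perfusion pressure, mmHg",
    "se_d": "spherical equivalent, dioptres",
    "bmi": "body-mass index, kg/m²",
    # imaging outcomes
    "sfct_um": "subfoveal choroidal thickness, µm",
    "cvi_percent": "choroidal vascularity index, %",
    "tca_mm2": "total choroidal area, mm²",
    "la_mm2": "luminal area, mm²",
    "sa_mm2": "stromal area, mm²",
}


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model_label: str = "two-way random, absolute agreement, single measures (ICC(A,1))"


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float


@dataclass(frozen=True)
class RegressionRow:
    variable: str
    beta_unstd: float
    beta_std: float
    p_value: float
    ci_low: float = float("nan")  # 95% CI of the unstandardized slope
    ci_high: float = float("nan")


# ---------------------------------------------------------------------------
# Variability

def coefficient_of_variation(mean: float, sd: float) -> float:
    """COV = 100 × SD / mean, in percent. Undefined for mean = 0."""
    if mean == 0:
        raise ValueError("coefficient of variation is undefined for zero mean")
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    return 100.0 * sd / mean


def sample_cov(values: Iterable[float]) -> float:
    """COV of a sample, using the n-1 standard deviation."""
    arr = np.asarray(list(values), dtype=float)
    return coefficient_of_variation(float(arr.mean()), float(arr.std(ddof=1)))


# ---------------------------------------------------------------------------
# Reliability

def validate_measurement_table(table) -> np.ndarray:
    """Check an n-subjects × k-raters value matrix: n,k >= 2, no missing cells."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"measurement table must be at least 2x2, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("measurement table contains missing or non-finite cells")
    return arr


def icc_absolute(table, alpha: float = 0.05) -> ICCResult:
    """Absolute-agreement single-measurement ICC from two-way random ANOVA.

    ICC(A,1) = (MS_rows − MS_err) / (MS_rows + (k−1)·MS_err
               + (k/n)·(MS_cols − MS_err))

    penalizing systematic between-rater offsets: shifting one column by a
    constant lowers the ICC even though the Pearson correlation is
    unchanged. The (1 − alpha) confidence interval uses the McGraw–Wong
    F-based bounds with Satterthwaite degrees of freedom.
    """
    y = validate_measurement_table(table)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("ICC undefined: zero total variance (all cells equal)")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise ValueError("ICC undefined: degenerate variance decomposition")
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # Perfect agreement: all rater effects and residuals vanish.
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0)

    # McGraw & Wong F-based interval for ICC(A,1).
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b) and mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
        f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        ci_low, ci_high = 1.0, 1.0
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high))


LOA_MULTIPLIER = 1.96  # 95% limits of agreement


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement between paired measurements.

    Differences are first-argument-minus-second (measurement 1 − measurement
    2, or grader 1 − grader 2). Limits of agreement are
    ``mean ± 1.96 × SD`` with the n−1 sample standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired measurements must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        sd_diff=sd_diff,
    )


# ---------------------------------------------------------------------------
# Derived covariates

def derive_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add MAP, OPP, spherical equivalent and BMI columns.

    MAP = DBP + (SBP − DBP) / 3
    OPP = (2/3) × MAP − IOP
    SE  = sphere + cylinder / 2
    BMI = weight (kg) / height (m)²
    """
    out = cohort.copy()
    if "sbp_mmhg" in out and "dbp_mmhg" in out:
        out["map_mmhg"] = out["dbp_mmhg"] + (out["sbp_mmhg"] - out["dbp_mmhg"]) / 3.0
        if "iop_mmhg" in out:
            out["opp_mmhg"] = (2.0 / 3.0) * out["map_mmhg"] - out["iop_mmhg"]
    if "sphere_d" in out and "cylinder_d" in out:
        out["se_d"] = out["sphere_d"] + out["cylinder_d"] / 2.0
    if "weight_kg" in out and "height_m" in out:
        if (out["height_m"] <= 0).any():
            bad = out.index[out["height_m"] <= 0].tolist()
            raise ValueError(f"non-positive height for records {bad[:5]}")
        out["bmi"] = out["weight_kg"] / out["height_m"] ** 2
    return out


def select_bp(readings: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Resolve repeated blood-pressure readings to a single (SBP, DBP).

    Two readings are averaged. When a third reading was taken (because the
    first two disagreed by > 10 mmHg systolic or > 5 mmHg diastolic), the
    mean of the two *closest* readings is used: closest by systolic gap,
    ties broken by smallest diastolic gap, then by earliest pair.
    """
    readings = [(float(s), float(d)) for s, d in readings]
    if len(readings) < 2:
        raise ValueError("at least two blood-pressure readings are required")
    if len(readings) == 2:
        pair = (0, 1)
    else:
        pairs = [(i, j) for i in range(len(readings)) for j in range(i + 1, len(readings))]
        pair = min(pairs, key=lambda p: (abs(readings[p[0]][0] - readings[p[1]][0]),
                                         abs(readings[p[0]][1] - readings[p[1]][1]),
                                         p))
    (s1, d1), (s2, d2) = readings[pair[0]], readings[pair[1]]
    return (s1 + s2) / 2.0, (d1 + d2) / 2.0


# ---------------------------------------------------------------------------
# Cohort screening

#: Exclusion criteria in application order: (name, required column, predicate
#: returning True when the record FAILS the criterion).
EXCLUSION_CRITERIA = (
    ("visual_acuity", "logmar_va", lambda v: v > 0.30),
    ("spherical_equivalent", "se_d", lambda v: v < -6.0),
    ("glaucoma", "glaucoma_flag", lambda v: bool(v)),
    ("retinal_disease", "retinal_disease_flag", lambda v: bool(v)),
    ("scan_quality", "scan_quality_db", lambda v: v < 18.0),
)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen a cohort: logMAR VA > 0.30, SE < −6 D, glaucoma/prior surgery,
    vitreo-retinal disease, OCT quality index < 18 dB.

    Each record is attributed to the *first* criterion it fails, so the
    per-criterion tally sums exactly to (input − retained). Spherical
    equivalent is derived from sphere/cylinder if not already present.
    Missing screened fields raise an error naming the record and field.
    """
    tally = {name: 0 for name, _, _ in EXCLUSION_CRITERIA}
    if len(cohort) == 0:
        return cohort.copy(), tally
    df = cohort
    if "se_d" not in df.columns and {"sphere_d", "cylinder_d"}.issubset(df.columns):
        df = derive_covariates(df)
    keep = []
    for idx, row in df.iterrows():
        failed = None
        for name, col, fails in EXCLUSION_CRITERIA:
            if col not in row or pd.isna(row[col]):
                rid = row.get("id", idx)
                raise ValueError(f"record {rid!r} is missing screened field {col!r}")
            if fails(row[col]):
                failed = name
                break
        if failed is None:
            keep.append(idx)
        else:
            tally[failed] += 1
    retained = df.loc[keep].copy()
    assert sum(tally.values()) == len(df) - len(retained)
    return retained, tally


# ---------------------------------------------------------------------------
# Association workflow

def _standardized(slope: float, x: np.ndarray, y: np.ndarray) -> float:
    sy = y.std(ddof=1)
    return slope * x.std(ddof=1) / sy if sy > 0 else float("nan")


def univariate_screen(cohort: pd.DataFrame, outcome: str,
                      candidates: Sequence[str], alpha: float = 0.10,
                      ) -> tuple[list[str], list[RegressionRow]]:
    """Per-variable simple linear regression of ``outcome`` on each candidate.

    Returns the list of variables with two-sided p < ``alpha`` (the entry
    rule for the multivariable model) and a row of statistics for every
    candidate. Zero-variance predictors are excluded with a warning.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    if y.size <= 2:
        raise ValueError("need more than 2 observations per fit")
    rows: list[RegressionRow] = []
    selected: list[str] = []
    for var in candidates:
        x = cohort[var].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            warnings.warn(f"predictor {var!r} has zero variance; excluded from screen")
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        row = RegressionRow(variable=var,
                            beta_unstd=float(res.params[1]),
                            beta_std=_standardized(float(res.params[1]), x, y),
                            p_value=float(res.pvalues[1]))
        rows.append(row)
        if row.p_value < alpha:
            selected.append(var)
    return selected, rows


def multivariate_fit(cohort: pd.DataFrame, outcome: str,
                     selected: Sequence[str]) -> list[RegressionRow]:
    """Multivariable OLS of ``outcome`` on the screened predictors.

    Reports unstandardized and standardized (slope × SD_x / SD_y)
    coefficients with two-sided t-test p-values. A rank-deficient design
    raises, naming the collinear columns.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    X = cohort[list(selected)].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = _find_collinear(cohort, selected)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    return [
        RegressionRow(variable=var,
                      beta_unstd=float(res.params[i + 1]),
                      beta_std=_standardized(float(res.params[i + 1]), X[:, i], y),
                      p_value=float(res.pvalues[i + 1]),
                      ci_low=float(ci[i + 1][0]), ci_high=float(ci[i + 1][1]))
        for i, var in enumerate(selected)
    ]


def _find_collinear(cohort: pd.DataFrame, selected: Sequence[str]) -> list[str]:
    """Columns that are exactly explained by the preceding ones (QR check)."""
    bad = []
    X = sm.add_constant(cohort[list(selected)].to_numpy(dtype=float))
    for i, var in enumerate(selected):
        sub = np.delete(X, i + 1, axis=1)
        resid = X[:, i + 1] - sub @ np.linalg.lstsq(sub, X[:, i + 1], rcond=None)[0]
        if np.allclose(resid, 0, atol=1e-10 * max(1.0, np.abs(X[:, i + 1]).max())):
            bad.append(var)
    return bad


# ---------------------------------------------------------------------------
# Summaries

def cohort_summary(cohort: pd.DataFrame,
                   quantities: Sequence[str] = ("cvi_percent", "sfct_um")) -> dict:
    """Mean ± SD and COV for the named quantities, plus the female percentage."""
    out: dict = {"n": int(len(cohort))}
    if "sex_female" in cohort:
        out["percent_female"] = 100.0 * float(cohort["sex_female"].mean())
    for q in quantities:
        if q in cohort:
            vals = cohort[q].dropna().to_numpy(dtype=float)
            if vals.size >= 2:
                out[q] = {"mean": float(vals.mean()),
                          "sd": float(vals.std(ddof=1)),
                          "cov": sample_cov(vals)}
    return out
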