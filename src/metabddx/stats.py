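"""Two-group differential statistics, FDR q-values and symptom correlations.

Per analyte: pooled-variance Student's t (Welch behind a flag) and Cohen's d
on the Blom-transformed scores, group means/SDs and the case/control fold
change on the raw scaled-intensity scale, Storey q-values across the panel,
and a significance label (``significant`` for p <= alpha, ``trend`` for
p in (alpha, 0.1], else ``ns``).

Demographic baseline comparisons use the same pooled t for continuous
variables and an *uncorrected* Pearson chi-square for dichotomous ones
(the continuity-corrected variant is available but is not the default;
the uncorrected statistic is what the emulated study's printed values
reproduce).

A summary-statistics entry point (:func:`pooled_t_from_summary`) exists
alongside the vector form so printed-table checks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

from .datamodel import (
    COVARIATES,
    GROUP_CONTROL,
    GROUP_PTSD,
    MED_CLASSES,
    AnalysisConfig,
    as_subject_frame,
)

__all__ = [
    "AnalyteResult",
    "pooled_t_test",
    "pooled_t_from_summary",
    "cohens_d",
    "cohens_d_from_summary",
    "fold_change",
    "chi_square_2x2",
    "storey_pi0",
    "storey_qvalues",
    "caps_correlation",
    "significance_label",
    "differential_analysis",
    "demographics_table",
]


@dataclass
class AnalyteResult:
    """One row of the differential-abundance table."""

    analyte: str
    n_control: int
    n_ptsd: int
    mean_control: float
    sd_control: float
    mean_ptsd: float
    sd_ptsd: float
    fold_change: float
    t_stat: float
    p_value: float
    cohens_d: float
    q_value: float
    significance: str


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def pooled_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t (pooled variance by default), two-tailed p.

    Sign convention follows ``(mean(a) - mean(b))``.  Zero pooled variance
    with equal means returns ``(0, 1)``; with unequal means it is an error
    (the data admit no finite t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def pooled_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Pooled-variance t from published (n, mean, SD) summaries.

    Agrees with :func:`pooled_t_test` to ~1e-15 when the summaries are the
    sample moments of the vectors.  Sign follows ``mean1 - mean2``.
    """
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def cohens_d_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float,
    signed: bool = False,
) -> float:
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    d = (mean2 - mean1) / np.sqrt(pooled_var)
    return float(d if signed else abs(d))


def cohens_d(a, b, signed: bool = False) -> float:
    """Standardized mean difference (mean(b) - mean(a)) / pooled SD.

    Reported as an absolute value by default, matching the sign convention
    of the summary tables this pipeline renders.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    return cohens_d_from_summary(
        a.size, a.mean(), a.std(ddof=1), b.size, b.mean(), b.std(ddof=1), signed=signed
    )


def fold_change(mean_control: float, mean_ptsd: float) -> float:
    """Case/control ratio of raw-scale group means."""
    if mean_control <= 0:
        raise ValueError("control mean must be > 0")
    return float(mean_ptsd / mean_control)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1.

    No continuity correction by default (Yates behind ``correction=True``).
    All margins must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("all margins must be > 0")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_pi0(p: np.ndarray, lambda_grid) -> float:
    """Estimate the null proportion pi0 from the p-value histogram tail.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid, smoothed
    with a natural cubic smoother and read off at the largest lambda, then
    clipped into [1/m, 1].
    """
    p = np.asarray(p, dtype=float)
    lam = np.asarray(sorted(set(float(x) for x in lambda_grid)))
    if lam.size < 4:
        raise ValueError("need >= 4 lambda grid points for the cubic smoother")
    m = p.size
    raw = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    spline = UnivariateSpline(lam, raw, k=3)
    pi0 = float(spline(lam.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(p, lambda_grid=None, pi0: float | None = None) -> np.ndarray:
    """FDR q-values: q_i = min over t >= p_i of pi0 * m * t / #{p <= t}.

    pi0 is estimated from ``lambda_grid`` when the panel is large enough
    (m >= 100); smaller panels conservatively use pi0 = 1, in which case the
    q-values coincide exactly with Benjamini-Hochberg adjusted p-values.
    Output is monotone nondecreasing in p and clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            grid = lambda_grid if lambda_grid is not None else AnalysisConfig().qvalue_lambda
            pi0 = storey_pi0(p, grid)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# panel-level analyses
# ---------------------------------------------------------------------------

def significance_label(p: float, config: AnalysisConfig) -> str:
    if p <= config.alpha:
        return "significant"
    if p <= config.trend_upper:
        return "trend"
    return "ns"


def _group_split(subjects: pd.DataFrame, index) -> tuple[np.ndarray, np.ndarray]:
    sub = subjects.loc[list(index)]
    grp = sub["group"].to_numpy()
    return grp == GROUP_CONTROL, grp == GROUP_PTSD


def differential_analysis(
    scaled, blom: pd.DataFrame, subjects, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-analyte case-control table (one row per column of the panel).

    ``scaled`` is the raw reporting-scale matrix (``MetaboliteMatrix`` or
    DataFrame) and ``blom`` its Blom-scale counterpart; both must share
    subjects and columns.  Subjects supply the group labels.
    """
    config = config or AnalysisConfig()
    raw = scaled.values if hasattr(scaled, "analyte_names") else scaled
    if list(raw.columns) != list(blom.columns) or list(raw.index) != list(blom.index):
        raise ValueError("scaled and blom tables must align")
    subjects = as_subject_frame(subjects)
    is_ctrl, is_ptsd = _group_split(subjects, raw.index)
    if is_ctrl.sum() < 2 or is_ptsd.sum() < 2:
        raise ValueError("need >= 2 subjects per group")

    raw_arr = raw.to_numpy()
    z = blom.to_numpy()
    mc = raw_arr[is_ctrl].mean(axis=0)
    sc = raw_arr[is_ctrl].std(axis=0, ddof=1)
    mp = raw_arr[is_ptsd].mean(axis=0)
    sp = raw_arr[is_ptsd].std(axis=0, ddof=1)
    res = sps.ttest_ind(
        z[is_ptsd], z[is_ctrl], axis=0, equal_var=not config.welch
    )
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate columns (zero variance in both groups): identical -> t=0, p=1
    flat = np.isnan(t)
    if flat.any():
        zc, zp = z[is_ctrl], z[is_ptsd]
        for j in np.where(flat)[0]:
            if zc[:, j].std() == 0 and zp[:, j].std() == 0 and zc[:, j].mean() == zp[:, j].mean():
                t[j], p[j] = 0.0, 1.0
            else:
                raise ValueError(
                    f"degenerate Blom scores for analyte {blom.columns[j]!r}"
                )
    n1, n2 = int(is_ptsd.sum()), int(is_ctrl.sum())
    pooled = np.sqrt(
        ((n1 - 1) * z[is_ptsd].std(axis=0, ddof=1) ** 2
         + (n2 - 1) * z[is_ctrl].std(axis=0, ddof=1) ** 2) / (n1 + n2 - 2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.abs(z[is_ptsd].mean(axis=0) - z[is_ctrl].mean(axis=0)) / pooled
    d[np.isnan(d) & (np.asarray(t) == 0)] = 0.0
    q = storey_qvalues(p, lambda_grid=config.qvalue_lambda)
    table = pd.DataFrame(
        {
            "analyte": list(raw.columns),
            "n_control": is_ctrl.sum(),
            "n_ptsd": is_ptsd.sum(),
            "mean_control": mc,
            "sd_control": sc,
            "mean_ptsd": mp,
            "sd_ptsd": sp,
            "fold_change": mp / mc,
            "t_stat": t,
            "p_value": p,
            "cohens_d": d,
            "q_value": q,
        }
    )
    table["significance"] = [significance_label(x, config) for x in table["p_value"]]
    return table.set_index("analyte", drop=False)


def iter_results(table: pd.DataFrame) -> list[AnalyteResult]:
    return [AnalyteResult(**row) for row in table.to_dict("records")]


def caps_correlation(
    blom: pd.DataFrame, subjects, analytes=None
) -> pd.DataFrame:
    """Pearson correlation of each analyte with current CAPS, cases only.

    Returns a frame with columns r, p, n and a ``computable`` flag; a
    constant analyte is reported as not computable rather than NaN-crashing.
    """
    subjects = as_subject_frame(subjects)
    sub = subjects.loc[list(blom.index)]
    keep = sub["group"].to_numpy() == GROUP_PTSD
    if keep.sum() < 3:
        raise ValueError("need >= 3 case subjects for correlations")
    caps = sub["caps_current"].to_numpy()[keep]
    cols = list(analytes) if analytes is not None else list(blom.columns)
    rows = []
    for name in cols:
        y = blom[name].to_numpy()[keep]
        if np.std(y) == 0 or np.std(caps) == 0:
            rows.append({"analyte": name, "r": np.nan, "p": np.nan,
                         "n": int(keep.sum()), "computable": False})
            continue
        r, p = sps.pearsonr(y, caps)
        rows.append({"analyte": name, "r": float(r), "p": float(p),
                     "n": int(keep.sum()), "computable": True})
    return pd.DataFrame(rows).set_index("analyte", drop=False)


def demographics_table(subjects, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Baseline group comparison: pooled t for continuous variables,
    uncorrected chi-square for dichotomous ones."""
    config = config or AnalysisConfig()
    frame = as_subject_frame(subjects)
    is_ctrl = frame["group"] == GROUP_CONTROL
    is_ptsd = frame["group"] == GROUP_PTSD
    rows = []
    continuous = list(COVARIATES) + ["caps_current", "caps_lifetime"]
    for var in continuous:
        a = frame.loc[is_ptsd, var].dropna().to_numpy()
        b = frame.loc[is_ctrl, var].dropna().to_numpy()
        t, p = pooled_t_test(a, b, welch=config.welch)
        rows.append({
            "variable": var, "kind": "continuous",
            "mean_control": b.mean(), "sd_control": b.std(ddof=1),
            "mean_ptsd": a.mean(), "sd_ptsd": a.std(ddof=1),
            "statistic": abs(t), "p_value": p,
        })
    dichotomous = ["smoker", "mdd", "any_medication"] + list(MED_CLASSES)
    for var in dichotomous:
        pos_c = int(frame.loc[is_ctrl, var].sum())
        pos_p = int(frame.loc[is_ptsd, var].sum())
        table = [[is_ctrl.sum() - pos_c, pos_c], [is_ptsd.sum() - pos_p, pos_p]]
        try:
            stat, p = chi_square_2x2(table)
        except ValueError:  # zero margin, e.g. nobody takes the drug
            stat, p = np.nan, np.nan
        rows.append({
            "variable": var, "kind": "dichotomous",
            "mean_control": pos_c, "sd_control": np.nan,
            "mean_ptsd": pos_p, "sd_ptsd": np.nan,
            "statistic": stat, "p_value": p,
        })
    return pd.DataFrame(rows).set_index("variable", drop=False)
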