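"""Covariate ANCOVA battery and exclusion-based sensitivity analyses.

Each ANCOVA is a one-covariate-at-a-time OLS model

    blom_score ~ intercept + group + covariate

whose reported value is the two-tailed p of the group coefficient
(t-based, df = n - 3).  Covariates enter untransformed; subjects with a
missing covariate are dropped and counted.  MDD can be supplied as a
binary covariate the same way.

Sensitivity analyses rerun the *entire* preprocessing + t-test chain on
the surviving subject subset (imputation minima and medians recomputed
within the subset), simulating having recruited the smaller cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import (
    GROUP_CONTROL,
    GROUP_PTSD,
    AnalysisConfig,
    MetaboliteMatrix,
    as_subject_frame,
)
from .preprocess import DEFAULT_RATIOS, RatioDefinition, prepare_cohort
from .stats import differential_analysis, pooled_t_test

__all__ = [
    "AdjustmentResult",
    "ancova_group_p",
    "ancova_battery",
    "sensitivity_exclusion",
    "subgroup_t",
    "EXCLUSION_PREDICATES",
]

_COLLINEAR_TOL = 1e-10


@dataclass
class AdjustmentResult:
    analyte: str
    label: str
    group_p: float
    n_used: int


def ancova_group_p(y, group, covariate) -> tuple[float, int]:
    """Group-effect p after adjusting for one covariate.

    ``group`` may be boolean/0-1 or the group label strings.  Subjects with
    a missing covariate or response are dropped (and reflected in
    ``n_used``).  A covariate (numerically) collinear with the group
    indicator or the intercept is a hard error -- the group effect would be
    unidentifiable.
    """
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    grp = np.asarray(group)
    if grp.dtype.kind in "UO":
        grp = (grp == GROUP_PTSD).astype(float)
    else:
        grp = grp.astype(float)
    keep = np.isfinite(y) & np.isfinite(cov)
    y, cov, grp = y[keep], cov[keep], grp[keep]
    n_used = int(keep.sum())
    if n_used < 4:
        raise ValueError(f"ANCOVA needs >= 4 usable subjects, got {n_used}")
    if len(np.unique(grp)) < 2:
        raise ValueError("both groups must survive covariate filtering")
    if np.var(cov) < _COLLINEAR_TOL:
        raise ValueError("covariate is (near-)constant: collinear with intercept")
    r = np.corrcoef(cov, grp)[0, 1]
    if 1.0 - r * r < _COLLINEAR_TOL:
        raise ValueError("covariate is collinear with the group indicator")
    X = np.column_stack([np.ones(n_used), grp, cov])
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[1]), n_used


def ancova_battery(
    blom: pd.DataFrame,
    subjects,
    covariates: Sequence[str] = ("bmi", "hba1c", "glucose", "cotinine"),
    analytes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Parallel single-covariate ANCOVAs; wide frame analyte x covariate p.

    ``covariates`` may include ``"mdd"`` (binary regressor) or
    ``"waist_hip"`` alongside the continuous clinical covariates.
    """
    subjects = as_subject_frame(subjects)
    sub = subjects.loc[list(blom.index)]
    group = (sub["group"] == GROUP_PTSD).to_numpy().astype(float)
    cols = list(analytes) if analytes is not None else list(blom.columns)
    out: dict[str, list[float]] = {}
    n_used: dict[str, int] = {}
    for cov_name in covariates:
        cov = sub[cov_name].to_numpy().astype(float)
        ps = []
        for name in cols:
            p, n = ancova_group_p(blom[name].to_numpy(), group, cov)
            ps.append(p)
            n_used[cov_name] = n
        out[cov_name] = ps
    frame = pd.DataFrame(out, index=pd.Index(cols, name="analyte"))
    frame.attrs["n_used"] = n_used
    return frame


# named exclusion predicates: True -> subject is excluded
EXCLUSION_PREDICATES: dict[str, Callable[[pd.Series], bool]] = {
    "any_medication": lambda row: bool(row["any_medication"]),
    "mdd": lambda row: bool(row["mdd"]),
    "smoker": lambda row: bool(row["smoker"]),
    **{
        cls: (lambda row, _c=cls: bool(row[_c]))
        for cls in (
            "sedatives", "statins", "antidepressants", "anticonvulsants",
            "anti_inflammatories", "antidiabetics", "antibiotics", "beta_blockers",
        )
    },
}


def _resolve_predicate(exclusion) -> tuple[str, Callable[[pd.Series], bool]]:
    if callable(exclusion):
        return getattr(exclusion, "__name__", "custom"), exclusion
    if exclusion in EXCLUSION_PREDICATES:
        return str(exclusion), EXCLUSION_PREDICATES[exclusion]
    raise KeyError(f"unknown exclusion predicate {exclusion!r}")


def sensitivity_exclusion(
    matrix: MetaboliteMatrix,
    subjects,
    exclusion,
    config: AnalysisConfig | None = None,
    ratio_defs: Sequence[RatioDefinition] | None = DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Re-run the full chain with a subject subset excluded.

    ``exclusion`` is a registered name (e.g. ``"any_medication"``) or a
    callable on a subject row returning True for *excluded* subjects.
    A pure function of the surviving subject set: preprocessing is redone
    from the unimputed matrix.
    """
    config = config or AnalysisConfig()
    label, pred = _resolve_predicate(exclusion)
    frame = as_subject_frame(subjects).loc[list(matrix.subject_ids)]
    keep = ~frame.apply(pred, axis=1).to_numpy().astype(bool)
    survivors = frame.loc[keep]
    for grp in (GROUP_CONTROL, GROUP_PTSD):
        if (survivors["group"] == grp).sum() < 2:
            raise ValueError(
                f"exclusion {label!r} leaves < 2 subjects in group {grp}"
            )
    sub_matrix = matrix.select_subjects(list(survivors.index))
    scaled, blom = prepare_cohort(sub_matrix, ratio_defs)
    result = differential_analysis(scaled, blom, survivors, config)
    result.insert(1, "exclusion", label)
    return result


def subgroup_t(
    matrix: MetaboliteMatrix,
    subjects,
    split,
    within: str = GROUP_PTSD,
    config: AnalysisConfig | None = None,
    ratio_defs: Sequence[RatioDefinition] | None = DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Pooled t between two subgroups of one group (e.g. MDD+/- cases).

    ``split`` is a registered predicate name or callable on a subject row;
    True/False defines the two cells.  Preprocessing is redone within the
    selected group's subjects.
    """
    config = config or AnalysisConfig()
    label, pred = _resolve_predicate(split)
    frame = as_subject_frame(subjects).loc[list(matrix.subject_ids)]
    sel = frame.loc[frame["group"] == within]
    if len(sel) < 4:
        raise ValueError(f"too few subjects in group {within}")
    flags = sel.apply(pred, axis=1).to_numpy().astype(bool)
    if flags.sum() < 2 or (~flags).sum() < 2:
        raise ValueError(f"split {label!r} leaves an empty/underfilled cell")
    sub_matrix = matrix.select_subjects(list(sel.index))
    scaled, blom = prepare_cohort(sub_matrix, ratio_defs)
    z = blom.to_numpy()
    rows = []
    for j, name in enumerate(blom.columns):
        t, p = pooled_t_test(z[flags, j], z[~flags, j], welch=config.welch)
        rows.append({"analyte": name, "split": label, "t_stat": t, "p_value": p,
                     "n_true": int(flags.sum()), "n_false": int((~flags).sum())})
    return pd.DataFrame(rows).set_index("analyte", drop=False)
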