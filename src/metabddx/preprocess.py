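"""Preprocessing chain: LOD imputation, median scaling, composite ratios,
Blom rank-based inverse-normal transformation.

The canonical order, applied per cohort, is

    impute_minimum -> median_scale -> add_composite_ratios -> blom

Group means/SDs and fold changes are reported on the imputed, median-scaled
("raw") scale; all hypothesis tests downstream run on the Blom scores.
Composite ratios are computed on the raw scale *before* the Blom step and
then transformed alongside the single analytes, so their reported means
stay on the interpretable ratio scale.

Imputation minima and medians are computed within whatever subject set is
passed in: the discovery and test cohorts are preprocessed separately
(separate platform batches), and sensitivity re-analyses on subject subsets
recompute both, as if the smaller cohort had been recruited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datamodel import MetaboliteMatrix

__all__ = [
    "RatioDefinition",
    "DEFAULT_RATIOS",
    "impute_minimum",
    "median_scale",
    "blom_transform",
    "blom_frame",
    "add_composite_ratios",
    "prepare_cohort",
]


@dataclass(frozen=True)
class RatioDefinition:
    """A named composite analyte: sum(numerator) / sum(denominator) per subject."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValueError(f"{self.name}: numerator and denominator must be non-empty")
        if num & den:
            raise ValueError(f"{self.name}: numerator and denominator must be disjoint")


#: anaerobic-vs-aerobic proxy: glycolysis end-products over a TCA intermediate
GLYCOLYTIC_RATIO = RatioDefinition(
    "GLYCOLYTIC_RATIO", ("pyruvate", "lactate"), ("citrate",)
)
#: global arginine bioavailability: arginine over its catabolites
GABR = RatioDefinition("GABR", ("arginine",), ("ornithine", "citrulline"))

DEFAULT_RATIOS: tuple[RatioDefinition, ...] = (GLYCOLYTIC_RATIO, GABR)


def impute_minimum(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace each below-LOD cell with its analyte's observed minimum.

    The minimum is taken over all non-missing values of that analyte across
    every subject in the matrix.  An analyte with no observed value at all
    is a hard error.  Observed cells are never altered, so no analyte's
    minimum ever decreases.
    """
    vals = matrix.values.to_numpy().copy()
    mask = matrix.mask.to_numpy()
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = [matrix.analyte_names[j] for j in np.where(all_missing)[0]]
        raise ValueError(f"analyte(s) with all cells below LOD: {bad}")
    with np.errstate(all="ignore"):
        col_min = np.nanmin(np.where(mask, np.nan, vals), axis=0)
    vals = np.where(mask, col_min, vals)
    frame = pd.DataFrame(vals, index=matrix.subject_ids, columns=matrix.analyte_names)
    return MetaboliteMatrix(frame)


def median_scale(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each analyte by its across-subject median (post: median == 1)."""
    if matrix.mask.to_numpy().any():
        raise ValueError("median_scale requires an imputed matrix (no masked cells)")
    med = matrix.values.median(axis=0)
    zero = med[med == 0]
    if len(zero):
        raise ValueError(f"analyte(s) with zero median: {list(zero.index)}")
    return MetaboliteMatrix(matrix.values / med)


def blom_transform(x) -> np.ndarray:
    """Blom rank-based inverse-normal scores.

    z_i = Phi^-1((r_i - 3/8) / (n + 1/4)) with average ranks for ties; the
    classical Blom offset.  Strictly order-preserving on distinct values and
    invariant under any strictly monotone transformation of the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("blom_transform expects a 1-D vector")
    n = x.size
    if n < 2:
        raise ValueError("blom_transform needs n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("blom_transform requires finite input")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 0.375) / (n + 0.25))


def blom_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Blom transform of an imputed matrix (vectorized)."""
    arr = values.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise ValueError("blom_frame requires finite values")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("blom_frame needs n >= 2")
    ranks = rankdata(arr, method="average", axis=0)
    z = ndtri((ranks - 0.375) / (n + 0.25))
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def add_composite_ratios(
    matrix: MetaboliteMatrix, defs: Iterable[RatioDefinition] = DEFAULT_RATIOS
) -> MetaboliteMatrix:
    """Append one column per ratio definition on the raw (scaled) intensities."""
    frame = matrix.values.copy()
    if matrix.mask.to_numpy().any():
        raise ValueError("composite ratios require an imputed matrix")
    for rd in defs:
        missing = [a for a in (*rd.numerator, *rd.denominator) if a not in frame.columns]
        if missing:
            raise KeyError(f"ratio {rd.name}: analyte(s) not in matrix: {missing}")
        if rd.name in frame.columns:
            raise ValueError(f"ratio name {rd.name!r} collides with an existing analyte")
        num = frame[list(rd.numerator)].sum(axis=1)
        den = frame[list(rd.denominator)].sum(axis=1)
        bad = den[den <= 0]
        if len(bad):
            raise ValueError(
                f"ratio {rd.name}: non-positive denominator for subject(s) "
                f"{list(bad.index)}"
            )
        frame[rd.name] = num / den
    return MetaboliteMatrix(frame)


def prepare_cohort(
    matrix: MetaboliteMatrix,
    ratio_defs: Sequence[RatioDefinition] | None = DEFAULT_RATIOS,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Run the full chain on one cohort.

    Returns ``(scaled, blom)`` where ``scaled`` is the imputed, median-scaled
    matrix with ratio columns appended (raw reporting scale) and ``blom`` the
    Blom-transformed scores of the same columns (testing scale).
    """
    imputed = impute_minimum(matrix)
    scaled = median_scale(imputed)
    if ratio_defs:
        scaled = add_composite_ratios(scaled, ratio_defs)
    return scaled, blom_frame(scaled.values)
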