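"""Shared data model and delimited-text I/O for the pipeline.

The two in-memory containers everything else operates on are

``MetaboliteMatrix``
    a subjects x analytes table of non-negative, dimensionless scaled
    intensities (each analyte is conventionally divided by its cohort
    median, so typical values sit near 1) together with a boolean
    missingness mask marking cells that fell below the platform's limit
    of detection (LOD);

``SubjectRecord``
    per-subject clinical metadata: cohort (discovery vs test), case/control
    group, continuous covariates (BMI, HbA1c, fasting glucose, plasma
    cotinine, waist-to-hip ratio), medication-class flags, comorbid MDD,
    smoking status and CAPS symptom scores.

Files are plain CSV/TSV.  In matrix files the first row holds analyte
names, the first column subject ids, and an *empty* cell is the only
missingness encoding -- numeric sentinels such as 0 or -1 are legal data
(0 is a valid scaled intensity).  ``write_matrix`` round-trips bit-
identically with ``read_matrix`` for finite values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

GROUP_CONTROL = "ptsd_neg"
GROUP_PTSD = "ptsd_pos"
GROUPS = (GROUP_CONTROL, GROUP_PTSD)
COHORTS = ("discovery", "test")

#: medication classes tracked per subject; ``any_medication`` is their OR
MED_CLASSES = (
    "sedatives",
    "statins",
    "antidepressants",
    "anticonvulsants",
    "anti_inflammatories",
    "antidiabetics",
    "antibiotics",
    "beta_blockers",
)

#: continuous covariates carried by every subject record
COVARIATES = ("bmi", "hba1c", "glucose", "cotinine", "waist_hip")

_SEP = {"csv": ",", "tsv": "\t"}


def _check_unique(names: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {kind} {n!r}")
        seen.add(n)


@dataclass
class MetaboliteMatrix:
    """Subjects x analytes scaled-intensity table with a below-LOD mask.

    ``values`` is a float DataFrame (index = subject ids, columns = analyte
    names); masked cells are stored as NaN.  ``mask`` is a boolean DataFrame
    of the same shape, True meaning below LOD / not detected.  Non-missing
    values must be finite and >= 0; subject ids and analyte names are unique
    and whitespace-trimmed.
    """

    values: pd.DataFrame
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.copy()
        vals.index = [str(i).strip() for i in vals.index]
        vals.columns = [str(c).strip() for c in vals.columns]
        _check_unique(list(vals.index), "subject id")
        _check_unique(list(vals.columns), "analyte")
        vals = vals.astype(float)
        if self.mask is None:
            mask = vals.isna()
        else:
            mask = self.mask.copy().astype(bool)
            if mask.shape != vals.shape:
                raise ValueError(
                    f"mask shape {mask.shape} != values shape {vals.shape}"
                )
            mask.index = vals.index
            mask.columns = vals.columns
        # canonical storage: masked cells are NaN in `values`
        vals = vals.mask(mask)
        observed = vals.to_numpy()[~mask.to_numpy()]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing values must be finite")
        if observed.size and np.any(observed < 0):
            raise ValueError("non-missing scaled intensities must be >= 0")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)

    # -- conveniences -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.values.copy(), self.mask.copy())

    def select_analytes(self, names: Sequence[str]) -> "MetaboliteMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"analytes not in matrix: {missing}")
        return MetaboliteMatrix(self.values[list(names)], self.mask[list(names)])

    def select_subjects(self, ids: Sequence[str]) -> "MetaboliteMatrix":
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"subjects not in matrix: {missing}")
        return MetaboliteMatrix(
            self.values.loc[list(ids)], self.mask.loc[list(ids)]
        )


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject (one row of the demographics table)."""

    subject_id: str
    cohort: str
    group: str
    covariates: dict[str, float] = field(default_factory=dict)
    med_flags: dict[str, bool] = field(default_factory=dict)
    mdd: bool = False
    caps_current: float = 0.0
    caps_lifetime: float = 0.0
    smoker: bool = False

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.caps_current < 0 or self.caps_lifetime < 0:
            raise ValueError("CAPS scores must be >= 0")
        flags = {c: bool(self.med_flags.get(c, False)) for c in MED_CLASSES}
        flags["any_medication"] = any(flags[c] for c in MED_CLASSES)
        if "any_medication" in self.med_flags and (
            bool(self.med_flags["any_medication"]) != flags["any_medication"]
        ):
            raise ValueError(
                f"any_medication inconsistent with class flags for "
                f"{self.subject_id}"
            )
        self.med_flags = flags
        for k, v in self.covariates.items():
            if v is not None and not np.isfinite(v):
                raise ValueError(f"covariate {k} not finite for {self.subject_id}")


def subjects_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords into a tidy DataFrame (one row per subject)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "cohort": r.cohort,
            "group": r.group,
        }
        for c in COVARIATES:
            row[c] = r.covariates.get(c, np.nan)
        for m in MED_CLASSES:
            row[m] = bool(r.med_flags.get(m, False))
        row["any_medication"] = bool(r.med_flags["any_medication"])
        row["mdd"] = bool(r.mdd)
        row["smoker"] = bool(r.smoker)
        row["caps_current"] = r.caps_current
        row["caps_lifetime"] = r.caps_lifetime
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.set_index("subject_id", drop=False)


def frame_to_subjects(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                cohort=str(row["cohort"]),
                group=str(row["group"]),
                covariates={c: float(row[c]) for c in COVARIATES if c in row},
                med_flags={m: bool(row[m]) for m in MED_CLASSES if m in row},
                mdd=bool(row["mdd"]),
                caps_current=float(row["caps_current"]),
                caps_lifetime=float(row["caps_lifetime"]),
                smoker=bool(row["smoker"]),
            )
        )
    return records


def as_subject_frame(subjects) -> pd.DataFrame:
    """Accept either a list of SubjectRecord or an already-tidy frame."""
    if isinstance(subjects, pd.DataFrame):
        return subjects
    return subjects_to_frame(subjects)


@dataclass
class AnalysisConfig:
    """Knobs shared across the statistical stages.

    alpha            two-tailed significance level (0.05)
    trend_upper      upper edge of the "trend" band (p in (alpha, 0.1])
    two_tailed       fixed True; one-tailed testing is not supported
    qvalue_lambda    tuning grid for the q-value pi0 estimate
    rng_seed         seed for every stochastic step (resampling)
    n_bootstrap      number of pseudo discovery/test re-splits
    welch            use Welch instead of pooled-variance t (off by default)
    """

    alpha: float = 0.05
    trend_upper: float = 0.1
    two_tailed: bool = True
    qvalue_lambda: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
    rng_seed: int = 0
    n_bootstrap: int = 1000
    welch: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.trend_upper <= 1):
            raise ValueError("need 0 < alpha < trend_upper <= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not self.two_tailed:
            raise NotImplementedError("all tests are two-tailed")
        lam = tuple(float(x) for x in self.qvalue_lambda)
        if any(not (0 <= x < 1) for x in lam):
            raise ValueError("qvalue_lambda values must lie in [0, 1)")
        self.qvalue_lambda = lam

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {**asdict(self), "qvalue_lambda": list(self.qvalue_lambda)}, fh
            )


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, dialect: str = "csv") -> MetaboliteMatrix:
    """Read a subjects x analytes matrix from CSV/TSV.

    First row = analyte names, first column = subject ids.  Empty cells
    (and only empty cells) become masked entries.  Duplicate ids/names and
    non-numeric non-empty cells are hard errors naming the offender.
    """
    sep = _SEP[dialect]
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows) < 2:
        raise ValueError(f"{path}: matrix file needs a header and >=1 row")
    analytes = [c.strip() for c in rows[0][1:]]
    _check_unique(analytes, "analyte")
    subject_ids = [r[0].strip() for r in rows[1:]]
    _check_unique(subject_ids, "subject id")
    width = len(analytes)
    values = np.full((len(subject_ids), width), np.nan)
    mask = np.zeros((len(subject_ids), width), dtype=bool)
    for i, row in enumerate(rows[1:]):
        cells = row[1:]
        if len(cells) != width:
            raise ValueError(
                f"{path}: row for subject {subject_ids[i]!r} has "
                f"{len(cells)} cells, expected {width}"
            )
        for j, cell in enumerate(cells):
            cell = cell.strip()
            if cell == "":
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at subject "
                    f"{subject_ids[i]!r}, analyte {analytes[j]!r}"
                ) from None
    frame = pd.DataFrame(values, index=subject_ids, columns=analytes)
    return MetaboliteMatrix(frame, pd.DataFrame(mask, index=subject_ids, columns=analytes))


def write_matrix(matrix: MetaboliteMatrix, path: str | Path, dialect: str = "csv") -> None:
    """Write a matrix; masked cells become empty, floats keep full precision."""
    sep = _SEP[dialect]
    vals = matrix.values.to_numpy()
    mask = matrix.mask.to_numpy()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["subject_id", *matrix.analyte_names])
        for i, sid in enumerate(matrix.subject_ids):
            row: list[str] = [sid]
            for j in range(matrix.n_analytes):
                row.append("" if mask[i, j] else repr(float(vals[i, j])))
            writer.writerow(row)


def read_matrix_xlsx(path: str | Path, sheet: int | str = 0) -> MetaboliteMatrix:
    """Convenience wrapper for an S1-dataset-shaped workbook sheet.

    Layout expectations are identical to :func:`read_matrix` (first column
    subject ids, header row analyte names, blank cells = below LOD).
    """
    frame = pd.read_excel(path, sheet_name=sheet, index_col=0)
    frame.index = [str(i).strip() for i in frame.index]
    frame.columns = [str(c).strip() for c in frame.columns]
    _check_unique(list(frame.index), "subject id")
    _check_unique(list(frame.columns), "analyte")
    return MetaboliteMatrix(frame.astype(float))


def read_subjects(path: str | Path, dialect: str = "csv") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_SEP[dialect])
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path}: subjects table needs a subject_id column")
    frame["subject_id"] = frame["subject_id"].astype(str)
    _check_unique(list(frame["subject_id"]), "subject id")
    boolish = list(MED_CLASSES) + ["any_medication", "mdd", "smoker"]
    for col in boolish:
        if col in frame.columns:
            frame[col] = frame[col].astype(int).astype(bool)
    return frame.set_index("subject_id", drop=False)


def write_subjects(frame: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    out = frame.copy()
    boolish = list(MED_CLASSES) + ["any_medication", "mdd", "smoker"]
    for col in boolish:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep=_SEP[dialect], index=False)


# ---------------------------------------------------------------------------
# panel harmonization
# ---------------------------------------------------------------------------

def harmonize_panels(
    discovery: MetaboliteMatrix, test: MetaboliteMatrix
) -> tuple[MetaboliteMatrix, MetaboliteMatrix, list[str]]:
    """Restrict both cohorts to their common analyte panel.

    The two platform runs identify partially different compound sets; only
    analytes named in *both* matrices are analysed.  Matching is exact
    string equality after whitespace trimming (no fuzzy chemical-name
    matching), and the shared panel is ordered lexicographically so results
    do not depend on input column order.  Downstream replication assumes
    the positional alignment this establishes.
    """
    shared = sorted(set(discovery.analyte_names) & set(test.analyte_names))
    if not shared:
        raise ValueError("no analytes shared between the two panels")
    return discovery.select_analytes(shared), test.select_analytes(shared), shared
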