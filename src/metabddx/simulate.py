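"""Synthetic discovery/test cohort generator.

Emulates a two-cohort case-control plasma metabolomics study: each analyte
is drawn per group from a zero-truncated normal whose *post-truncation*
mean and SD equal the configured (published summary) values, cells below a
configurable limit-of-detection quantile of the control distribution are
censored, and subject metadata (covariates, medication flags, MDD, smoking,
CAPS symptom scores) is drawn with group-dependent parameters so that
covariate-group confounding mirrors the demographics table of the study
being emulated.

The defaults (``default_spec``) reproduce the published discovery cohort
(51 controls / 52 cases) and test cohort (31/31) analyte summaries, plus
20 null analytes (identical group distributions) for type-I-error checks
and two synthetic support analytes (ornithine, citrulline) so the built-in
composite ratios are computable.

Analytes are drawn independently by default.  An optional single common
latent factor (``latent_loading``) induces positive inter-analyte
correlation via a Gaussian copula without changing any marginal, and an
optional linear leakage term (``leakage``) adds ``beta * covariate`` to a
metabolite so covariate-adjustment behaviour can be probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .datamodel import (
    COVARIATES,
    GROUP_CONTROL,
    GROUP_PTSD,
    MED_CLASSES,
    MetaboliteMatrix,
    SubjectRecord,
)

__all__ = [
    "AnalyteSpec",
    "CohortSpec",
    "default_spec",
    "generate",
    "spec_to_yaml",
    "spec_from_yaml",
]


# ---------------------------------------------------------------------------
# zero-truncated normal with moment matching
# ---------------------------------------------------------------------------

def _lam(a: float) -> float:
    # inverse Mills ratio phi(a) / P(Z > a)
    return norm.pdf(a) / ndtr(-a)


def _k2(a: float) -> float:
    lam = _lam(a)
    return 1.0 + a * lam - lam * lam


@lru_cache(maxsize=None)
def truncnorm_params(mean: float, sd: float) -> tuple[float, float, float]:
    """Parent ``(mu, sigma, alpha)`` of a zero-truncated normal.

    For ``mean/sd >= 1.05`` the parent is solved so the truncated
    distribution has exactly the requested mean and SD (the mean/SD ratio
    of any zero-truncated normal exceeds 1, approaching 1 in the heavy-
    truncation exponential limit).  Below that ratio no solution exists
    and the requested values are used directly as parent parameters; the
    realised moments then deviate from the request (documented behaviour,
    affects only heavily-skewed metadata such as near-zero symptom scores).
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    ratio = mean / sd
    if ratio >= 6.0:
        # truncation mass < 1e-9; parent == truncated to double precision
        return float(mean), float(sd), -ratio
    if ratio < 1.05:
        return float(mean), float(sd), -ratio

    def f(a: float) -> float:
        return a - _lam(a) + ratio * np.sqrt(_k2(a))

    alpha = brentq(f, -(ratio + 3.0), 5.0, xtol=1e-12)
    sigma = sd / np.sqrt(_k2(alpha))
    mu = -alpha * sigma
    return float(mu), float(sigma), float(alpha)


def _tn_ppf(u: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Quantile function of the truncated parent at uniforms ``u``."""
    lo = ndtr(alpha)
    return mu + sigma * ndtri(lo + np.asarray(u) * (1.0 - lo))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class AnalyteSpec:
    """Group-wise summary parameters for one simulated analyte.

    ``lod_quantile`` is the fraction of the *control* distribution censored
    as below-LOD; the censoring threshold derived from it applies to both
    groups, so a shifted case distribution is censored at a different rate.
    """

    name: str
    control_mean: float
    control_sd: float
    ptsd_mean: float
    ptsd_sd: float
    lod_quantile: float = 0.01

    def __post_init__(self) -> None:
        if min(self.control_mean, self.control_sd, self.ptsd_mean, self.ptsd_sd) <= 0:
            raise ValueError(f"{self.name}: means and SDs must be > 0")
        if not (0 <= self.lod_quantile < 1):
            raise ValueError(f"{self.name}: lod_quantile must be in [0, 1)")

    @property
    def is_null(self) -> bool:
        return (
            self.control_mean == self.ptsd_mean and self.control_sd == self.ptsd_sd
        )


@dataclass
class CohortSpec:
    """Full generating model for one cohort (control + case arms)."""

    cohort: str
    n_control: int
    n_ptsd: int
    analytes: list[AnalyteSpec]
    #: covariate -> (control_mean, control_sd, ptsd_mean, ptsd_sd)
    covariate_model: dict[str, tuple[float, float, float, float]]
    #: med class -> (P(control), P(ptsd))
    med_prevalence: dict[str, tuple[float, float]]
    mdd_prevalence: tuple[float, float] = (0.0, 0.5)
    smoker_prevalence: tuple[float, float] = (0.05, 0.2)
    #: (nonsmoker (mean, sd), smoker (mean, sd)) for plasma cotinine ng/mL
    cotinine_model: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 1.0),
        (250.0, 100.0),
    )
    caps_current_model: tuple[tuple[float, float], tuple[float, float]] = (
        (3.0, 4.0),
        (68.0, 17.0),
    )
    caps_lifetime_model: tuple[tuple[float, float], tuple[float, float]] = (
        (9.0, 8.0),
        (91.0, 15.0),
    )
    latent_loading: float = 0.0
    #: analyte name -> (covariate name, beta); value += beta * covariate
    leakage: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_ptsd < 2:
            raise ValueError("need >= 2 subjects per group")
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in spec")
        for cls, (pc, pp) in self.med_prevalence.items():
            if not (0 <= pc <= 1 and 0 <= pp <= 1):
                raise ValueError(f"{cls}: prevalences must be in [0, 1]")
        for probs in (self.mdd_prevalence, self.smoker_prevalence):
            if not all(0 <= p <= 1 for p in probs):
                raise ValueError("probabilities must be in [0, 1]")
        if not (0 <= self.latent_loading < 1):
            raise ValueError("latent_loading must be in [0, 1)")
        for analyte, (cov, _beta) in self.leakage.items():
            if analyte not in names:
                raise ValueError(f"leakage refers to unknown analyte {analyte!r}")
            if cov not in self.covariate_model and cov != "cotinine":
                raise ValueError(f"leakage refers to unknown covariate {cov!r}")


# (control_mean, control_sd, ptsd_mean, ptsd_sd) per analyte, published
# discovery-cohort summaries.
_DISCOVERY_ANALYTES: dict[str, tuple[float, float, float, float]] = {
    "glutamine": (1.050, 0.145, 0.978, 0.133),
    "trans-urocanate": (1.051, 0.539, 0.834, 0.427),
    "phenyllactate (PLA)": (0.781, 0.327, 1.033, 0.639),
    "arginine": (1.142, 0.297, 1.013, 0.374),
    "3-hydroxyisobutyrate": (1.094, 0.301, 0.987, 0.296),
    "5-oxoproline": (0.943, 0.149, 1.073, 0.187),
    "pyruvate": (1.056, 0.736, 1.272, 0.649),
    "lactate": (0.937, 0.283, 1.239, 0.341),
    "citrate": (1.071, 0.267, 0.948, 0.231),
    "linolenate [alpha or gamma; (18:3n3 or 6)]": (1.198, 0.533, 1.013, 0.577),
    "dihomo-linoleate (20:2n6)": (1.196, 0.598, 0.979, 0.510),
    "dihomo-linolenate (20:3n3 or n6)": (1.096, 0.407, 0.951, 0.393),
    "docosahexaenoate (DHA; 22:6n3)": (1.117, 0.568, 0.938, 0.501),
    "10-nonadecenoate (19:1n9)": (1.212, 0.525, 1.041, 0.631),
    "eicosenoate (20:1n9 or 11)": (1.282, 0.646, 1.028, 0.625),
    "sphingosine-1-phosphate": (0.947, 0.386, 1.122, 0.459),
    "octanoylcarnitine": (0.936, 0.406, 1.241, 0.690),
    "hexanoylcarnitine": (1.003, 0.288, 1.174, 0.439),
    "decanoylcarnitine": (0.970, 0.432, 1.272, 0.643),
    "cortisol": (0.912, 0.398, 1.085, 0.339),
    "hypoxanthine": (0.943, 0.384, 1.286, 0.687),
}

# published test-cohort summaries for the same panel
_TEST_ANALYTES: dict[str, tuple[float, float, float, float]] = {
    "glutamine": (1.050, 0.120, 1.020, 0.124),
    "trans-urocanate": (1.178, 0.508, 1.390, 2.329),
    "phenyllactate (PLA)": (1.007, 0.485, 1.100, 0.445),
    "arginine": (1.107, 0.244, 1.090, 0.197),
    "3-hydroxyisobutyrate": (1.021, 0.380, 1.130, 0.656),
    "5-oxoproline": (0.916, 0.137, 0.927, 0.134),
    "pyruvate": (1.409, 0.838, 2.177, 1.248),
    "lactate": (1.045, 0.316, 1.369, 0.494),
    "citrate": (1.066, 0.231, 1.048, 0.220),
    "linolenate [alpha or gamma; (18:3n3 or 6)]": (1.420, 0.647, 1.088, 0.501),
    "dihomo-linoleate (20:2n6)": (1.364, 0.583, 1.102, 0.459),
    "dihomo-linolenate (20:3n3 or n6)": (1.146, 0.383, 0.864, 0.364),
    "docosahexaenoate (DHA; 22:6n3)": (1.331, 0.839, 0.829, 0.299),
    "10-nonadecenoate (19:1n9)": (1.355, 0.534, 1.142, 0.457),
    "eicosenoate (20:1n9 or 11)": (1.647, 1.034, 1.135, 0.505),
    "sphingosine-1-phosphate": (1.137, 0.555, 1.274, 0.556),
    "octanoylcarnitine": (1.831, 2.794, 1.594, 1.439),
    "hexanoylcarnitine": (1.553, 1.245, 1.504, 0.905),
    "decanoylcarnitine": (1.988, 3.216, 1.687, 1.454),
    "cortisol": (1.239, 0.434, 1.224, 0.426),
    "hypoxanthine": (1.392, 0.784, 1.886, 0.857),
}

# synthetic support analytes: the source study prints only the composite
# arginine-bioavailability ratio, not its catabolite components, so these
# are chosen to land the composite near its published group means.
_SUPPORT_ANALYTES = {
    "discovery": {
        "ornithine": (0.99, 0.30, 1.06, 0.32),
        "citrulline": (0.99, 0.28, 1.07, 0.30),
    },
    "test": {
        "ornithine": (0.97, 0.25, 1.04, 0.26),
        "citrulline": (0.97, 0.24, 1.04, 0.25),
    },
}

N_NULL_ANALYTES = 20

_COVARIATE_MODEL = {
    "discovery": {
        "bmi": (28.24, 4.15, 30.03, 5.12),
        "hba1c": (5.48, 0.42, 5.35, 0.91),
        "glucose": (79.94, 13.76, 91.42, 23.57),
        "waist_hip": (0.89, 0.12, 0.91, 0.08),
    },
    "test": {
        "bmi": (28.78, 5.74, 30.00, 5.00),
        "hba1c": (5.18, 0.42, 5.52, 0.87),
        "glucose": (82.19, 9.19, 88.26, 25.99),
        "waist_hip": (0.87, 0.19, 0.86, 0.25),
    },
}

_MED_PREVALENCE = {
    "discovery": {
        "sedatives": (1 / 51, 6 / 52),
        "statins": (1 / 51, 2 / 52),
        "antidepressants": (2 / 51, 15 / 52),
        "anticonvulsants": (0.0, 3 / 52),
        "anti_inflammatories": (5 / 51, 4 / 52),
        "antidiabetics": (1 / 51, 1 / 52),
        "antibiotics": (1 / 51, 1 / 52),
        "beta_blockers": (1 / 51, 1 / 52),
    },
    "test": {
        "sedatives": (3 / 31, 4 / 31),
        "statins": (0.0, 2 / 31),
        "antidepressants": (2 / 31, 5 / 31),
        "anticonvulsants": (0.0, 2 / 31),
        "anti_inflammatories": (0.0, 1 / 31),
        "antidiabetics": (1 / 31, 1 / 31),
        "antibiotics": (0.0, 0.0),
        "beta_blockers": (0.0, 0.0),
    },
}

_CLINICAL = {
    "discovery": {
        "sizes": (51, 52),
        "mdd": (0.0, 27 / 52),
        "smoker": (3 / 51, 11 / 52),
        "caps_current": ((2.90, 4.24), (68.02, 16.80)),
        "caps_lifetime": ((8.65, 7.83), (90.87, 15.47)),
    },
    "test": {
        "sizes": (31, 31),
        "mdd": (0.0, 20 / 31),
        "smoker": (1 / 31, 0.0),  # zero smokers observed in the case arm
        "caps_current": ((5.23, 6.20), (71.77, 17.11)),
        "caps_lifetime": ((10.39, 9.46), (92.71, 16.54)),
    },
}


def default_spec(cohort: str = "discovery", lod_quantile: float = 0.01) -> CohortSpec:
    """Study-parameterized cohort spec (discovery 51/52, test 31/31).

    Includes every published analyte summary for the requested cohort,
    the two synthetic ratio-support analytes and 20 null analytes
    (identical group distributions, mean 1.0 SD 0.3) for calibration.
    """
    if cohort not in ("discovery", "test"):
        raise ValueError(f"unknown cohort {cohort!r}")
    table = _DISCOVERY_ANALYTES if cohort == "discovery" else _TEST_ANALYTES
    analytes = [
        AnalyteSpec(name, *params, lod_quantile=lod_quantile)
        for name, params in table.items()
    ]
    for name, params in _SUPPORT_ANALYTES[cohort].items():
        analytes.append(AnalyteSpec(name, *params, lod_quantile=lod_quantile))
    for i in range(1, N_NULL_ANALYTES + 1):
        analytes.append(
            AnalyteSpec(f"null_{i:02d}", 1.0, 0.3, 1.0, 0.3, lod_quantile=lod_quantile)
        )
    clin = _CLINICAL[cohort]
    return CohortSpec(
        cohort=cohort,
        n_control=clin["sizes"][0],
        n_ptsd=clin["sizes"][1],
        analytes=analytes,
        covariate_model=dict(_COVARIATE_MODEL[cohort]),
        med_prevalence=dict(_MED_PREVALENCE[cohort]),
        mdd_prevalence=clin["mdd"],
        smoker_prevalence=clin["smoker"],
        caps_current_model=clin["caps_current"],
        caps_lifetime_model=clin["caps_lifetime"],
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_group_truncnorm(
    u: np.ndarray, is_ptsd: np.ndarray, ctrl: tuple[float, float], ptsd: tuple[float, float]
) -> np.ndarray:
    pc = truncnorm_params(*ctrl)
    pp = truncnorm_params(*ptsd)
    return np.where(is_ptsd, _tn_ppf(u, *pp), _tn_ppf(u, *pc))


def generate(
    spec: CohortSpec, seed: int
) -> tuple[MetaboliteMatrix, list[SubjectRecord]]:
    """Draw one cohort; identical ``(spec, seed)`` gives bit-identical output."""
    n = spec.n_control + spec.n_ptsd
    rng = np.random.default_rng(seed)
    is_ptsd = np.zeros(n, dtype=bool)
    is_ptsd[spec.n_control:] = True
    prefix = "D" if spec.cohort == "discovery" else "T"
    subject_ids = [f"{prefix}{i:03d}" for i in range(1, n + 1)]

    m = len(spec.analytes)
    if spec.latent_loading > 0:
        factor = rng.standard_normal(n)
        eps = rng.standard_normal((n, m))
        rho = spec.latent_loading
        u = ndtr(rho * factor[:, None] + np.sqrt(1 - rho * rho) * eps)
    else:
        u = rng.random((n, m))

    values = np.empty((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for j, a in enumerate(spec.analytes):
        col = _draw_group_truncnorm(
            u[:, j], is_ptsd, (a.control_mean, a.control_sd), (a.ptsd_mean, a.ptsd_sd)
        )
        if a.lod_quantile > 0:
            thr = _tn_ppf(
                a.lod_quantile, *truncnorm_params(a.control_mean, a.control_sd)
            )
            mask[:, j] = col < thr
        values[:, j] = col

    # covariates (group-dependent means induce covariate-group confounding)
    cov: dict[str, np.ndarray] = {}
    for name in ("bmi", "hba1c", "glucose", "waist_hip"):
        cm = spec.covariate_model[name]
        cov[name] = _draw_group_truncnorm(rng.random(n), is_ptsd, cm[:2], cm[2:])
    smoker = np.where(
        is_ptsd,
        rng.random(n) < spec.smoker_prevalence[1],
        rng.random(n) < spec.smoker_prevalence[0],
    )
    (ns_mean, ns_sd), (s_mean, s_sd) = spec.cotinine_model
    cov["cotinine"] = _draw_group_truncnorm(
        rng.random(n), smoker, (ns_mean, ns_sd), (s_mean, s_sd)
    )

    med = {}
    for cls in MED_CLASSES:
        pc, pp = spec.med_prevalence.get(cls, (0.0, 0.0))
        med[cls] = np.where(is_ptsd, rng.random(n) < pp, rng.random(n) < pc)
    mdd = np.where(
        is_ptsd,
        rng.random(n) < spec.mdd_prevalence[1],
        rng.random(n) < spec.mdd_prevalence[0],
    )
    caps_cur = _draw_group_truncnorm(
        rng.random(n), is_ptsd, spec.caps_current_model[0], spec.caps_current_model[1]
    )
    caps_life = _draw_group_truncnorm(
        rng.random(n), is_ptsd, spec.caps_lifetime_model[0], spec.caps_lifetime_model[1]
    )

    # optional metabolite <- covariate leakage (after masking decision,
    # clipped at 0 to respect the non-negativity invariant)
    name_to_col = {a.name: j for j, a in enumerate(spec.analytes)}
    for analyte, (cov_name, beta) in spec.leakage.items():
        j = name_to_col[analyte]
        values[:, j] = np.maximum(values[:, j] + beta * cov[cov_name], 0.0)

    values[mask] = np.nan
    analyte_names = [a.name for a in spec.analytes]
    matrix = MetaboliteMatrix(
        pd.DataFrame(values, index=subject_ids, columns=analyte_names),
        pd.DataFrame(mask, index=subject_ids, columns=analyte_names),
    )
    records = [
        SubjectRecord(
            subject_id=subject_ids[i],
            cohort=spec.cohort,
            group=GROUP_PTSD if is_ptsd[i] else GROUP_CONTROL,
            covariates={c: float(cov[c][i]) for c in COVARIATES},
            med_flags={cls: bool(med[cls][i]) for cls in MED_CLASSES},
            mdd=bool(mdd[i]),
            caps_current=float(caps_cur[i]),
            caps_lifetime=float(caps_life[i]),
            smoker=bool(smoker[i]),
        )
        for i in range(n)
    ]
    return matrix, records


# ---------------------------------------------------------------------------
# YAML spec round-trip (CLI surface)
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    data = asdict(spec)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["analytes"] = [AnalyteSpec(**a) for a in data["analytes"]]
    data["covariate_model"] = {
        k: tuple(v) for k, v in data["covariate_model"].items()
    }
    data["med_prevalence"] = {k: tuple(v) for k, v in data["med_prevalence"].items()}
    for key in ("mdd_prevalence", "smoker_prevalence"):
        data[key] = tuple(data[key])
    data["cotinine_model"] = tuple(tuple(x) for x in data["cotinine_model"])
    for key in ("caps_current_model", "caps_lifetime_model"):
        data[key] = tuple(tuple(x) for x in data[key])
    data["leakage"] = {k: tuple(v) for k, v in (data.get("leakage") or {}).items()}
    return CohortSpec(**data)
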