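"""End-to-end orchestration: simulate or ingest -> preprocess -> group
statistics -> covariate/sensitivity batteries -> replication, under one
YAML-able config, with a JSON run manifest for reproducibility audits.

Outputs (CSV + JSON) per run:

    discovery_results.csv   per-analyte differential table, discovery cohort
    test_results.csv        same for the test cohort
    adjustments.csv         ANCOVA battery + exclusion sensitivity re-tests
    replication_report.csv  replication classes + validation success fractions
    manifest.json           config snapshot, seeds, versions, digests, counts

Reruns with an identical config produce byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import __version__
from .datamodel import (
    AnalysisConfig,
    MetaboliteMatrix,
    as_subject_frame,
    harmonize_panels,
    read_matrix,
    read_subjects,
    subjects_to_frame,
    write_matrix,
    write_subjects,
)
from .adjust import ancova_battery, sensitivity_exclusion
from .preprocess import DEFAULT_RATIOS, RatioDefinition, prepare_cohort
from .replication import classify_replication, validation_success_fraction
from .simulate import default_spec, generate
from .stats import differential_analysis

log = logging.getLogger("metabddx")

OUTPUT_FILES = (
    "discovery_results.csv",
    "test_results.csv",
    "adjustments.csv",
    "replication_report.csv",
    "manifest.json",
)

DEFAULT_PIPELINE_CONFIG: dict = {
    "simulate": True,
    "seed": 0,
    "alpha": 0.05,
    "trend_upper": 0.1,
    "n_bootstrap": 1000,
    "covariates": ["bmi", "hba1c", "glucose", "cotinine"],
    "exclusions": ["any_medication"],
    "ratios": None,  # None -> built-ins (glycolytic ratio, GABR)
    "inputs": None,  # or dict with discovery_matrix/discovery_subjects/...
    "lod_quantile": 0.01,
}


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = dict(DEFAULT_PIPELINE_CONFIG)
    config.update(user)
    return config


def _ratio_defs(config: dict) -> tuple[RatioDefinition, ...]:
    if config.get("ratios") is None:
        return DEFAULT_RATIOS
    return tuple(
        RatioDefinition(
            r["name"], tuple(r["numerator"]), tuple(r["denominator"])
        )
        for r in config["ratios"]
    )


def _analysis_config(config: dict) -> AnalysisConfig:
    return AnalysisConfig(
        alpha=config.get("alpha", 0.05),
        trend_upper=config.get("trend_upper", 0.1),
        rng_seed=config.get("seed", 0),
        n_bootstrap=config.get("n_bootstrap", 1000),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohorts(config: dict):
    if config.get("simulate", True):
        seed = int(config.get("seed", 0))
        lod = float(config.get("lod_quantile", 0.01))
        dm, dsub = generate(default_spec("discovery", lod_quantile=lod), seed)
        tm, tsub = generate(default_spec("test", lod_quantile=lod), seed + 1)
        return dm, subjects_to_frame(dsub), tm, subjects_to_frame(tsub), {}
    inputs = config.get("inputs") or {}
    needed = ("discovery_matrix", "discovery_subjects", "test_matrix", "test_subjects")
    missing = [k for k in needed if k not in inputs]
    if missing:
        raise PipelineError(f"ingest: missing input paths {missing}")
    digests = {k: _sha256(Path(v)) for k, v in inputs.items()}
    return (
        read_matrix(inputs["discovery_matrix"]),
        read_subjects(inputs["discovery_subjects"]),
        read_matrix(inputs["test_matrix"]),
        read_subjects(inputs["test_subjects"]),
        digests,
    )


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute every stage and write the five output files.

    Any stage failure raises :class:`PipelineError` naming the stage and
    offending entity; no partial outputs are left behind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = _analysis_config(config)
    ratio_defs = _ratio_defs(config)
    stage = "ingest"
    counts: dict = {}
    try:
        dmat, dsub, tmat, tsub, input_digests = _load_cohorts(config)
        counts["discovery"] = {"subjects": dmat.n_subjects, "analytes": dmat.n_analytes}
        counts["test"] = {"subjects": tmat.n_subjects, "analytes": tmat.n_analytes}

        stage = "harmonize"
        dmat, tmat, shared = harmonize_panels(dmat, tmat)
        counts["harmonized_panel"] = len(shared)
        log.info("harmonized panel: %d analytes", len(shared))

        stage = "preprocess"
        d_scaled, d_blom = prepare_cohort(dmat, ratio_defs)
        t_scaled, t_blom = prepare_cohort(tmat, ratio_defs)

        stage = "diffstats"
        d_res = differential_analysis(d_scaled, d_blom, dsub, acfg)
        t_res = differential_analysis(t_scaled, t_blom, tsub, acfg)

        stage = "adjustments"
        battery = ancova_battery(d_blom, dsub, covariates=config["covariates"])
        adj_rows = battery.reset_index().melt(
            id_vars="analyte", var_name="label", value_name="group_p"
        )
        adj_rows.insert(1, "analysis", "ancova")
        for excl in config.get("exclusions") or []:
            sens = sensitivity_exclusion(dmat, dsub, excl, acfg, ratio_defs)
            block = sens[["analyte", "p_value"]].rename(columns={"p_value": "group_p"})
            block.insert(1, "analysis", "exclusion")
            block.insert(2, "label", excl)
            adj_rows = pd.concat([adj_rows, block], ignore_index=True)

        stage = "replication"
        report = classify_replication(d_res, t_res, acfg)
        pooled_vals = pd.concat([dmat.values, tmat.values])
        pooled_mask = pd.concat([dmat.mask, tmat.mask])
        pooled = MetaboliteMatrix(pooled_vals, pooled_mask)
        pooled_sub = pd.concat([as_subject_frame(dsub), as_subject_frame(tsub)])
        n_ctrl_d = int((as_subject_frame(dsub)["group"] != "ptsd_pos").sum())
        n_ptsd_d = dmat.n_subjects - n_ctrl_d
        n_ctrl_t = int((as_subject_frame(tsub)["group"] != "ptsd_pos").sum())
        n_ptsd_t = tmat.n_subjects - n_ctrl_t
        fractions = validation_success_fraction(
            pooled,
            pooled_sub,
            (n_ctrl_d, n_ptsd_d),
            (n_ctrl_t, n_ptsd_t),
            acfg,
            ratio_defs,
        )
        report.success_fraction = fractions.loc[
            [a for a in report.discovery_significant if a in fractions.index]
        ]
        report.n_permutations = acfg.n_bootstrap
        rep_frame = report.to_frame()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- write outputs atomically-ish: collect, then emit, cleanup on error
    written: list[Path] = []
    try:
        float_fmt = "%.12g"
        for name, frame in (
            ("discovery_results.csv", d_res),
            ("test_results.csv", t_res),
            ("adjustments.csv", adj_rows),
            ("replication_report.csv", rep_frame),
        ):
            path = out / name
            frame.to_csv(path, index=False, float_format=float_fmt)
            written.append(path)
        manifest = {
            "config": {k: v for k, v in sorted(config.items())},
            "seed": config.get("seed", 0),
            "versions": {
                "metabddx": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "counts": counts,
            "input_digests": input_digests,
            "output_digests": {p.name: _sha256(p) for p in written},
            "n_permutations": acfg.n_bootstrap,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(out / "manifest.json")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"write: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_summary_table(results: pd.DataFrame, layout: str = "table2") -> pd.DataFrame:
    """Format a results frame the way the study's summary tables print.

    ``table2``: per-analyte means/SDs (3 dp), fold change (3 dp), p
    (3 dp, "<0.001" below), Cohen's d and q (3 dp), plus any ANCOVA
    columns present.  ``table1``: demographics layout (group means +/- SD,
    statistic, p).  Formatting is locale-independent (always ".").
    """
    if layout == "table2":
        cols = {
            "analyte": results.get("analyte", results.index),
            "control_mean": results["mean_control"].map("{:.3f}".format),
            "control_sd": results["sd_control"].map("{:.3f}".format),
            "ptsd_mean": results["mean_ptsd"].map("{:.3f}".format),
            "ptsd_sd": results["sd_ptsd"].map("{:.3f}".format),
            "ptsd_over_control": results["fold_change"].map("{:.3f}".format),
            "p_value": results["p_value"].map(_fmt_p),
            "cohens_d": results["cohens_d"].map("{:.3f}".format),
            "q_value": results["q_value"].map("{:.3f}".format),
        }
        out = pd.DataFrame(cols).reset_index(drop=True)
        extra = [c for c in results.columns if c.startswith("ancova_")]
        for c in extra:
            out[c] = results[c].map(_fmt_p).to_numpy()
        return out
    if layout == "table1":
        rows = []
        for _, r in results.iterrows():
            if r.get("kind") == "dichotomous":
                control = f"{int(r['mean_control'])}"
                ptsd = f"{int(r['mean_ptsd'])}"
            else:
                control = f"{r['mean_control']:.2f} ± {r['sd_control']:.2f}"
                ptsd = f"{r['mean_ptsd']:.2f} ± {r['sd_ptsd']:.2f}"
            rows.append(
                {
                    "variable": r["variable"],
                    "control": control,
                    "ptsd": ptsd,
                    "statistic": "" if not np.isfinite(r["statistic"]) else f"{r['statistic']:.2f}",
                    "p_value": _fmt_p(r["p_value"]),
                }
            )
        return pd.DataFrame(rows, columns=["variable", "control", "ptsd", "statistic", "p_value"])
    raise ValueError(f"unknown layout {layout!r}")


def simulate_to_dir(spec, seed: int, out_dir: str | Path) -> Path:
    """Write one simulated cohort as matrix.csv + subjects.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, records = generate(spec, seed)
    write_matrix(matrix, out / "matrix.csv")
    write_subjects(subjects_to_frame(records), out / "subjects.csv")
    return out
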