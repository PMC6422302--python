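"""Shared fixtures: small hand-built matrices and session-scoped
simulation batteries reused by the calibration/property tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import metabddx as m
from metabddx.datamodel import GROUP_PTSD, MetaboliteMatrix, subjects_to_frame


@pytest.fixture
def tiny_matrix() -> MetaboliteMatrix:
    values = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0], "b": [np.nan, 2.0, 3.0]},
        index=["s1", "s2", "s3"],
    )
    return MetaboliteMatrix(values)


@pytest.fixture
def default_cohort():
    """One generated discovery cohort plus its subject frame."""
    matrix, records = m.generate(m.default_spec(), seed=7)
    return matrix, subjects_to_frame(records)


def _configured_direction(spec):
    """Expected case-vs-control sign per analyte/built-in ratio."""
    direction = {
        a.name: np.sign(a.ptsd_mean - a.control_mean) for a in spec.analytes
    }
    direction["GLYCOLYTIC_RATIO"] = 1.0  # pyruvate+lactate up, citrate down
    direction["GABR"] = -1.0  # arginine down, catabolites up
    return direction


@pytest.fixture(scope="session")
def discovery_battery():
    """Differential tables for 200 seeded discovery cohorts (default spec).

    Returns ``(spec, frame)`` with one row per analyte x seed carrying
    p-values, fold changes and observed effect directions.
    """
    spec = m.default_spec()
    rows = []
    for seed in range(200):
        matrix, records = m.generate(spec, seed)
        scaled, blom = m.prepare_cohort(matrix)
        res = m.differential_analysis(scaled, blom, subjects_to_frame(records))
        rows.append(
            res[["analyte", "fold_change", "p_value", "mean_control", "mean_ptsd"]]
            .assign(seed=seed)
        )
    frame = pd.concat(rows, ignore_index=True)
    frame["direction"] = np.sign(frame["mean_ptsd"] - frame["mean_control"])
    return spec, frame


@pytest.fixture(scope="session")
def expected_directions(discovery_battery):
    spec, _ = discovery_battery
    return _configured_direction(spec)


@pytest.fixture(scope="session")
def replication_battery():
    """Replication classifications over 200 seeded discovery/test pairs."""
    counts: dict[str, int] = {}
    n_pairs = 200
    for seed in range(n_pairs):
        dmat, dsub = m.generate(m.default_spec("discovery"), seed)
        tmat, tsub = m.generate(m.default_spec("test"), 100_000 + seed)
        d_scaled, d_blom = m.prepare_cohort(dmat)
        t_scaled, t_blom = m.prepare_cohort(tmat)
        d_res = m.differential_analysis(d_scaled, d_blom, subjects_to_frame(dsub))
        t_res = m.differential_analysis(t_scaled, t_blom, subjects_to_frame(tsub))
        report = m.classify_replication(d_res, t_res)
        for name in report.replicated:
            counts[name] = counts.get(name, 0) + 1
    return counts, n_pairs
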