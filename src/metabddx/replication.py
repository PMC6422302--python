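"""Discovery -> test replication classification and the resampling-based
validation success fraction.

``classify_replication`` labels every discovery-significant analyte by its
test-cohort status: *replicated* (test p <= alpha, same effect direction),
*trend_replicated* (test p in (alpha, 0.1], same direction) or *failed*.

``validation_success_fraction`` pools both cohorts and repeatedly re-splits
the subjects -- stratified by case/control status, without replacement --
into a pseudo-discovery and a pseudo-test cohort of the original sizes.
The full preprocessing + t-test chain (minimum imputation, median scaling,
composite ratios, Blom transform, pooled t) is rerun inside each pseudo
cohort, and an analyte succeeds in one re-split iff it is significant with
a consistent direction in both halves.  The per-analyte success fraction
over the re-splits summarises how robustly a finding survives the
two-cohort design.  A with-replacement bootstrap variant sits behind
``with_replacement=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri

from .datamodel import (
    GROUP_PTSD,
    AnalysisConfig,
    MetaboliteMatrix,
    as_subject_frame,
)
from .preprocess import DEFAULT_RATIOS, RatioDefinition

__all__ = [
    "ReplicationReport",
    "classify_replication",
    "validation_success_fraction",
    "plot_validation_fractions",
]


@dataclass
class ReplicationReport:
    """Discovery-significant panel partitioned by test-cohort outcome."""

    discovery_significant: list[str]
    replicated: list[str]
    trend_replicated: list[str]
    failed: list[str]
    success_fraction: pd.Series | None = None
    n_permutations: int = 0
    rng_seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        status = {}
        for name in self.replicated:
            status[name] = "replicated"
        for name in self.trend_replicated:
            status[name] = "trend_replicated"
        for name in self.failed:
            status[name] = "failed"
        rows = [
            {"analyte": a, "status": status[a]} for a in self.discovery_significant
        ]
        frame = pd.DataFrame(rows, columns=["analyte", "status"])
        if self.success_fraction is not None:
            frame = frame.set_index("analyte")
            frame["success_fraction"] = self.success_fraction
            frame = frame.reset_index()
        return frame


def classify_replication(
    discovery_results: pd.DataFrame,
    test_results: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> ReplicationReport:
    """Partition discovery findings by their test-cohort status.

    Both result tables must cover the identical (harmonized) analyte panel;
    effect direction is the sign of (mean_ptsd - mean_control).
    """
    config = config or AnalysisConfig()
    disc = discovery_results.set_index("analyte") if "analyte" in discovery_results.columns else discovery_results
    test = test_results.set_index("analyte") if "analyte" in test_results.columns else test_results
    only = set(disc.index) ^ set(test.index)
    if only:
        raise ValueError(
            f"analytes present in one result set only: {sorted(only)}"
        )
    sig = disc.loc[disc["p_value"] <= config.alpha]
    replicated, trend, failed = [], [], []
    for name, row in sig.iterrows():
        d_dir = np.sign(row["mean_ptsd"] - row["mean_control"])
        trow = test.loc[name]
        t_dir = np.sign(trow["mean_ptsd"] - trow["mean_control"])
        same = d_dir == t_dir and d_dir != 0
        if same and trow["p_value"] <= config.alpha:
            replicated.append(name)
        elif same and trow["p_value"] <= config.trend_upper:
            trend.append(name)
        else:
            failed.append(name)
    return ReplicationReport(
        discovery_significant=list(sig.index),
        replicated=replicated,
        trend_replicated=trend,
        failed=failed,
        rng_seed=config.rng_seed,
    )


# ---------------------------------------------------------------------------
# resampling machinery
# ---------------------------------------------------------------------------

def _resolve_ratio_terms(
    columns: Sequence[str], ratio_defs: Sequence[RatioDefinition] | None
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    terms = []
    pos = {name: j for j, name in enumerate(columns)}
    for rd in ratio_defs or ():
        missing = [a for a in (*rd.numerator, *rd.denominator) if a not in pos]
        if missing:
            raise KeyError(f"ratio {rd.name}: analyte(s) not in matrix: {missing}")
        terms.append(
            (
                rd.name,
                np.array([pos[a] for a in rd.numerator]),
                np.array([pos[a] for a in rd.denominator]),
            )
        )
    return terms


def _chain_tests(
    values: np.ndarray,
    mask: np.ndarray,
    is_ptsd: np.ndarray,
    ratio_terms: list[tuple[str, np.ndarray, np.ndarray]],
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized impute -> scale -> ratios -> Blom -> pooled t.

    Same arithmetic as the public chain (verified by test); returns
    ``(p_values, directions)`` over analytes then ratio columns.
    """
    masked = np.where(mask, np.nan, values)
    if np.isnan(masked).all(axis=0).any():
        raise ValueError("analyte with all cells below LOD in a pseudo-cohort")
    with np.errstate(all="ignore"):
        col_min = np.nanmin(masked, axis=0)
    v = np.where(mask, col_min, values)
    med = np.median(v, axis=0)
    if np.any(med == 0):
        raise ValueError("zero analyte median in a pseudo-cohort")
    v = v / med
    extra = [
        v[:, num].sum(axis=1) / v[:, den].sum(axis=1) for _, num, den in ratio_terms
    ]
    if extra:
        v = np.column_stack([v, *extra])
    n = v.shape[0]
    ranks = sps.rankdata(v, method="average", axis=0)
    z = ndtri((ranks - 0.375) / (n + 0.25))
    res = sps.ttest_ind(z[is_ptsd], z[~is_ptsd], axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    direction = np.sign(v[is_ptsd].mean(axis=0) - v[~is_ptsd].mean(axis=0))
    return p, direction


def validation_success_fraction(
    matrix: MetaboliteMatrix,
    subjects,
    discovery_sizes: tuple[int, int],
    test_sizes: tuple[int, int],
    config: AnalysisConfig | None = None,
    ratio_defs: Sequence[RatioDefinition] | None = DEFAULT_RATIOS,
    with_replacement: bool = False,
) -> pd.Series:
    """Per-analyte fraction of re-splits significant in both pseudo-cohorts.

    ``discovery_sizes`` / ``test_sizes`` are ``(n_control, n_ptsd)`` of the
    original cohorts; without replacement they must tile the pooled counts
    exactly.  Deterministic under ``config.rng_seed``.
    """
    config = config or AnalysisConfig()
    frame = as_subject_frame(subjects).loc[list(matrix.subject_ids)]
    is_ptsd_all = (frame["group"] == GROUP_PTSD).to_numpy()
    ctrl_idx = np.where(~is_ptsd_all)[0]
    ptsd_idx = np.where(is_ptsd_all)[0]
    dc, dp = discovery_sizes
    tc, tp = test_sizes
    if min(dc, dp, tc, tp) < 2:
        raise ValueError("each pseudo-cohort cell needs >= 2 subjects")
    if not with_replacement and (
        dc + tc != ctrl_idx.size or dp + tp != ptsd_idx.size
    ):
        raise ValueError(
            f"cohort sizes infeasible: pooled controls={ctrl_idx.size}, "
            f"cases={ptsd_idx.size}, requested {(dc, tc)} / {(dp, tp)}"
        )

    values = matrix.values.to_numpy()
    mask = matrix.mask.to_numpy()
    ratio_terms = _resolve_ratio_terms(matrix.analyte_names, ratio_defs)
    names = matrix.analyte_names + [t[0] for t in ratio_terms]
    d_flags = np.zeros(dc + dp, dtype=bool)
    d_flags[dc:] = True
    t_flags = np.zeros(tc + tp, dtype=bool)
    t_flags[tc:] = True

    rng = np.random.default_rng(config.rng_seed)
    successes = np.zeros(len(names))
    for _ in range(config.n_bootstrap):
        if with_replacement:
            d_ctrl = rng.choice(ctrl_idx, size=dc, replace=True)
            d_ptsd = rng.choice(ptsd_idx, size=dp, replace=True)
            t_ctrl = rng.choice(ctrl_idx, size=tc, replace=True)
            t_ptsd = rng.choice(ptsd_idx, size=tp, replace=True)
        else:
            perm_c = rng.permutation(ctrl_idx)
            perm_p = rng.permutation(ptsd_idx)
            d_ctrl, t_ctrl = perm_c[:dc], perm_c[dc:]
            d_ptsd, t_ptsd = perm_p[:dp], perm_p[dp:]
        d_rows = np.concatenate([d_ctrl, d_ptsd])
        t_rows = np.concatenate([t_ctrl, t_ptsd])
        pd_, dird = _chain_tests(
            values[d_rows], mask[d_rows], d_flags, ratio_terms, config.welch
        )
        pt_, dirt = _chain_tests(
            values[t_rows], mask[t_rows], t_flags, ratio_terms, config.welch
        )
        ok = (
            (pd_ <= config.alpha)
            & (pt_ <= config.alpha)
            & (dird == dirt)
            & (dird != 0)
        )
        successes += ok
    return pd.Series(successes / config.n_bootstrap, index=names, name="success_fraction")


def plot_validation_fractions(fractions: pd.Series, path) -> None:
    """Bar plot of per-analyte validation success fractions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(fractions)), 4))
    fractions.sort_values(ascending=False).plot.bar(ax=ax, color="#3b6ea5")
    ax.set_ylabel("validation success fraction")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
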