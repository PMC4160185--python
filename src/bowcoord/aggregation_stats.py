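"""Two-step aggregation to per-participant/condition summaries.

Statistics are first computed per transition (two transitions for the
circular patterns, four for Fo8) and then averaged, unweighted, across
transitions — never pooled across transitions.  The module also provides
the estimator-comparison statistics (Pearson r and OLS slope) and a tidy
long-format export for external inferential tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transition_features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class ConditionSummary:
    """Per participant-and-condition feature means and SDs."""

    participant: str | None
    condition: dict
    means: dict[str, float]
    sds: dict[str, float]
    n_events: int
    n_transitions: int
    excluded_transitions: int = 0
    missing_counts: dict[str, int] = field(default_factory=dict)

    def coefficient_of_variation(self, feature: str) -> float:
        mean = self.means[feature]
        if not np.isfinite(mean) or mean == 0:
            raise ValueError(f"CV undefined for feature {feature!r} (zero mean)")
        return self.sds[feature] / abs(mean)


def summarize_condition(
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    transition_col: str = "transition_id",
) -> ConditionSummary:
    """Two-step aggregation of one participant-condition feature table.

    Per-transition means and SDs first, then an unweighted average across
    transitions.  Transitions with no valid events for a feature are
    excluded from that feature's average, with counts logged.
    """
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    if transition_col not in features.columns:
        raise ValueError(f"features table lacks a {transition_col!r} column")
    groups = features.groupby(transition_col, sort=True)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    missing: dict[str, int] = {}
    excluded = 0
    for col in feature_cols:
        per_mean = groups[col].mean()
        per_sd = groups[col].std(ddof=1)
        valid = per_mean.notna()
        n_excl = int((~valid).sum())
        if n_excl:
            logger.info(
                "feature %s: excluded %d transition(s) with no valid events",
                col, n_excl,
            )
            excluded = max(excluded, n_excl)
        means[col] = float(per_mean[valid].mean()) if valid.any() else np.nan
        sds[col] = float(per_sd[valid].mean()) if valid.any() else np.nan
        missing[col] = int(features[col].isna().sum())

    condition = {
        key: features[key].iloc[0]
        for key in ("pattern", "tempo_bpm", "dynamic_level", "string_combination",
                    "condition")
        if key in features.columns
    }
    participant = (
        str(features["participant"].iloc[0]) if "participant" in features.columns
        else None
    )
    return ConditionSummary(
        participant=participant,
        condition=condition,
        means=means,
        sds=sds,
        n_events=len(features),
        n_transitions=int(features[transition_col].nunique()),
        excluded_transitions=excluded,
        missing_counts=missing,
    )


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Wide table mirroring the deposited per-participant/condition layout.

    One row per summary; per-feature ``<feature>_mean`` and ``<feature>_sd``
    columns plus participant, condition descriptors and event counts.
    """
    rows = []
    for s in summaries:
        row: dict = {"participant": s.participant}
        row.update(s.condition)
        for feat, val in s.means.items():
            row[f"{feat}_mean"] = val
        for feat, val in s.sds.items():
            row[f"{feat}_sd"] = val
        row["n_events"] = s.n_events
        row["n_transitions"] = s.n_transitions
        rows.append(row)
    return pd.DataFrame(rows)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample SD divided by the absolute mean."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(vals.std(ddof=1) / abs(mean))


def compare_estimators(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson correlation and OLS slope of y on x (alternative vs regular).

    Pairs with a missing value in either input are excluded pairwise; the
    number of pairs used is logged and returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("compare_estimators: dropped %d incomplete pair(s)", n_dropped)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    r, _ = stats.pearsonr(x, y)
    slope, _ = np.polyfit(x, y, 1)
    return {"pearson_r": float(r), "slope": float(slope), "n": int(x.size)}


def export_tidy(summaries_frame: pd.DataFrame) -> pd.DataFrame:
    """Long format: one row per participant x condition x feature x statistic."""
    if summaries_frame.empty:
        raise ValueError("no summaries to export")
    stat_cols = [
        c for c in summaries_frame.columns if c.endswith(("_mean", "_sd"))
    ]
    id_cols = [c for c in summaries_frame.columns if c not in stat_cols]
    long = summaries_frame.melt(
        id_vars=id_cols, value_vars=stat_cols, var_name="feature_stat",
        value_name="value",
    )
    split = long["feature_stat"].str.rsplit("_", n=1, expand=True)
    long["feature"] = split[0]
    long["statistic"] = split[1]
    return long.drop(columns="feature_stat")
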