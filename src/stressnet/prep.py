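"""Preparation of scored cohort tables for the two network analyses.

First analysis: impute, accumulate and log-scale life-event scores,
median-split everything into Low/High, and lay the result out as a
two-time-slice table (one row per consecutive pair of completed time
points, slice variables suffixed ``_1``/``_2``).

Second analysis: impute, take within-participant change scores between
consecutive time points, standardise them, and attach a study-level
any-injury outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from stressnet.cohort import TIME_POINTS

#: Time-varying continuous measures carried into the two-slice layout.
SLICE_VARS = ("nle", "bis", "fffs", "ri", "stiffness", "hrv", "balance")
#: Explanatory (time-stable) variables of the two-slice layout.
EXPLANATORY = ("gender", "sport_type", "comp_level", "prev_injury", "training_hours", "baseline_nle")
#: Continuous measures differenced for the change-score layout.
CHANGE_VARS = ("nle", "bis", "fffs", "ri", "stiffness", "hrv", "balance")

LOW, HIGH = "Low", "High"


@dataclass(frozen=True)
class DiscretizationMap:
    """A median-split rule for one variable: boundary, labels, span."""

    variable: str
    boundary: float
    vmin: float
    vmax: float
    labels: tuple[str, str] = (LOW, HIGH)

    def __post_init__(self):
        if not self.vmin <= self.boundary <= self.vmax:
            raise ValueError("boundary must lie within [vmin, vmax]")
        if len(self.labels) != 2:
            raise ValueError("exactly two labels required")

    def apply(self, values) -> pd.Series:
        arr = np.asarray(values, dtype=float)
        out = np.where(arr <= self.boundary, self.labels[0], self.labels[1])
        index = values.index if isinstance(values, (pd.Series, pd.DataFrame)) else None
        out = pd.Series(out, index=index, dtype="object")
        out[np.isnan(arr)] = None
        return out

    def span_text(self) -> str:
        fmt = lambda v: f"{v:,.6g}"
        return (
            f"{fmt(self.vmin)}–{fmt(self.boundary)} ({self.labels[0]})  "
            f">{fmt(self.boundary)}–{fmt(self.vmax)} ({self.labels[1]})"
        )

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "boundary": self.boundary,
            "min": self.vmin,
            "max": self.vmax,
            "labels": list(self.labels),
            "span": self.span_text(),
        }


def save_maps(maps: dict[str, DiscretizationMap], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in maps.items()}, fh, indent=2)


def load_maps(path) -> dict[str, DiscretizationMap]:
    with open(path) as fh:
        raw = json.load(fh)
    return {
        k: DiscretizationMap(
            variable=v["variable"],
            boundary=v["boundary"],
            vmin=v["min"],
            vmax=v["max"],
            labels=tuple(v["labels"]),
        )
        for k, v in raw.items()
    }


# ---------------------------------------------------------------------------
# Atomic operations
# ---------------------------------------------------------------------------

def impute_bagged_trees(
    table: pd.DataFrame,
    n_trees: int = 25,
    seed: int = 0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Fill missing numeric entries with bagged-regression-tree predictions.

    For each numeric column with gaps, an ensemble of ``n_trees``
    bootstrap-resampled, unpruned regression trees is trained on the
    rows where the column is observed (all other columns as predictors,
    categoricals one-hot encoded, remaining predictor gaps median
    filled) and used to predict the gaps.  Observed entries are never
    changed; results are deterministic given ``seed``.
    """
    out = table.copy()
    numeric = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    targets = columns if columns is not None else [c for c in numeric if out[c].isna().any()]
    if not targets:
        return out
    for col in targets:
        if out[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")

    predictors_num = out[numeric].copy()
    predictors_num = predictors_num.fillna(predictors_num.median(numeric_only=True))
    cat_cols = [c for c in out.columns if c not in numeric]
    dummies = pd.get_dummies(out[cat_cols].astype("object"), dummy_na=True) if cat_cols else None

    for k, col in enumerate(sorted(targets)):
        mask = table[col].isna()
        if not mask.any():
            continue
        feats = predictors_num.drop(columns=[col])
        if dummies is not None and len(dummies.columns):
            feats = pd.concat([feats, dummies], axis=1)
        model = BaggingRegressor(
            estimator=DecisionTreeRegressor(random_state=0),
            n_estimators=n_trees,
            bootstrap=True,
            random_state=seed + k,
        )
        model.fit(feats[~mask], table.loc[~mask, col])
        out.loc[mask, col] = model.predict(feats[mask])
    return out


def cumulative_life_events(scores) -> np.ndarray:
    """Running total of per-time-point life-event scores."""
    arr = np.asarray(scores, dtype=float)
    if np.any(arr < 0):
        raise ValueError("life-event scores must be non-negative")
    return np.cumsum(arr)


def log_scale(score) -> np.ndarray | float:
    """``ln(score + 1)``; maps the zero-heavy count scale toward normal."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise ValueError("score must be non-negative")
    out = np.log1p(arr)
    return float(out) if out.ndim == 0 else out


def median_split(values, variable: str = "x") -> tuple[pd.Series, DiscretizationMap]:
    """Binarise at the median: values at or below it are Low, above High."""
    arr = np.asarray(values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size < 2:
        raise ValueError("need at least two non-missing values")
    if np.all(obs == obs[0]):
        raise ValueError(f"degenerate split: all values of {variable!r} identical")
    m = float(np.median(obs))
    dmap = DiscretizationMap(variable=variable, boundary=m, vmin=float(obs.min()), vmax=float(obs.max()))
    return dmap.apply(values), dmap


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def _measure_rows(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["time"].isin(TIME_POINTS)].copy()


def transform_life_events(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add baseline, cumulative and log-cumulative life-event columns.

    ``baseline_nle`` is the untransformed T1 score repeated on every
    row of a participant; ``nle_cumlog``/``tle_cumlog`` are the
    log-scaled running totals over T1..T3.
    """
    out = cohort.copy()
    out["baseline_nle"] = np.nan
    out["nle_cumlog"] = np.nan
    out["tle_cumlog"] = np.nan
    mrows = out["time"].isin(TIME_POINTS)
    for pid, grp in out[mrows].groupby("participant"):
        grp = grp.sort_values("time")
        base = grp.loc[grp["time"] == "T1", "nle"]
        if len(base):
            out.loc[out["participant"] == pid, "baseline_nle"] = float(base.iloc[0])
        out.loc[grp.index, "nle_cumlog"] = log_scale(cumulative_life_events(grp["nle"]))
        out.loc[grp.index, "tle_cumlog"] = log_scale(cumulative_life_events(grp["tle"]))
    return out


def discretise_first(
    cohort: pd.DataFrame,
    *,
    retained_only: bool = True,
) -> tuple[pd.DataFrame, dict[str, DiscretizationMap]]:
    """Median-split the transformed cohort for the two-slice analysis.

    Life-event medians are taken per time point (their distribution
    shifts as the totals accumulate); other measures are pooled across
    time points; explanatory variables are split across participants.
    ``retained_only`` restricts median computation to participants with
    more than one time point.
    """
    out = cohort.copy()
    maps: dict[str, DiscretizationMap] = {}
    mrows = out["time"].isin(TIME_POINTS)
    if retained_only:
        counts = out[mrows].groupby("participant")["time"].size()
        retained = set(counts[counts > 1].index)
        basis = mrows & out["participant"].isin(retained)
    else:
        basis = mrows

    for col in ("nle_cumlog",):
        for t in TIME_POINTS:
            rows = basis & (out["time"] == t)
            labels, dmap = median_split(out.loc[rows, col], variable=f"{col}@{t}")
            trows = mrows & (out["time"] == t)
            maps[f"{col}@{t}"] = dmap
            out.loc[trows, f"{col}_level"] = dmap.apply(out.loc[trows, col])

    for col in ("bis", "fffs", "ri", "stiffness", "hrv", "balance"):
        labels, dmap = median_split(out.loc[basis, col], variable=col)
        maps[col] = dmap
        out.loc[mrows, f"{col}_level"] = dmap.apply(out.loc[mrows, col])

    for col in ("training_hours", "baseline_nle"):
        per_part = out.loc[basis].drop_duplicates("participant")
        _, dmap = median_split(per_part[col], variable=col)
        maps[col] = dmap
        out[f"{col}_level"] = dmap.apply(out[col])
    return out, maps


def build_2tbn_table(cohort_disc: pd.DataFrame) -> pd.DataFrame:
    """Lay out the discretised cohort as two-time-slice rows.

    A participant completing T1-T3 contributes the pairs (T1, T2) and
    (T2, T3); a participant with only T1 contributes nothing.  Slice
    variables take the ``_1``/``_2`` suffix; the outcome columns
    ``injured_1``/``injured_2`` hold the reports for the interval
    ending at the second slice and the following interval.
    """
    level_of = {"nle": "nle_cumlog_level"}
    for v in SLICE_VARS:
        level_of.setdefault(v, f"{v}_level")
    rows = []
    for pid, grp in cohort_disc.groupby("participant", sort=True):
        grp = grp.set_index("time")
        present = [t for t in TIME_POINTS if t in grp.index]
        reports = {t: grp.loc[t, "injured"] for t in ("T2", "T3", "T4") if t in grp.index}
        for a, b in zip(present[:-1], present[1:]):
            if TIME_POINTS.index(b) - TIME_POINTS.index(a) != 1:
                continue  # non-consecutive completion; no valid pair
            nxt = f"T{TIME_POINTS.index(b) + 2}"
            rec = {"participant": pid, "pair": f"{a}+{b}"}
            for col in EXPLANATORY:
                src = f"{col}_level" if f"{col}_level" in grp.columns else col
                rec[col] = grp.loc[a, src]
            for v in SLICE_VARS:
                rec[f"{v}_1"] = grp.loc[a, level_of[v]]
                rec[f"{v}_2"] = grp.loc[b, level_of[v]]
            rec["injured_1"] = reports.get(b)
            rec["injured_2"] = reports.get(nxt)
            rows.append(rec)
    cols = (
        ["participant", "pair", *EXPLANATORY]
        + [f"{v}_{s}" for v in SLICE_VARS for s in (1, 2)]
        + ["injured_1", "injured_2"]
    )
    table = pd.DataFrame(rows, columns=cols)
    # A pair is only usable when the report for its own interval exists;
    # the following-interval report (injured_2) may be missing for a
    # participant who stopped attending, and such rows are kept so the
    # caller can decide how to handle them.
    return table.dropna(subset=["injured_1"]).reset_index(drop=True)


def build_change_table(
    cohort: pd.DataFrame,
    *,
    change_vars: tuple[str, ...] = CHANGE_VARS,
) -> pd.DataFrame:
    """Standardised within-participant change scores plus any-injury flag.

    One row per consecutive time-point interval; deltas are pooled over
    intervals and standardised to mean 0, sd 1.  The outcome is
    ``injured`` if the participant reported an injury in any interval
    of the study.  Baseline life events are deliberately absent.
    """
    rows = []
    for pid, grp in cohort.groupby("participant", sort=True):
        grp_m = grp[grp["time"].isin(TIME_POINTS)].set_index("time")
        present = [t for t in TIME_POINTS if t in grp_m.index]
        if len(present) < 2:
            continue
        reports = grp.loc[grp["time"].isin(("T2", "T3", "T4")), "injured"].dropna()
        any_injury = "injured" if (reports == "injured").any() else "healthy"
        hours = grp_m["training_hours"].iloc[0]
        for a, b in zip(present[:-1], present[1:]):
            if TIME_POINTS.index(b) - TIME_POINTS.index(a) != 1:
                continue
            rec = {
                "participant": pid,
                "interval": f"{a}→{b}",
                "gender": grp_m.loc[a, "gender"],
                "sport_type": grp_m.loc[a, "sport_type"],
                "comp_level": grp_m.loc[a, "comp_level"],
                "prev_injury": grp_m.loc[a, "prev_injury"],
                "training_hours_raw": hours,
                "injured": any_injury,
            }
            for v in change_vars:
                rec[f"d_{v}"] = float(grp_m.loc[b, v]) - float(grp_m.loc[a, v])
            rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no participant contributed a change interval")
    _, hours_map = median_split(
        table.drop_duplicates("participant")["training_hours_raw"], variable="training_hours"
    )
    table["training_hours"] = hours_map.apply(table["training_hours_raw"])
    table = table.drop(columns=["training_hours_raw"])
    for v in change_vars:
        col = table[f"d_{v}"]
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"degenerate change column d_{v}: zero variance")
        table[f"d_{v}"] = (col - col.mean()) / sd
    return table.reset_index(drop=True)
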