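"""Sorter-by-study result tables: thresholded averages, counts, and imputation.

A :class:`StudyResultTable` holds one row per (sorter, recording, ground-truth
unit) with that unit's accuracy/precision/recall, its SNR, and event count,
plus a mask of (sorter, recording) cells where sorting failed or timed out.
Recordings group into studies and studies into study sets.

Aggregation semantics:

* ``average_metric`` — per study, the unweighted mean of the chosen per-unit
  metric over ground-truth units with SNR at or above the threshold (default
  8); the study-set value is the unweighted mean of its study means.  Missing
  recordings are filled by linear-regression imputation of per-recording mean
  accuracies (one model per sorter and study set, fit on the sorters with no
  missing data) unless imputation is disabled, in which case they are simply
  excluded.
* ``count_above`` — per study, the number of ground-truth units whose accuracy
  reaches the accuracy threshold (default 0.8), regardless of SNR.  Missing
  cells are never imputed here; they contribute zero and flag the cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AggregationParams",
    "StudyResultTable",
    "average_metric",
    "count_above",
    "impute_missing",
    "fit_accuracy_predictor",
    "PredictorFit",
]

logger = logging.getLogger(__name__)

UNIT_COLUMNS = [
    "sorter",
    "study_set",
    "study",
    "recording",
    "gt_unit",
    "accuracy",
    "precision",
    "recall",
    "snr",
    "num_events",
]


@dataclass(frozen=True)
class AggregationParams:
    snr_threshold: float = 8.0
    accuracy_threshold: float = 0.8
    metric: str = "accuracy"
    impute: bool = True

    def __post_init__(self):
        if self.snr_threshold < 0 or self.accuracy_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.metric not in ("accuracy", "precision", "recall"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class StudyResultTable:
    """Per-unit sorting results plus the failed-run mask."""

    units: pd.DataFrame
    missing: set = field(default_factory=set)  # {(sorter, recording)}

    def __post_init__(self):
        absent = set(UNIT_COLUMNS) - set(self.units.columns)
        if absent:
            raise ValueError(f"units table lacks columns {sorted(absent)}")
        for (sorter, rec) in self.missing:
            mask = (self.units["sorter"] == sorter) & (self.units["recording"] == rec)
            if mask.any():
                raise ValueError(
                    f"missing cell ({sorter}, {rec}) also carries unit rows"
                )
        bad = self.units[
            (self.units[["accuracy", "precision", "recall"]].lt(0).any(axis=1))
            | (self.units[["accuracy", "precision", "recall"]].gt(1).any(axis=1))
            | (self.units["snr"] < 0)
        ]
        if len(bad):
            raise ValueError("metrics outside [0,1] or negative snr in units table")

    @property
    def sorters(self) -> list:
        return sorted(self.units["sorter"].unique())

    def recording_map(self) -> pd.DataFrame:
        """Unique (study_set, study, recording) triples."""
        return self.units[["study_set", "study", "recording"]].drop_duplicates()


def _qualifying(table: StudyResultTable, params: AggregationParams) -> pd.DataFrame:
    return table.units[table.units["snr"] >= params.snr_threshold]


def _gt_unit_counts(units: pd.DataFrame) -> pd.Series:
    """Qualifying ground-truth units per recording (max over sorters)."""
    per = units.groupby(["recording", "sorter"])["gt_unit"].nunique()
    if len(per) == 0:
        return pd.Series(dtype=float)
    return per.groupby("recording").max()


def impute_missing(values: pd.DataFrame, missing_mask: pd.DataFrame) -> pd.DataFrame:
    """Fill missing per-recording means by OLS on the complete sorters.

    ``values`` is sorters x recordings; ``missing_mask`` marks cells to fill.
    For each incomplete sorter an ordinary least squares model with intercept
    is fit of its observed entries on the complete sorters' entries at the same
    recordings, and predictions (clipped to [0, 1]) fill its missing entries.
    Falls back to the sorter's observed mean when no complete sorter exists or
    the fit is under-determined.  Observed entries are never changed.
    """
    values = values.astype(float).copy()
    missing_mask = missing_mask.astype(bool)
    complete = [s for s in values.index if not missing_mask.loc[s].any()]
    for sorter in values.index:
        miss = missing_mask.loc[sorter]
        if not miss.any():
            continue
        observed_cols = values.columns[~miss]
        missing_cols = values.columns[miss]
        if len(observed_cols) == 0:
            logger.warning("sorter %s has no observed entries; left missing", sorter)
            continue
        y = values.loc[sorter, observed_cols].to_numpy()
        fallback = float(np.mean(y))
        if complete and len(observed_cols) >= len(complete) + 1:
            X = values.loc[complete, observed_cols].to_numpy().T
            X1 = np.column_stack([np.ones(len(X)), X])
            coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
            Xm = values.loc[complete, missing_cols].to_numpy().T
            pred = np.column_stack([np.ones(len(Xm)), Xm]) @ coef
        else:
            logger.info(
                "sorter %s: imputation under-determined "
                "(%d observed, %d complete sorters); using observed mean",
                sorter, len(observed_cols), len(complete),
            )
            pred = np.full(len(missing_cols), fallback)
        values.loc[sorter, missing_cols] = np.clip(pred, 0.0, 1.0)
    return values


def _imputed_recording_means(
    table: StudyResultTable, params: AggregationParams
) -> dict[tuple, float]:
    """Imputed per-recording mean accuracy for every missing (sorter, recording)."""
    if not table.missing:
        return {}
    qual = _qualifying(table, params)
    rec_map = table.recording_map()
    missing_recs = {r for (_, r) in table.missing}
    out: dict[tuple, float] = {}
    for study_set, grp in rec_map.groupby("study_set"):
        recs = sorted(grp["recording"].unique())
        sorters = table.sorters
        vals = pd.DataFrame(np.nan, index=sorters, columns=recs)
        mask = pd.DataFrame(False, index=sorters, columns=recs)
        sub = qual[qual["recording"].isin(recs)]
        means = sub.groupby(["sorter", "recording"])[params.metric].mean()
        for (s, r), v in means.items():
            vals.loc[s, r] = v
        for s, r in table.missing:
            if r in recs:
                mask.loc[s, r] = True
        # observed-but-empty cells (no qualifying units) get 0 so the design
        # matrix is dense; they do not enter any study average directly
        vals[vals.isna() & ~mask] = 0.0
        filled = impute_missing(vals, mask)
        for s, r in table.missing:
            if r in recs and not np.isnan(filled.loc[s, r]):
                out[(s, r)] = float(filled.loc[s, r])
    return out


def average_metric(
    table: StudyResultTable, params: AggregationParams = AggregationParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sorter x study and sorter x study-set unweighted metric means.

    Per study: mean of the chosen metric over qualifying units (SNR at or
    above threshold) of non-missing recordings; when imputation is on, each
    missing recording contributes its imputed per-recording mean, weighted by
    that recording's qualifying ground-truth unit count so units stay equally
    weighted.  Study-set values are unweighted means of study means.
    """
    qual = _qualifying(table, params)
    rec_map = table.recording_map()
    imputed = _imputed_recording_means(table, params) if params.impute else {}
    unit_counts = _gt_unit_counts(qual)
    sorters = table.sorters
    studies = rec_map[["study_set", "study"]].drop_duplicates()
    study_vals = pd.DataFrame(
        np.nan, index=sorters, columns=list(studies["study"])
    )
    for _, row in studies.iterrows():
        study = row["study"]
        recs = rec_map[rec_map["study"] == study]["recording"].unique()
        for s in sorters:
            obs = qual[
                (qual["sorter"] == s)
                & (qual["recording"].isin(recs))
                & (~qual["recording"].isin([r for (ss, r) in table.missing if ss == s]))
            ]
            total = obs[params.metric].sum()
            weight = float(len(obs))
            for r in recs:
                if (s, r) in imputed:
                    w = float(unit_counts.get(r, 0))
                    total += imputed[(s, r)] * w
                    weight += w
            study_vals.loc[s, study] = total / weight if weight > 0 else np.nan
    set_means = {}
    for study_set, grp in studies.groupby("study_set"):
        cols = list(grp["study"])
        set_means[study_set] = study_vals[cols].mean(axis=1)
    study_set_vals = pd.DataFrame(set_means)
    return study_vals, study_set_vals


def count_above(
    table: StudyResultTable, params: AggregationParams = AggregationParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Units at or above the accuracy threshold, per sorter and study.

    Returns the counts and a same-shaped boolean frame flagging cells with at
    least one failed (missing) recording — rendered as an asterisk downstream.
    Missing cells contribute zero; counts are never imputed.
    """
    rec_map = table.recording_map()
    sorters = table.sorters
    studies = rec_map["study"].unique()
    counts = pd.DataFrame(0, index=sorters, columns=studies)
    flags = pd.DataFrame(False, index=sorters, columns=studies)
    hits = table.units[table.units["accuracy"] >= params.accuracy_threshold]
    grouped = hits.groupby(["sorter", "study"]).size()
    for (s, st), n in grouped.items():
        counts.loc[s, st] = int(n)
    study_of = dict(zip(rec_map["recording"], rec_map["study"]))
    for s, r in table.missing:
        if r in study_of:
            flags.loc[s, study_of[r]] = True
    return counts, flags


@dataclass(frozen=True)
class PredictorFit:
    """OLS fit of accuracy on [SNR, firing rate, log ISI-vr]."""

    coefficients: dict[str, float]
    predictions: np.ndarray
    pearson_r: float
    dropped: tuple[str, ...] = ()


def fit_accuracy_predictor(units: pd.DataFrame) -> PredictorFit:
    """Regress per-unit accuracy on SNR, firing rate, and log ISI-vr.

    ``units`` needs columns snr, firing_rate, isi_violation_ratio, accuracy.
    Zero ISI-vr values are floored at half the smallest positive observed
    value before the log.  Collinear predictors are dropped (flagged in the
    result) rather than fit through a pseudo-inverse.
    """
    import statsmodels.api as sm

    if len(units) < 5:
        raise ValueError("need at least 5 units to fit the accuracy predictor")
    isi = units["isi_violation_ratio"].to_numpy(dtype=float)
    if np.any(isi < 0) or not np.any(isi > 0):
        raise ValueError("isi_violation_ratio must be non-negative with some positive")
    floor = 0.5 * isi[isi > 0].min()
    log_isi = np.log(np.maximum(isi, floor))
    design = pd.DataFrame(
        {
            "snr": units["snr"].to_numpy(dtype=float),
            "firing_rate": units["firing_rate"].to_numpy(dtype=float),
            "log_isi_vr": log_isi,
        }
    )
    dropped: list[str] = []
    while design.shape[1] > 1:
        X = np.column_stack([np.ones(len(design)), design.to_numpy()])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        # drop the last column whose removal restores full rank
        for col in reversed(design.columns.tolist()):
            trial = design.drop(columns=[col])
            Xt = np.column_stack([np.ones(len(trial)), trial.to_numpy()])
            if np.linalg.matrix_rank(Xt) == Xt.shape[1]:
                dropped.append(col)
                design = trial
                break
        else:
            dropped.append(design.columns[-1])
            design = design.iloc[:, :-1]
    if dropped:
        logger.warning("dropped collinear predictor(s): %s", dropped)
    y = units["accuracy"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(design.to_numpy())).fit()
    pred = model.predict(sm.add_constant(design.to_numpy()))
    names = ["intercept"] + design.columns.tolist()
    coefficients = dict(zip(names, model.params))
    if np.std(pred) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    return PredictorFit(
        coefficients=coefficients,
        predictions=pred,
        pearson_r=r,
        dropped=tuple(dropped),
    )
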