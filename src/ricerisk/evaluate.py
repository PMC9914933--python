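"""Risk-level assignment of forecast indicators and evaluation metrics.

A forecast (NIPI, THQ, TCR) triplet is normalised with the level space's
stored min-max parameters and assigned to the risk level whose cluster
center is nearest in Euclidean distance. Indicator forecasts are scored
with RMSE/MAE; level predictions with one-vs-rest precision, recall and F1
per level (reported in percent).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .grading import INDICATORS, RiskLevelSpace

__all__ = [
    "LevelPrediction",
    "assign_level",
    "assign_levels_frame",
    "regression_metrics",
    "classification_metrics",
    "EvaluationReport",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class LevelPrediction:
    """Nearest-center level for one province-week triplet."""

    province: str
    week_index: int
    level: str
    distances: Dict[str, float]


def assign_level(
    point: Sequence[float],
    space: RiskLevelSpace,
    province: str = "",
    week_index: int = 0,
) -> LevelPrediction:
    """Assign one raw (NIPI, THQ, TCR) point to the nearest level center.

    The point is normalised with the space's stored parameters first; ties
    are broken toward the lower level (argmin on the level-ordered centers).
    """
    z = space.normalization.transform(np.asarray(point, dtype=float))
    dists = np.linalg.norm(space.centers_normalized - z, axis=1)
    best = int(np.argmin(dists))  # first minimum -> lower level on ties
    return LevelPrediction(
        province=province,
        week_index=week_index,
        level=space.levels[best],
        distances={lv: float(d) for lv, d in zip(space.levels, dists)},
    )


def assign_levels_frame(points: pd.DataFrame, space: RiskLevelSpace) -> pd.DataFrame:
    """Vectorised nearest-center assignment for a ``nipi/thq/tcr`` frame."""
    z = space.normalization.transform(points[list(INDICATORS)].to_numpy(dtype=float))
    d = np.linalg.norm(z[:, None, :] - space.centers_normalized[None], axis=2)
    out = points.copy()
    out["level"] = [space.levels[i] for i in d.argmin(axis=1)]
    return out


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> Tuple[float, float]:
    """Root-mean-square error and mean absolute error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must have equal nonzero length")
    err = y - yhat
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def classification_metrics(
    true_levels: Sequence[str],
    predicted_levels: Sequence[str],
    levels: Sequence[str],
) -> Dict[str, Dict[str, float]]:
    """One-vs-rest precision/recall/F1 (in %) and TP/FP/FN counts per level.

    Zero-denominator ratios are reported as 0 with a warning (an empty
    class in a split is legitimate for rare high-risk levels).
    """
    t = np.asarray(true_levels)
    p = np.asarray(predicted_levels)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    known = set(levels)
    strays = (set(t) | set(p)) - known
    if strays:
        raise ValueError(f"labels outside the level set: {sorted(strays)}")
    out: Dict[str, Dict[str, float]] = {}
    for lv in levels:
        tp = int(np.sum((p == lv) & (t == lv)))
        fp = int(np.sum((p == lv) & (t != lv)))
        fn = int(np.sum((p != lv) & (t == lv)))
        if tp + fp == 0:
            warnings.warn(f"no predictions of level {lv!r}; precision set to 0")
            prec = 0.0
        else:
            prec = 100.0 * tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(f"no true samples of level {lv!r}; recall set to 0")
            rec = 0.0
        else:
            rec = 100.0 * tp / (tp + fn)
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        out[lv] = {
            "precision": prec, "recall": rec, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn,
        }
    return out


@dataclass
class EvaluationReport:
    """Indicator regression errors plus per-level classification metrics."""

    regression: Dict[str, Dict[str, float]]  # indicator -> {rmse, mae}
    classification: Dict[str, Dict[str, float]]  # level -> {precision, ...}
    n_points: int

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(
            {"regression": self.regression,
             "classification": self.classification,
             "n_points": self.n_points}, indent=2))

    def summary(self) -> str:
        lines = ["Indicator forecast errors"]
        for ind, m in self.regression.items():
            lines.append(f"  {ind:<6} RMSE {m['rmse']:.6g}   MAE {m['mae']:.6g}")
        lines.append("")
        lines.append(f"{'Level':<10}{'P%':>8}{'R%':>8}{'F1%':>8}{'TP':>6}{'FP':>6}{'FN':>6}")
        for lv, m in self.classification.items():
            lines.append(
                f"{lv:<10}{m['precision']:>8.2f}{m['recall']:>8.2f}"
                f"{m['f1']:>8.2f}{m['tp']:>6.0f}{m['fp']:>6.0f}{m['fn']:>6.0f}"
            )
        return "\n".join(lines)


def evaluate_pipeline(
    truth: pd.DataFrame,
    forecast: pd.DataFrame,
    space: RiskLevelSpace,
    true_levels: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Score a forecast against the true indicator series.

    Parameters
    ----------
    truth
        Indicator frame ``province, week, nipi, thq, tcr`` covering at
        least the forecast weeks.
    forecast
        Same columns over the forecast weeks.
    space
        Fitted :class:`RiskLevelSpace` used both to derive truth levels
        (nearest center on the true triplets, unless ``true_levels`` is
        supplied) and to assign levels to forecasts.
    true_levels
        Optional frame ``province, week, level`` of ground-truth labels
        (e.g. from the synthetic generator) overriding the derived ones.
    """
    merged = forecast.merge(
        truth, on=["province", "week"], suffixes=("_pred", "_true")
    )
    if merged.empty:
        raise ValueError("no overlapping province-weeks between truth and forecast")

    regression = {}
    for ind in INDICATORS:
        rmse, mae = regression_metrics(
            merged[f"{ind}_true"], merged[f"{ind}_pred"]
        )
        regression[ind] = {"rmse": rmse, "mae": mae}

    pred_pts = merged.rename(columns={f"{i}_pred": i for i in INDICATORS})
    pred_assigned = assign_levels_frame(pred_pts, space)["level"]
    if true_levels is not None:
        lv = merged.merge(true_levels, on=["province", "week"])["level"]
        true_assigned = lv.to_numpy()
    else:
        true_pts = merged.rename(columns={f"{i}_true": i for i in INDICATORS})
        true_assigned = assign_levels_frame(true_pts, space)["level"].to_numpy()

    classification = classification_metrics(
        true_assigned, pred_assigned.to_numpy(), space.levels
    )
    return EvaluationReport(regression, classification, len(merged))
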