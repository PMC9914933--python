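"""Risk grading of the 3-D indicator space by K-medoids clustering.

The (NIPI, THQ, TCR) points of all province-weeks are min-max normalised,
clustered with a randomised-swap K-medoids algorithm for each candidate
cluster count k, and the k with the largest mean silhouette is kept. The
chosen medoids are then ordered by Euclidean distance from the origin of
the normalised space, which yields the risk levels: points near the origin
have uniformly small indicators (low risk), points far from it large ones.

K-medoids is preferred over k-means here because surveillance data contain
isolated extreme province-weeks; medoids are dataset points and therefore
robust to such outliers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "NormalizationParams",
    "normalize",
    "kmedoids",
    "silhouette",
    "RiskLevelSpace",
    "RiskGradingModel",
    "RiskGradingResults",
    "grade_risk_space",
]

INDICATORS = ("nipi", "thq", "tcr")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-indicator observed minimum and maximum used for min-max scaling."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum <= self.minimum):
            raise ValueError("max must exceed min for every indicator")

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.minimum) / (
            self.maximum - self.minimum
        )

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * (self.maximum - self.minimum) + self.minimum


def normalize(
    points: np.ndarray, params: Optional[NormalizationParams] = None
) -> Tuple[np.ndarray, NormalizationParams]:
    """Min-max normalise ``(x - min)/(max - min)`` per coordinate.

    With ``params`` given the stored ranges are reused (transform mode);
    out-of-range values then fall outside [0, 1] and are deliberately not
    clipped. Without, ranges are fitted on ``points``.
    """
    points = np.asarray(points, dtype=float)
    if params is None:
        params = NormalizationParams(points.min(axis=0), points.max(axis=0))
    return params.transform(points), params


def _assign(dist_to_medoids: np.ndarray) -> np.ndarray:
    # ties broken toward the lowest medoid index (argmin is first-match)
    return dist_to_medoids.argmin(axis=1)


def kmedoids(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    patience_factor: int = 200,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Randomised-swap K-medoids with Euclidean cost.

    From random initial medoids, points are assigned to the nearest medoid;
    a random (medoid, non-medoid) swap is proposed and accepted iff the
    total cost Σ d(point, its medoid) strictly decreases. The search stops
    after ``patience_factor · k`` consecutive rejected proposals. The best
    of ``n_restarts`` independent starts is returned.

    Returns ``(medoid_indices, assignment, cost)``; deterministic for a
    fixed seed.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    dist = cdist(points, points)
    master = np.random.default_rng(seed)

    best: Tuple[float, np.ndarray] = (np.inf, np.empty(0, dtype=int))
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        medoids = rng.choice(n, size=k, replace=False)
        # incremental bookkeeping: nearest / second-nearest medoid per point
        d_sub = dist[:, medoids]
        nearest = d_sub.argmin(axis=1)
        d1 = d_sub[np.arange(n), nearest]
        if k > 1:
            d_sub2 = d_sub.copy()
            d_sub2[np.arange(n), nearest] = np.inf
            d2 = d_sub2.min(axis=1)
        else:
            d2 = np.full(n, np.inf)
        cost = d1.sum()
        patience = patience_factor * k
        rejected = 0
        while rejected < patience:
            x = rng.integers(k)  # medoid slot to swap out
            y = rng.integers(n)  # candidate replacement
            if y in medoids:
                rejected += 1
                continue
            dy = dist[:, y]
            # cost if medoid slot x is replaced by point y
            trial_cost = np.where(
                nearest == x, np.minimum(d2, dy), np.minimum(d1, dy)
            ).sum()
            if trial_cost < cost:
                medoids = medoids.copy()
                medoids[x] = y
                cost = trial_cost
                d_sub = dist[:, medoids]
                nearest = d_sub.argmin(axis=1)
                d1 = d_sub[np.arange(n), nearest]
                d_sub2 = d_sub.copy()
                d_sub2[np.arange(n), nearest] = np.inf
                d2 = d_sub2.min(axis=1)
                rejected = 0
            else:
                rejected += 1
        if cost < best[0]:
            best = (cost, np.sort(medoids))

    cost, medoids = best[0], best[1]
    assignment = _assign(dist[:, medoids])
    return medoids, assignment, float(cost)


def silhouette(points: np.ndarray, assignment: np.ndarray) -> float:
    """Mean silhouette coefficient ``(b - a)/max(a, b)`` over all points.

    ``a`` is the mean distance to the point's own cluster (excluding
    itself), ``b`` the smallest mean distance to any other cluster. Points
    in singleton clusters score 0.
    """
    points = np.asarray(points, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ValueError("silhouette requires at least two clusters")
    dist = cdist(points, points)
    scores = np.zeros(len(points))
    sizes = {lab: int((assignment == lab).sum()) for lab in labels}
    for i in range(len(points)):
        own = assignment[i]
        if sizes[own] == 1:
            continue  # singleton convention: s = 0
        a = dist[i, assignment == own].sum() / (sizes[own] - 1)
        b = min(
            dist[i, assignment == lab].mean() for lab in labels if lab != own
        )
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


_LEVEL_NAMES = {3: ("Low", "Medium", "High")}


def _level_names(k: int) -> Tuple[str, ...]:
    return _LEVEL_NAMES.get(k, tuple(f"Level{i+1}" for i in range(k)))


@dataclass
class RiskLevelSpace:
    """Fitted risk-level space: ordered medoid centers in normalised space.

    ``centers_normalized[i]`` is the center of ``levels[i]``; levels are
    ordered by increasing Euclidean distance from the origin, so the first
    level is the lowest risk.
    """

    k: int
    levels: Tuple[str, ...]
    centers_normalized: np.ndarray
    centers_original: np.ndarray
    medoid_indices: np.ndarray
    silhouette_by_k: Dict[int, float]
    normalization: NormalizationParams

    def to_json(self, path: Path) -> None:
        payload = {
            "k": self.k,
            "levels": list(self.levels),
            "centers_normalized": self.centers_normalized.tolist(),
            "centers_original": self.centers_original.tolist(),
            "medoid_indices": self.medoid_indices.tolist(),
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "normalization": {
                "minimum": self.normalization.minimum.tolist(),
                "maximum": self.normalization.maximum.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Path) -> "RiskLevelSpace":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            levels=tuple(d["levels"]),
            centers_normalized=np.array(d["centers_normalized"]),
            centers_original=np.array(d["centers_original"]),
            medoid_indices=np.array(d["medoid_indices"], dtype=int),
            silhouette_by_k={int(k): v for k, v in d["silhouette_by_k"].items()},
            normalization=NormalizationParams(
                np.array(d["normalization"]["minimum"]),
                np.array(d["normalization"]["maximum"]),
            ),
        )


class RiskGradingModel:
    """Grades the indicator space into risk levels.

    Parameters
    ----------
    points : pandas.DataFrame or array
        Indicator series with columns ``nipi, thq, tcr`` (extra columns
        such as province/week are carried through to the assignment), or a
        plain (n, 3) array.
    """

    def __init__(self, points) -> None:
        if isinstance(points, pd.DataFrame):
            self._frame = points.reset_index(drop=True)
            self._X = points[list(INDICATORS)].to_numpy(dtype=float)
        else:
            self._frame = None
            self._X = np.asarray(points, dtype=float)
        if self._X.ndim != 2:
            raise ValueError("points must be 2-D")

    def fit(
        self,
        k_candidates: Sequence[int] = range(2, 8),
        seed: int = 0,
        n_restarts: int = 20,
    ) -> "RiskGradingResults":
        """Fit K-medoids for each candidate k and keep the best silhouette."""
        k_candidates = list(k_candidates)
        if len(self._X) < max(k_candidates):
            raise ValueError("fewer points than the largest candidate k")
        Xn, params = normalize(self._X)
        master = np.random.default_rng(seed)
        sil_by_k: Dict[int, float] = {}
        fits: Dict[int, Tuple[np.ndarray, np.ndarray, float]] = {}
        for k in k_candidates:
            sub_seed = int(master.integers(2**31))
            medoids, assignment, cost = kmedoids(
                Xn, k, seed=sub_seed, n_restarts=n_restarts
            )
            if len(np.unique(assignment)) < 2:
                warnings.warn(f"k={k} collapsed to a single occupied cluster")
                sil_by_k[k] = -1.0
            else:
                sil_by_k[k] = silhouette(Xn, assignment)
            fits[k] = (medoids, assignment, cost)

        best_k = max(sil_by_k, key=lambda k: (sil_by_k[k], -k))
        medoids, assignment, cost = fits[best_k]

        centers = Xn[medoids]
        order = np.argsort(np.linalg.norm(centers, axis=1), kind="stable")
        centers_sorted = centers[order]
        medoids_sorted = medoids[order]
        # relabel assignment so that label i == i-th level in the order
        relabel = np.empty(best_k, dtype=int)
        relabel[order] = np.arange(best_k)
        assignment = relabel[assignment]

        space = RiskLevelSpace(
            k=best_k,
            levels=_level_names(best_k),
            centers_normalized=centers_sorted,
            centers_original=params.inverse(centers_sorted),
            medoid_indices=medoids_sorted,
            silhouette_by_k=sil_by_k,
            normalization=params,
        )
        return RiskGradingResults(self, space, assignment, float(cost))


@dataclass
class RiskGradingResults:
    """Results of :meth:`RiskGradingModel.fit`."""

    model: RiskGradingModel
    space: RiskLevelSpace
    assignment: np.ndarray
    cost: float

    @property
    def labels(self) -> List[str]:
        """Level name per input point."""
        return [self.space.levels[a] for a in self.assignment]

    def assignment_frame(self) -> pd.DataFrame:
        base = (
            self.model._frame.copy()
            if self.model._frame is not None
            else pd.DataFrame(self.model._X, columns=list(INDICATORS))
        )
        base["level"] = self.labels
        return base

    def summary(self) -> str:
        sp = self.space
        lines = [
            "Risk level space (K-medoids, min-max normalised indicators)",
            f"selected k = {sp.k}  "
            f"(mean silhouette {sp.silhouette_by_k[sp.k]:.4f}, cost {self.cost:.4f})",
            "",
            "silhouette by k: "
            + ", ".join(f"{k}:{v:.4f}" for k, v in sorted(sp.silhouette_by_k.items())),
            "",
            f"{'level':<8}{'n':>6}  {'NIPI':>10}{'THQ':>10}{'TCR':>12}  (original units)",
        ]
        counts = np.bincount(self.assignment, minlength=sp.k)
        for i, lv in enumerate(sp.levels):
            c = sp.centers_original[i]
            lines.append(
                f"{lv:<8}{counts[i]:>6}  {c[0]:>10.5f}{c[1]:>10.5f}{c[2]:>12.3e}"
            )
        return "\n".join(lines)


def grade_risk_space(
    points,
    k_candidates: Sequence[int] = range(2, 8),
    seed: int = 0,
    n_restarts: int = 20,
) -> RiskLevelSpace:
    """Functional wrapper: fit the grading model and return the level space."""
    return RiskGradingModel(points).fit(k_candidates, seed, n_restarts).space
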