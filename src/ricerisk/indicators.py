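"""Weekly province-level risk indicators for heavy metals in rice.

Three indicators summarise one province-week of sampling data:

* **NIPI** — Nemerow integrated pollution index,
  ``sqrt((Pmax² + Pave²)/2)`` over the per-metal single-factor indices
  ``P = C/S`` (concentration over regulatory limit).
* **THQ** — target hazard quotient, the sum over metals of
  ``HQ = (F50 · Cavg) / (RfD · W)``.
* **TCR** — total carcinogenic risk, ``Σ EF·ED·CSF·EDI / ATC`` with
  ``EDI = F50 · Cavg / W``.

Non-detects are imputed at half the limit of detection before any
aggregation (the standard treatment when the non-detect fraction is well
below 60%). The weekly concentration ``Cavg`` for a province is the mean of
the LOD-substituted sample values of that week.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constants import DEFAULT_LOD, METALS, HMConstants

__all__ = [
    "SamplingRecord",
    "ConsumptionRecord",
    "substitute_lod",
    "single_factor_index",
    "nemerow_index",
    "hazard_quotient",
    "target_hazard_quotient",
    "estimated_daily_intake",
    "total_carcinogenic_risk",
    "build_indicator_series",
]


@dataclass
class SamplingRecord:
    """One laboratory measurement of the three metals in one rice sample.

    ``censored[m]`` is True when metal ``m`` was below the limit of
    detection; the stored concentration then equals the LOD itself.
    """

    province: str
    week_index: int
    concentrations: Dict[str, float] = field(default_factory=dict)
    censored: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {m}: {c}")


@dataclass(frozen=True)
class ConsumptionRecord:
    """Mean daily rice consumption of one province, kg/d."""

    province: str
    f50: float

    def __post_init__(self) -> None:
        if not self.f50 > 0:
            raise ValueError("f50 must be > 0")


def substitute_lod(
    record: SamplingRecord, lod: Mapping[str, float]
) -> SamplingRecord:
    """Replace censored concentrations by half the limit of detection.

    Uncensored entries pass through unchanged. Raises ``KeyError`` when a
    censored metal has no LOD entry and ``ValueError`` for nonpositive LODs.
    """
    new_conc = dict(record.concentrations)
    for m, is_cens in record.censored.items():
        if m not in record.concentrations:
            raise KeyError(f"unknown metal key {m!r}")
        if is_cens:
            if m not in lod:
                raise KeyError(f"no LOD given for metal {m!r}")
            if not lod[m] > 0:
                raise ValueError(f"LOD for {m!r} must be > 0")
            new_conc[m] = lod[m] / 2.0
    return replace(record, concentrations=new_conc)


def single_factor_index(c: float, s: float) -> float:
    """Single-factor pollution index ``P = C/S`` (dimensionless)."""
    if not s > 0:
        raise ValueError("regulatory limit s must be > 0")
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return c / s


def nemerow_index(p: Sequence[float]) -> float:
    """Nemerow integrated pollution index of single-factor indices.

    ``sqrt((max(p)² + mean(p)²)/2)`` — weights the worst contaminant
    against the average so one elevated metal is not diluted away.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty index sequence")
    if np.any(arr < 0):
        raise ValueError("single-factor indices must be >= 0")
    pmax = float(arr.max())
    pave = float(arr.mean())
    return math.sqrt((pmax**2 + pave**2) / 2.0)


def hazard_quotient(f50: float, cavg: float, rfd: float, w: float) -> float:
    """Noncarcinogenic hazard quotient ``(F50·Cavg)/(RfD·W)``."""
    if not (f50 > 0 and rfd > 0 and w > 0):
        raise ValueError("f50, rfd and w must be > 0")
    if cavg < 0:
        raise ValueError("cavg must be >= 0")
    return (f50 * cavg) / (rfd * w)


def target_hazard_quotient(hq: Union[Mapping[str, float], Sequence[float]]) -> float:
    """Target hazard quotient: the sum of per-metal hazard quotients.

    Values above 1 flag a noncarcinogenic risk; at or below 1 the risk is
    considered low (additivity assumed, no synergy or antagonism).
    """
    values = list(hq.values()) if isinstance(hq, Mapping) else list(hq)
    if any(v < 0 for v in values):
        raise ValueError("hazard quotients must be >= 0")
    return float(sum(values))


def estimated_daily_intake(f50: float, cavg: float, w: float) -> float:
    """Estimated daily intake ``F50·Cavg/W`` in mg/(kg·d)."""
    if not (f50 > 0 and w > 0):
        raise ValueError("f50 and w must be > 0")
    if cavg < 0:
        raise ValueError("cavg must be >= 0")
    return (f50 * cavg) / w


def total_carcinogenic_risk(
    edi: Mapping[str, float], constants: HMConstants
) -> float:
    """Total carcinogenic risk ``Σ_j EF·ED·CSF_j·EDI_j / ATC``.

    With the defaults EF=365 d/y, ED=70 y and ATC=365·70 d the prefactor
    cancels and TCR reduces to ``Σ CSF_j·EDI_j`` exactly.
    """
    prefactor = constants.ef * constants.ed / constants.atc  # 1.0 at defaults
    total = 0.0
    for m, e in edi.items():
        if e < 0:
            raise ValueError(f"EDI for {m!r} must be >= 0")
        total += prefactor * constants.csf[m] * e
    return total


# ---------------------------------------------------------------------------
# series construction


def _records_to_frame(samples: Iterable[SamplingRecord]) -> pd.DataFrame:
    rows = []
    for r in samples:
        row = {"province": r.province, "week": r.week_index}
        for m in METALS:
            row[m] = r.concentrations[m]
            row[f"{m}_censored"] = bool(r.censored.get(m, False))
        rows.append(row)
    return pd.DataFrame(rows)


def build_indicator_series(
    samples: Union[Iterable[SamplingRecord], pd.DataFrame],
    consumption: Union[Iterable[ConsumptionRecord], pd.DataFrame],
    constants: Optional[HMConstants] = None,
    lod: Optional[Mapping[str, float]] = None,
    n_weeks: Optional[int] = None,
) -> pd.DataFrame:
    """Compute the weekly (NIPI, THQ, TCR) series for every province.

    Parameters
    ----------
    samples
        Sampling table — ``SamplingRecord`` objects or a DataFrame with
        columns ``province, week, cd, cr, as, cd_censored, cr_censored,
        as_censored``.
    consumption
        Per-province mean daily rice consumption (kg/d) — records or a
        DataFrame with columns ``province, f50_kg_per_day``.
    constants
        Exposure constants; defaults to :class:`HMConstants`.
    lod
        Limit of detection per metal, mg/kg, for the half-LOD substitution.
    n_weeks
        Length of the week axis. Defaults to the largest week observed.

    Returns
    -------
    pandas.DataFrame
        Columns ``province, week, nipi, thq, tcr, gap_filled`` with one row
        per province-week over ``1..n_weeks``. Weeks with no samples carry
        the last available indicator triplet forward (leading gaps take the
        first available one) and are flagged ``gap_filled``.
    """
    constants = constants or HMConstants()
    lod = dict(lod or DEFAULT_LOD)

    if not isinstance(samples, pd.DataFrame):
        samples = _records_to_frame(samples)
    if samples.empty:
        raise ValueError("no sampling records given")
    samples = samples.copy()

    if not isinstance(consumption, pd.DataFrame):
        consumption = pd.DataFrame(
            [{"province": c.province, "f50_kg_per_day": c.f50} for c in consumption]
        )
    f50_map = dict(
        zip(consumption["province"], consumption["f50_kg_per_day"].astype(float))
    )
    if any(not v > 0 for v in f50_map.values()):
        raise ValueError("all consumption values must be > 0")

    provinces = sorted(samples["province"].unique())
    missing = [p for p in provinces if p not in f50_map]
    if missing:
        raise ValueError(f"no consumption record for provinces: {missing}")

    # half-LOD substitution, vectorised
    for m in METALS:
        if not lod[m] > 0:
            raise ValueError(f"LOD for {m!r} must be > 0")
        cens = samples[f"{m}_censored"].astype(bool)
        samples[m] = np.where(cens, lod[m] / 2.0, samples[m].astype(float))

    if n_weeks is None:
        n_weeks = int(samples["week"].max())

    weekly = samples.groupby(["province", "week"], as_index=False)[list(METALS)].mean()

    s_vec = np.array([constants.limit[m] for m in METALS])
    rfd_vec = np.array([constants.rfd[m] for m in METALS])
    csf_vec = np.array([constants.csf[m] for m in METALS])
    w = constants.body_weight
    carc = constants.ef * constants.ed / constants.atc

    out_rows = []
    for prov in provinces:
        sub = weekly[weekly["province"] == prov].set_index("week")
        if sub.empty:
            raise ValueError(f"province {prov!r} has no samples on the week axis")
        f50 = f50_map[prov]
        triplet = None
        pending: list = []  # leading gap weeks awaiting the first observation
        for week in range(1, n_weeks + 1):
            if week in sub.index:
                cavg = sub.loc[week, list(METALS)].to_numpy(dtype=float)
                p = cavg / s_vec
                nipi = math.sqrt((p.max() ** 2 + p.mean() ** 2) / 2.0)
                hq = (f50 * cavg) / (rfd_vec * w)
                thq = float(hq.sum())
                edi = (f50 * cavg) / w
                tcr = float((carc * csf_vec * edi).sum())
                triplet = (nipi, thq, tcr)
                for wk in pending:
                    out_rows.append((prov, wk, *triplet, True))
                pending = []
                out_rows.append((prov, week, *triplet, False))
            elif triplet is not None:
                out_rows.append((prov, week, *triplet, True))
            else:
                pending.append(week)
        if pending:  # whole axis empty is impossible here, but be safe
            raise ValueError(f"province {prov!r} has no samples on the week axis")

    out = pd.DataFrame(
        out_rows, columns=["province", "week", "nipi", "thq", "tcr", "gap_filled"]
    )
    return out.sort_values(["province", "week"], ignore_index=True)
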