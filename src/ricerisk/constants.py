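"""Regulatory limits and exposure constants for the three metals tracked in rice.

The package follows the Chinese national contaminant limits for rice
(GB 2762) for cadmium, chromium and inorganic arsenic, together with the
JECFA/EPA oral reference doses (RfD) and EPA cancer slope factors (CSF)
used in dietary exposure assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

#: Canonical metal keys, in fixed order: cadmium, chromium, inorganic arsenic.
METALS: Tuple[str, str, str] = ("cd", "cr", "as")


@dataclass(frozen=True)
class HMConstants:
    """Heavy-metal exposure constants.

    Attributes
    ----------
    limit : dict
        National maximum level per metal in rice, mg/kg.
    rfd : dict
        Oral reference dose per metal, mg/(kg·d).
    csf : dict
        Cancer slope factor per metal, kg·d/mg.
    body_weight : float
        Average adult body weight W, kg.
    ef : float
        Exposure frequency, days/year.
    ed : float
        Exposure duration, years.
    atc : float
        Averaging time for carcinogenic effects, days (365 × ed by default,
        in which case EF·ED/ATC cancels to 1 exactly).
    """

    limit: Dict[str, float] = field(
        default_factory=lambda: {"cd": 0.2, "cr": 1.0, "as": 0.2}
    )
    rfd: Dict[str, float] = field(
        default_factory=lambda: {"cd": 0.001, "cr": 0.003, "as": 0.0003}
    )
    csf: Dict[str, float] = field(
        default_factory=lambda: {"cd": 6.3, "cr": 0.5, "as": 1.5}
    )
    body_weight: float = 60.0
    ef: float = 365.0
    ed: float = 70.0
    atc: float = 365.0 * 70.0

    def __post_init__(self) -> None:
        for name in ("limit", "rfd", "csf"):
            table = getattr(self, name)
            missing = [m for m in METALS if m not in table]
            if missing:
                raise ValueError(f"{name} missing metals: {missing}")
            bad = {m: v for m, v in table.items() if not v > 0}
            if bad:
                raise ValueError(f"{name} must be strictly positive, got {bad}")
        for name in ("body_weight", "ef", "ed", "atc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


#: Default laboratory limits of detection, mg/kg (configurable everywhere).
DEFAULT_LOD: Dict[str, float] = {"cd": 0.01, "cr": 0.05, "as": 0.01}
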