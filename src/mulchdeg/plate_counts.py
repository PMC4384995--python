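"""Dilution-plate arithmetic: CFU per gram dry soil and degrader isolation rates.

A soil suspension (wet soil shaken in water) is serially diluted and spread
on selective plates; colonies are counted, and on emulsified-polyester
overlay plates the colonies surrounded by a clear zone are the polymer
degraders.  Counts convert to CFU per gram of *dry* soil via the plated
volume, the dilution factor, the suspension volume and the soil water
content (water mass / wet mass); the degrader *isolation rate* is the
clear-zone-positive share of the total count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateObservation",
    "SoilSuspension",
    "ViableCount",
    "cfu_per_g_dry",
    "isolation_rate",
    "viable_count",
    "cross_soil_summary",
    "log10_transform",
    "counts_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlateObservation:
    """Colony counts from one plate, with its dilution metadata."""

    colonies_total: int
    colonies_clearing: int
    dilution_factor: float
    volume_plated_ml: float
    medium: str = "fungal"

    def __post_init__(self) -> None:
        if self.colonies_total < 0 or self.colonies_clearing < 0:
            raise ValueError("colony counts must be non-negative")
        if self.colonies_clearing > self.colonies_total:
            raise ValueError("clear-zone colonies cannot exceed the total count")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1 (fold dilution)")
        if self.volume_plated_ml <= 0:
            raise ValueError("volume_plated_ml must be positive")


@dataclass(frozen=True)
class SoilSuspension:
    """How the original suspension was made from wet soil."""

    wet_mass_g: float = 1.0
    suspension_volume_ml: float = 10.0
    water_content_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.wet_mass_g <= 0:
            raise ValueError("wet_mass_g must be positive")
        if not 0 <= self.water_content_fraction < 1:
            raise ValueError("water_content_fraction must lie in [0, 1)")

    @property
    def dry_mass_g(self) -> float:
        return self.wet_mass_g * (1.0 - self.water_content_fraction)


@dataclass
class ViableCount:
    """Per-soil viable-count summary on one medium (CFU per g dry soil)."""

    soil_id: str
    medium: str
    cfu_total_per_g_dry: float
    cfu_clearing_per_g_dry: float
    isolation_rate_percent: float  # NaN when total is 0 or missing
    rate_source: str = "cfu_ratio"  # "raw_counts" when computed from colonies

    def __post_init__(self) -> None:
        tot, clr = self.cfu_total_per_g_dry, self.cfu_clearing_per_g_dry
        if not (math.isnan(tot) or math.isnan(clr)) and clr > tot * (1 + 1e-12):
            raise ValueError("clearing CFU cannot exceed total CFU")


def cfu_per_g_dry(
    colonies: int | float,
    obs: PlateObservation | None = None,
    susp: SoilSuspension | None = None,
    *,
    dilution_factor: float | None = None,
    volume_plated_ml: float | None = None,
) -> float:
    """Convert a colony count into CFU per gram of dry soil.

    colonies / volume_plated * dilution * suspension_volume / dry_mass,
    with dry mass = wet mass * (1 - water content).
    """
    if obs is not None:
        dilution_factor = obs.dilution_factor
        volume_plated_ml = obs.volume_plated_ml
    if dilution_factor is None or volume_plated_ml is None:
        raise ValueError("dilution_factor and volume_plated_ml are required")
    if volume_plated_ml <= 0:
        raise ValueError("volume_plated_ml must be positive")
    susp = susp or SoilSuspension()
    conc_per_ml = colonies / volume_plated_ml * dilution_factor
    return conc_per_ml * susp.suspension_volume_ml / susp.dry_mass_g


def isolation_rate(clearing: float, total: float) -> float:
    """Percent of the viable population that clears the polymer (0-100).

    Accepts either CFU densities or raw colony counts (the ratio is
    scale-invariant).  A zero or missing total gives NaN.
    """
    if math.isnan(total) or math.isnan(clearing) or total == 0:
        return float("nan")
    if clearing > total:
        raise ValueError("clearing count exceeds total count")
    return 100.0 * clearing / total


def viable_count(
    obs: PlateObservation, susp: SoilSuspension, soil_id: str = ""
) -> ViableCount:
    """Full per-plate conversion: densities plus raw-count isolation rate."""
    total = cfu_per_g_dry(obs.colonies_total, obs, susp)
    clearing = cfu_per_g_dry(obs.colonies_clearing, obs, susp)
    rate = isolation_rate(obs.colonies_clearing, obs.colonies_total)
    return ViableCount(
        soil_id=soil_id,
        medium=obs.medium,
        cfu_total_per_g_dry=total,
        cfu_clearing_per_g_dry=clearing,
        isolation_rate_percent=rate,
        rate_source="raw_counts",
    )


def cross_soil_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min/max (with soil labels) across a multi-soil table.

    ``table`` is indexed by soil_id with numeric columns; NA entries are
    skipped.  Returns a frame with rows ``min``, ``min_soil``, ``max``,
    ``max_soil`` (all-NA columns stay NA).
    """
    if len(table) == 0:
        raise ValueError("summary requires at least one soil")
    out: dict[str, list] = {}
    for col in table.columns:
        s = pd.to_numeric(table[col], errors="coerce").dropna()
        if s.empty:
            out[col] = [np.nan, None, np.nan, None]
        else:
            out[col] = [s.min(), s.idxmin(), s.max(), s.idxmax()]
    return pd.DataFrame(out, index=["min", "min_soil", "max", "max_soil"])


def log10_transform(
    counts, zero_policy: str = "exclude", offset: float = 1.0
) -> np.ndarray:
    """Base-10 log of viable counts, for normality checks and trend tests.

    Zeros are excluded with a warning by default; ``zero_policy="offset"``
    adds ``offset`` to every value instead.  Negative counts are an error.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("viable counts cannot be negative")
    if zero_policy == "offset":
        return np.log10(arr + offset)
    zeros = arr == 0
    if zeros.any():
        warnings.warn(
            f"excluded {int(zeros.sum())} zero count(s) from log10 transform",
            stacklevel=2,
        )
        arr = arr[~zeros]
    return np.log10(arr)


REQUIRED_COLUMNS = [
    "soil_id",
    "medium",
    "dilution_factor",
    "volume_plated_ml",
    "colonies_total",
    "colonies_clearing",
    "wet_mass_g",
    "suspension_volume_ml",
    "water_content_fraction",
]


def counts_table(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a long per-plate CSV table into the per-soil summary table.

    Input columns are :data:`REQUIRED_COLUMNS`; plates sharing (soil_id,
    medium) are pooled by summing colonies and averaging the per-plate
    density estimates.  Isolation rates come from pooled raw counts
    (falling back to the CFU ratio when counts are missing; the path used
    is recorded in ``rate_source``).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing columns {missing}")
    rows = []
    for (soil, medium), grp in df.groupby(["soil_id", "medium"], sort=False):
        totals, clearings = [], []
        raw_tot = raw_clr = 0.0
        have_raw = True
        for _, r in grp.iterrows():
            susp = SoilSuspension(
                wet_mass_g=r["wet_mass_g"],
                suspension_volume_ml=r["suspension_volume_ml"],
                water_content_fraction=r["water_content_fraction"],
            )
            if pd.isna(r["colonies_total"]):
                have_raw = False
                totals.append(np.nan)
                clearings.append(np.nan)
                continue
            obs = PlateObservation(
                colonies_total=int(r["colonies_total"]),
                colonies_clearing=int(r["colonies_clearing"]),
                dilution_factor=r["dilution_factor"],
                volume_plated_ml=r["volume_plated_ml"],
                medium=medium,
            )
            totals.append(cfu_per_g_dry(obs.colonies_total, obs, susp))
            clearings.append(cfu_per_g_dry(obs.colonies_clearing, obs, susp))
            raw_tot += obs.colonies_total
            raw_clr += obs.colonies_clearing
        tot_vals = [v for v in totals if not np.isnan(v)]
        clr_vals = [v for v in clearings if not np.isnan(v)]
        tot = float(np.mean(tot_vals)) if tot_vals else float("nan")
        clr = float(np.mean(clr_vals)) if clr_vals else float("nan")
        if have_raw and raw_tot > 0:
            rate, source = isolation_rate(raw_clr, raw_tot), "raw_counts"
        else:
            rate, source = isolation_rate(clr, tot), "cfu_ratio"
        log.info("%s/%s isolation rate from %s", soil, medium, source)
        rows.append(
            dict(
                soil_id=soil,
                medium=medium,
                cfu_total_per_g_dry=tot,
                cfu_clearing_per_g_dry=clr,
                isolation_rate_percent=rate,
                rate_source=source,
            )
        )
    return pd.DataFrame(rows)
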