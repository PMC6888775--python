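"""Habitat-potential classification and per-zone occurrence rates.

A surveyed site is *potential* habitat when it has at least
``hard_substrate_threshold_pct`` combined hard-substrate cover and lies no
deeper than the local light limit (a configurable fraction, default 0.6, of
the photic depth derived from Secchi depth). Occurrence rates are then
tallied per water-body zone, excluding zones with too few potential sites.

A "Fucus observation" is any site with ``fucus_cover_pct > 0`` (sites are
counted once; cover thresholds belong to the zone-belt definition, not to
occurrence rates). The occurrence-rate numerator is restricted to potential
sites so rates cannot exceed 100; off-layer observations are surfaced only
through :func:`layer_validation`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fucusstat.errors import ConfigurationError, InputError

log = logging.getLogger(__name__)

# 11-class substrate scheme; the first seven classes count as hard substrate.
HARD_CLASSES = (
    "bedrock",
    "boulders_gt300",
    "boulders_120_300",
    "boulders_60_120",
    "stones_10_60",
    "stones_6_10",
    "gravel",
)
SOFT_CLASSES = ("sand", "silt", "clay", "mud")
SUBSTRATE_CLASSES = HARD_CLASSES + SOFT_CLASSES

# Secchi->photic multiplier. Either a single coefficient or a piecewise
# table of (secchi_upper_bound, coefficient) pairs applied by lookup.
PhoticCoefficients = float | Sequence[tuple[float, float]]


@dataclass
class PotentialConfig:
    hard_substrate_threshold_pct: float = 10.0
    photic_coefficients: PhoticCoefficients = 2.0
    light_fraction: float = 0.6
    min_sites_per_zone: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.hard_substrate_threshold_pct <= 100:
            raise ConfigurationError("hard_substrate_threshold_pct must be in (0,100]")
        if not 0 < self.light_fraction <= 1:
            raise ConfigurationError("light_fraction must be in (0,1]")
        if self.min_sites_per_zone < 1:
            raise ConfigurationError("min_sites_per_zone must be >= 1")


def photic_depth(
    secchi_m: float | np.ndarray, coefficients: PhoticCoefficients = 2.0
) -> float | np.ndarray:
    """Photic depth (1% surface PAR) from Secchi depth.

    ``coefficients`` is either a single multiplier or a piecewise table of
    ``(secchi_upper_bound, coefficient)`` pairs sorted by bound; the
    coefficient of the first bound >= the Secchi value applies, and values
    beyond the last bound use the last coefficient.
    """
    secchi = np.asarray(secchi_m, dtype=float)
    if np.any(secchi <= 0):
        raise InputError("Secchi depth must be > 0")
    if isinstance(coefficients, (int, float)):
        out = float(coefficients) * secchi
    else:
        table = sorted(coefficients, key=lambda t: t[0])
        bounds = np.array([b for b, _ in table])
        coefs = np.array([c for _, c in table])
        idx = np.minimum(np.searchsorted(bounds, secchi, side="left"), len(table) - 1)
        out = coefs[idx] * secchi
    return float(out) if np.isscalar(secchi_m) else out


def light_limit_depth(
    photic_m: float | np.ndarray, light_fraction: float = 0.6
) -> float | np.ndarray:
    """Depth of adequate light: ``light_fraction`` times the photic depth."""
    if not 0 < light_fraction <= 1:
        raise ConfigurationError("light_fraction must be in (0,1]")
    photic = np.asarray(photic_m, dtype=float)
    if np.any(photic < 0):
        raise InputError("photic depth must be >= 0")
    out = light_fraction * photic
    return float(out) if np.isscalar(photic_m) else out


def hard_substrate_pct(points: pd.DataFrame) -> np.ndarray:
    """Summed hard-class cover per row; missing classes count as 0 (logged)."""
    missing = [c for c in HARD_CLASSES if c not in points.columns]
    if missing:
        log.warning("substrate classes missing, treated as 0%%: %s", missing)
    present = [c for c in HARD_CLASSES if c in points.columns]
    if not present:
        return np.zeros(len(points))
    return points[present].fillna(0.0).to_numpy(dtype=float).sum(axis=1)


def is_potential_site(
    point: Mapping[str, float],
    light_limit_at_point: float,
    config: PotentialConfig | None = None,
) -> bool:
    """Single-site predicate: enough hard substrate and shallow enough.

    The depth comparison is inclusive: a site exactly at the light limit is
    potential.
    """
    config = config or PotentialConfig()
    hard = sum(float(point.get(c, 0) or 0) for c in HARD_CLASSES)
    return (
        hard >= config.hard_substrate_threshold_pct
        and float(point["depth_m"]) <= light_limit_at_point
    )


def potential_flags(
    points: pd.DataFrame,
    light_limit: np.ndarray,
    config: PotentialConfig | None = None,
) -> np.ndarray:
    """Vectorised :func:`is_potential_site` over a survey-point table.

    Rows whose light limit is missing (NaN, e.g. off-grid points) are never
    potential and are counted in the log.
    """
    config = config or PotentialConfig()
    light_limit = np.asarray(light_limit, dtype=float)
    if len(light_limit) != len(points):
        raise InputError("light_limit length must match points")
    hard = hard_substrate_pct(points)
    depth = points["depth_m"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        flags = (hard >= config.hard_substrate_threshold_pct) & (depth <= light_limit)
    n_nan = int(np.sum(~np.isfinite(light_limit)))
    if n_nan:
        log.warning("potential_flags: %d points lack a light limit (off-grid)", n_nan)
    log.info("potential_flags: %d of %d sites potential", int(flags.sum()), len(points))
    return flags


@dataclass
class ZoneSummary:
    zone_id: object
    n_potential: int
    n_with_fucus: int
    occurrence_rate_pct: float | None
    excluded: bool


def zone_occurrence_rates(
    points: pd.DataFrame, config: PotentialConfig | None = None
) -> pd.DataFrame:
    """Per-zone occurrence rate with the small-zone exclusion rule.

    ``points`` must carry ``zone_id``, a boolean ``potential`` column and
    ``fucus_cover_pct``. The numerator counts potential sites with any Fucus
    (cover > 0). Zones with fewer than ``min_sites_per_zone`` potential sites
    are flagged excluded with a null rate.
    """
    config = config or PotentialConfig()
    for col in ("zone_id", "potential", "fucus_cover_pct"):
        if col not in points.columns:
            raise InputError(f"points table missing column '{col}'")
    rows = []
    for zone_id, grp in points.groupby("zone_id", sort=True):
        pot = grp[grp["potential"].astype(bool)]
        n_potential = len(pot)
        n_with = int((pot["fucus_cover_pct"].to_numpy(dtype=float) > 0).sum())
        excluded = n_potential < config.min_sites_per_zone
        rate = None if excluded else 100.0 * n_with / n_potential
        rows.append(
            {
                "zone_id": zone_id,
                "n_potential": n_potential,
                "n_with_fucus": n_with,
                "occurrence_rate_pct": rate,
                "excluded": excluded,
            }
        )
    out = pd.DataFrame(rows)
    n_excl = int(out["excluded"].sum()) if len(out) else 0
    log.info(
        "zone_occurrence_rates: %d zones, %d excluded (<%d potential sites)",
        len(out), n_excl, config.min_sites_per_zone,
    )
    return out


def layer_validation(
    points: pd.DataFrame, config: PotentialConfig | None = None
) -> float | None:
    """Percent of Fucus observations falling outside the potential layer.

    Returns None (with a warning) when there are no Fucus observations.
    """
    fucus = points["fucus_cover_pct"].to_numpy(dtype=float) > 0
    n_fucus = int(fucus.sum())
    if n_fucus == 0:
        warnings.warn("layer_validation: no Fucus observations", stacklevel=2)
        return None
    outside = fucus & ~points["potential"].to_numpy(dtype=bool)
    frac = 100.0 * int(outside.sum()) / n_fucus
    log.info(
        "layer_validation: %.2f%% of %d Fucus observations outside the layer",
        frac, n_fucus,
    )
    return frac
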