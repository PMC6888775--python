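"""Fucus-belt detection on dive transects.

A belt (zone) exists on a transect when at least two consecutive study
points — consecutive in distance order, regardless of spacing — both have
Fucus cover at or above the threshold. The lower limit is the deepest point
with cover >= threshold anywhere on the transect (literal reading); the
``contiguous_only`` switch restricts it to points inside a qualifying
contiguous run. A detected limit is only *retained* for depth-model use when
hard substrate continues below it, proving the belt was not cut off by
unsuitable substrate or by the transect ending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fucusstat.errors import InputError
from fucusstat.habitat import hard_substrate_pct

log = logging.getLogger(__name__)

DEFAULT_COVER_THRESHOLD = 10.0
DEFAULT_HARD_THRESHOLD = 10.0


@dataclass
class FucusZoneResult:
    transect_id: object
    zone_detected: bool
    lower_limit_m: float | None
    substrate_continues: bool | None
    retained: bool


def _sorted_transect(transect: pd.DataFrame) -> pd.DataFrame:
    if "distance_m" not in transect.columns:
        raise InputError("transect table missing 'distance_m'")
    return transect.sort_values("distance_m", kind="mergesort")


def detect_zone(
    transect: pd.DataFrame, cover_threshold: float = DEFAULT_COVER_THRESHOLD
) -> bool:
    """True iff some pair of consecutive points both have cover >= threshold."""
    if len(transect) < 2:
        log.info("detect_zone: < 2 points, no zone")
        return False
    cover = _sorted_transect(transect)["fucus_cover_pct"].to_numpy(dtype=float)
    above = cover >= cover_threshold
    return bool(np.any(above[1:] & above[:-1]))


def lower_limit(
    transect: pd.DataFrame,
    cover_threshold: float = DEFAULT_COVER_THRESHOLD,
    contiguous_only: bool = False,
) -> float | None:
    """Depth of the deepest >=threshold cover, or None when no zone detected.

    With ``contiguous_only`` the maximum is taken only over points belonging
    to a run of >= 2 consecutive above-threshold points.
    """
    if not detect_zone(transect, cover_threshold):
        return None
    t = _sorted_transect(transect)
    cover = t["fucus_cover_pct"].to_numpy(dtype=float)
    depth = t["depth_m"].to_numpy(dtype=float)
    above = cover >= cover_threshold
    if contiguous_only:
        in_run = above & (
            np.concatenate(([False], above[:-1])) | np.concatenate((above[1:], [False]))
        )
        candidates = depth[in_run]
    else:
        candidates = depth[above]
    return float(candidates.max())


def substrate_continues_below(
    transect: pd.DataFrame,
    limit_m: float,
    hard_threshold: float = DEFAULT_HARD_THRESHOLD,
) -> bool:
    """True iff some point strictly deeper than the limit has >=threshold hard cover.

    False when the transect has no points below the limit (it ended at the
    belt), which also disqualifies the transect.
    """
    if limit_m is None:
        raise InputError("substrate_continues_below requires a detected limit")
    depth = transect["depth_m"].to_numpy(dtype=float)
    below = depth > limit_m
    if not below.any():
        return False
    hard = hard_substrate_pct(transect)
    return bool(np.any(hard[below] >= hard_threshold))


def _is_malformed(transect: pd.DataFrame) -> str | None:
    for col in ("distance_m", "depth_m", "fucus_cover_pct"):
        if col not in transect.columns:
            return f"missing column '{col}'"
        vals = transect[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            return f"non-finite values in '{col}'"
    dist = np.sort(transect["distance_m"].to_numpy(dtype=float))
    if len(dist) > 1 and np.any(np.diff(dist) <= 0):
        return "distances not strictly increasing"
    return None


def assess_transects(
    transects: pd.DataFrame,
    cover_threshold: float = DEFAULT_COVER_THRESHOLD,
    hard_threshold: float = DEFAULT_HARD_THRESHOLD,
    contiguous_only: bool = False,
) -> pd.DataFrame:
    """Evaluate every transect: detection, lower limit, continuation, retention.

    ``transects`` is a long table keyed by ``transect_id``. Malformed
    transects are skipped with a warning. ``retained`` is true exactly when a
    zone was detected and hard substrate continues below its lower limit.
    """
    if "transect_id" not in transects.columns:
        raise InputError("transects table missing 'transect_id'")
    rows = []
    n_skipped = 0
    for tid, grp in transects.groupby("transect_id", sort=True):
        problem = _is_malformed(grp)
        if problem:
            log.warning("assess_transects: skipping transect %r (%s)", tid, problem)
            n_skipped += 1
            continue
        detected = detect_zone(grp, cover_threshold)
        limit = (
            lower_limit(grp, cover_threshold, contiguous_only) if detected else None
        )
        continues = (
            substrate_continues_below(grp, limit, hard_threshold)
            if limit is not None
            else None
        )
        rows.append(
            {
                "transect_id": tid,
                "zone_detected": detected,
                "lower_limit_m": limit,
                "substrate_continues": continues,
                "retained": bool(detected and continues),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "transect_id", "zone_detected", "lower_limit_m",
            "substrate_continues", "retained",
        ],
    )
    log.info(
        "assess_transects: %d transects, %d with zones, %d retained, %d skipped",
        len(out), int(out["zone_detected"].sum()) if len(out) else 0,
        int(out["retained"].sum()) if len(out) else 0, n_skipped,
    )
    return out
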