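"""Per-crop statistics, detection accuracy and the Area-LOS relation.

Summary statistics of the day-of-year metrics are wrap-aware: winter
crops green up around the year boundary in degraded scenarios, so DOY
means and SDs are computed on the circle (period 365) and reported back
on the 1-365 scale. The per-collection "overall SD" is the unweighted
mean of the per-crop SDs, rounded to the nearest day — the convention of
the workflow's summary tables. Detection accuracy is the percentage of
planted crop seasons matched by a detected season of the same parcel,
SOS-year and season class, rounded to integer percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .calendar import CropCalendar

__all__ = [
    "circular_doy_mean",
    "circular_doy_sd",
    "crop_stats",
    "average_overall_sd",
    "detection_table_from_counts",
    "detection_accuracy",
    "area_los_regression",
]


def circular_doy_mean(doy: np.ndarray) -> float:
    """Wrap-aware mean of day-of-year values (period 365), in (0, 365]."""
    m = float(stats.circmean(np.asarray(doy, dtype=float), high=365.0, low=0.0))
    return 365.0 if m == 0 else m


def circular_doy_sd(doy: np.ndarray) -> float:
    """Wrap-aware SD of day-of-year values in days (period 365)."""
    return float(stats.circstd(np.asarray(doy, dtype=float), high=365.0, low=0.0))


def average_overall_sd(per_crop_sds) -> float:
    """Per-collection overall SD: unweighted mean of the per-crop SDs,
    rounded to the nearest day."""
    vals = np.asarray(list(per_crop_sds), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.nan
    return float(np.round(vals.mean()))


def crop_stats(seasons: pd.DataFrame,
               group_cols: tuple[str, ...] = ("collection", "method", "crop"),
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/SD of SOS, EOS (circular DOY) and LOS (days) per group.

    Returns (per_crop, overall): per-crop rows carry mean, SD and group
    size for each metric (SD is NaN for singleton groups, never 0);
    overall rows average the per-crop SDs within each collection x method.
    """
    if not len(seasons):
        raise ValueError("empty seasons table")
    rows = []
    for key, grp in seasons.groupby(list(group_cols)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_cols, key))
        row["n"] = len(grp)
        for metric, circular in (("sos_doy", True), ("eos_doy", True),
                                 ("los_days", False)):
            x = grp[metric].to_numpy(dtype=float)
            if circular:
                row[f"{metric}_mean"] = circular_doy_mean(x)
                sd = circular_doy_sd(x) if len(x) > 1 else np.nan
            else:
                row[f"{metric}_mean"] = float(np.mean(x))
                sd = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
            row[f"{metric}_sd"] = sd
        rows.append(row)
    per_crop = pd.DataFrame(rows)

    agg_cols = [c for c in group_cols if c != "crop"]
    overall_rows = []
    if agg_cols:
        for key, grp in per_crop.groupby(agg_cols):
            key = key if isinstance(key, tuple) else (key,)
            row = dict(zip(agg_cols, key))
            for metric in ("sos_doy", "eos_doy", "los_days"):
                row[f"{metric}_overall_sd"] = average_overall_sd(
                    grp[f"{metric}_sd"])
            overall_rows.append(row)
    return per_crop, pd.DataFrame(overall_rows)


def detection_table_from_counts(detected: dict[str, int],
                                planted: dict[str, int]) -> pd.DataFrame:
    """Assemble the per-crop detection table from raw counts.

    accuracy = 100 * detected / planted rounded to integer percent; the
    totals row sums the per-crop counts and recomputes its accuracy from
    the summed counts.
    """
    rows = []
    for crop, n_pl in planted.items():
        n_det = int(detected.get(crop, 0))
        rows.append({"crop": crop, "planted": int(n_pl), "detected": n_det,
                     "accuracy_pct": int(round(100.0 * n_det / n_pl))})
    total_pl = int(sum(r["planted"] for r in rows))
    total_det = int(sum(r["detected"] for r in rows))
    rows.append({"crop": "total", "planted": total_pl, "detected": total_det,
                 "accuracy_pct": int(round(100.0 * total_det / total_pl))})
    return pd.DataFrame(rows)


def detection_accuracy(seasons: pd.DataFrame, planted: pd.DataFrame,
                       calendar: CropCalendar | None = None) -> pd.DataFrame:
    """Seasons detected vs crops planted, per crop, with a totals row.

    Planted entries and detected seasons are matched one-to-one within
    each (parcel, year, season class) cell, greedily by SOS proximity to
    the calendar planting day when a calendar is given. Detected seasons
    with no remaining planted entry are counted as unmatched.
    """
    if planted is None or not len(planted):
        raise ValueError("planted record is empty; accuracy undefined")
    planted = planted.copy()
    detected_per_crop = {c: 0 for c in planted["crop"].unique()}
    unmatched = 0

    sea_groups = ({k: g for k, g in seasons.groupby(
        ["parcel_id", "year", "season_class"])} if len(seasons) else {})
    matched_idx: set = set()
    for key, pgrp in planted.groupby(["parcel_id", "year", "season_class"]):
        sgrp = sea_groups.get(key)
        if sgrp is None:
            continue
        avail = list(sgrp.index)
        for _, prow in pgrp.iterrows():
            if not avail:
                break
            if calendar is not None and prow["crop"] in calendar:
                pdoy = calendar.planting_doy(prow["crop"])
                dist = [(float((seasons.loc[i, "sos_doy"] - pdoy) % 365.0), i)
                        for i in avail]
                dist.sort()
                pick = dist[0][1]
            else:
                pick = avail[0]
            avail.remove(pick)
            matched_idx.add(pick)
            detected_per_crop[prow["crop"]] += 1
    if len(seasons):
        unmatched = len(seasons) - len(matched_idx)

    planted_counts = planted.groupby("crop").size().to_dict()
    out = detection_table_from_counts(detected_per_crop, planted_counts)
    out["unmatched"] = 0
    out.loc[out["crop"] == "total", "unmatched"] = unmatched
    return out


def area_los_regression(seasons: pd.DataFrame) -> tuple[float, float, float]:
    """Standardized OLS of season Area against LOS; returns
    (slope, intercept, r).

    Area (LAI*days) is first scaled by the mean peak LAI of the table so
    both axes are in day units, then both variables are z-standardized
    before the ordinary least-squares fit, so a perfectly proportional
    Area-LOS relation yields slope 1 regardless of season shape.
    """
    if len(seasons) < 3:
        raise ValueError("regression needs at least 3 seasons")
    los = seasons["los_days"].to_numpy(dtype=float)
    peak = seasons["peak_lai"].to_numpy(dtype=float)
    area = seasons["area"].to_numpy(dtype=float) / float(np.mean(peak))
    if np.std(los) == 0 or np.std(area) == 0:
        raise ValueError("degenerate variance in Area-LOS regression")
    zx = (los - los.mean()) / los.std()
    zy = (area - area.mean()) / area.std()
    res = stats.linregress(zx, zy)
    return float(res.slope), float(res.intercept), float(res.rvalue)
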