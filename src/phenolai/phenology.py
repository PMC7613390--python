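"""Growing-season detection and LSP metric extraction.

A growing season is a local-minimum / local-maximum / local-minimum triple
of the LAI curve. Candidate peaks must stand out by a minimum prominence
(a fraction of the series range, default 30%) and be at least 90 days
apart; of peaks closer than that, only the largest survives (ties keep the
earlier). Start and end of season are the days where the curve crosses a
fraction (default 30%) of an amplitude above the flanking minima:

* seasonal method — the amplitude is per season: peak value minus the mean
  of its two flanking minima;
* relative method — one fixed amplitude for the whole series: mean of the
  kept peak values minus mean of their flanking minima values. Seasons
  whose curve never reaches the resulting level are not detected.

Crossings are located by linear interpolation between samples. A season
whose flanking minimum is only attained at a series endpoint is incomplete
(the series does not contain the full cycle) and is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .calendar import CropCalendar, season_class_of_doy
from .series import SampledSeries, day_to_doy, day_to_year

__all__ = [
    "DetectionConfig",
    "Peak",
    "PeakSet",
    "Season",
    "find_seasons",
    "seasonal_threshold",
    "relative_threshold",
    "season_metrics",
    "assign_crop",
    "extract_seasons",
    "seasons_to_frame",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Season-detection thresholds.

    prominence_frac : minimum peak prominence as a fraction of the series
        range (the workflow uses 0.10-0.30; default 0.30).
    min_separation : minimum days between kept peaks (default 90).
    amplitude_frac : SOS/EOS threshold fraction of the amplitude (default 0.30).
    method : "seasonal" or "relative".
    """

    prominence_frac: float = 0.30
    min_separation: float = 90.0
    amplitude_frac: float = 0.30
    method: str = "seasonal"

    def __post_init__(self):
        if not 0 < self.prominence_frac < 1:
            raise ValueError("prominence_frac must be in (0,1)")
        if not 0 < self.amplitude_frac < 1:
            raise ValueError("amplitude_frac must be in (0,1)")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")
        if self.method not in ("seasonal", "relative"):
            raise ValueError("method must be 'seasonal' or 'relative'")


@dataclass
class Peak:
    index: int
    t_peak: float
    v_peak: float
    prominence: float
    left_min: tuple[int, float, float]    # (index, day, value)
    right_min: tuple[int, float, float]
    left_complete: bool
    right_complete: bool

    @property
    def complete(self) -> bool:
        return self.left_complete and self.right_complete


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class Season:
    """One detected growth cycle with its LSP metrics."""

    parcel_id: str
    method: str
    sos: float                # day since epoch (continuous)
    eos: float
    t_peak: float
    v_peak: float
    amplitude: float
    peak_doy: float = np.nan
    sos_doy: float = np.nan
    eos_doy: float = np.nan
    year: int = 0             # calendar year of SOS
    eos_year: int = 0
    season_class: str = ""
    los: float = np.nan       # eos - sos, absolute days
    area: float = np.nan      # LAI*days above the SOS-EOS chord
    crop: str = ""


def _min_on(v: np.ndarray, lo: int, hi: int):
    """Position (first occurrence) and value of the minimum of v[lo..hi]."""
    seg = v[lo:hi + 1]
    vmin = float(seg.min())
    return int(np.argmin(seg)) + lo, vmin


def find_seasons(series: SampledSeries, cfg: DetectionConfig = DetectionConfig()
                 ) -> PeakSet:
    """Locate season peaks passing the prominence and separation rules."""
    if len(series) < 5:
        raise ValueError("season detection needs at least 5 samples")
    t, v = series.times, series.values
    rng = float(v.max() - v.min())
    if rng == 0:
        return PeakSet([])
    prom_thresh = cfg.prominence_frac * rng
    idx, props = find_peaks(v, prominence=prom_thresh)
    if len(idx) == 0:
        return PeakSet([])

    # enforce minimum separation in days: greedily keep the tallest
    # (earlier wins ties), discard smaller peaks within min_separation
    order = np.lexsort((idx, -v[idx]))
    kept: list[int] = []
    for j in order:
        pi = idx[j]
        if all(abs(t[pi] - t[k]) >= cfg.min_separation for k in kept):
            kept.append(pi)
    kept.sort()
    prom_by_idx = dict(zip(idx, props["prominences"]))

    n = len(v)
    peaks = []
    for pos, pi in enumerate(kept):
        lb = kept[pos - 1] if pos > 0 else 0
        rb = kept[pos + 1] if pos < len(kept) - 1 else n - 1
        li, lv = _min_on(v, lb, pi)
        ri, rv = _min_on(v, pi, rb)
        # Completeness: a flank whose minimum sits on a series endpoint is
        # genuine only if the curve has already descended below the season's
        # threshold level there; otherwise the series cuts the cycle short
        # (start mid-green-up or end mid-senescence) and no season is
        # computed from this peak on that side.
        base_proxy = min(lv, rv)
        level = base_proxy + cfg.amplitude_frac * (v[pi] - base_proxy)
        lcomp = li != 0 or v[0] <= level
        rcomp = ri != n - 1 or v[n - 1] <= level
        peaks.append(Peak(
            index=pi, t_peak=float(t[pi]), v_peak=float(v[pi]),
            prominence=float(prom_by_idx[pi]),
            left_min=(li, float(t[li]), float(lv)),
            right_min=(ri, float(t[ri]), float(rv)),
            left_complete=lcomp, right_complete=rcomp,
        ))
    return PeakSet(peaks)


def _cross_up(t, v, lo: int, pi: int, level: float) -> float | None:
    """Last upward crossing of `level` before the peak, by linear interp."""
    if v[pi] < level:
        return None
    for i in range(pi - 1, lo - 1, -1):
        if v[i] < level <= v[i + 1]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _cross_down(t, v, pi: int, hi: int, level: float) -> float | None:
    """First downward crossing of `level` after the peak."""
    if v[pi] < level:
        return None
    for i in range(pi, hi):
        if v[i] >= level > v[i + 1]:
            frac = (v[i] - level) / (v[i] - v[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _build_season(series, peak: Peak, amp: float, frac: float,
                  method: str) -> Season | None:
    t, v = series.times, series.values
    if amp <= 0:
        return None
    sos = _cross_up(t, v, peak.left_min[0], peak.index,
                    peak.left_min[2] + frac * amp)
    eos = _cross_down(t, v, peak.index, peak.right_min[0],
                      peak.right_min[2] + frac * amp)
    if sos is None or eos is None:
        return None
    season = Season(
        parcel_id=series.parcel_id, method=method, sos=sos, eos=eos,
        t_peak=peak.t_peak, v_peak=peak.v_peak, amplitude=amp,
        peak_doy=day_to_doy(peak.t_peak, series.epoch_year),
        sos_doy=day_to_doy(sos, series.epoch_year),
        eos_doy=day_to_doy(eos, series.epoch_year),
        year=day_to_year(sos, series.epoch_year),
        eos_year=day_to_year(eos, series.epoch_year),
    )
    season.season_class = season_class_of_doy(season.sos_doy)
    return season_metrics(season, series)


def seasonal_threshold(series: SampledSeries, peaks: PeakSet,
                       cfg: DetectionConfig = DetectionConfig()) -> list[Season]:
    """SOS/EOS per season from its own amplitude (peak minus mean of its
    flanking minima); incomplete seasons are discarded."""
    seasons = []
    for p in peaks:
        if not p.complete:
            continue
        amp = p.v_peak - 0.5 * (p.left_min[2] + p.right_min[2])
        s = _build_season(series, p, amp, cfg.amplitude_frac, "seasonal")
        if s is not None:
            seasons.append(s)
    return seasons


def relative_threshold(series: SampledSeries, peaks: PeakSet,
                       cfg: DetectionConfig = DetectionConfig()) -> list[Season]:
    """SOS/EOS from one fixed amplitude for the whole series (mean of kept
    peak values minus mean of their flanking minima values). Seasons whose
    curve never reaches the resulting level are not detected."""
    if len(peaks) == 0:
        return []
    peak_mean = float(np.mean([p.v_peak for p in peaks]))
    min_vals = {}
    for p in peaks:
        min_vals[p.left_min[0]] = p.left_min[2]
        min_vals[p.right_min[0]] = p.right_min[2]
    rel_amp = peak_mean - float(np.mean(list(min_vals.values())))
    seasons = []
    for p in peaks:
        if not p.complete:
            continue
        s = _build_season(series, p, rel_amp, cfg.amplitude_frac, "relative")
        if s is not None:
            seasons.append(s)
    return seasons


def season_metrics(season: Season, series: SampledSeries) -> Season:
    """Fill in LOS and Area.

    LOS is EOS minus SOS in days. Area is the trapezoidal integral over
    [SOS, EOS] of the LAI curve above the straight line (chord) joining
    the curve values at SOS and EOS, floored at zero.
    """
    if season.eos <= season.sos:
        raise ValueError("season has eos <= sos")
    season.los = season.eos - season.sos
    t, v = series.times, series.values
    inner = (t > season.sos) & (t < season.eos)
    ts = np.concatenate([[season.sos], t[inner], [season.eos]])
    vs = np.interp(ts, t, v)
    chord = vs[0] + (vs[-1] - vs[0]) * (ts - ts[0]) / (ts[-1] - ts[0])
    season.area = float(np.trapezoid(np.maximum(vs - chord, 0.0), ts))
    return season


def assign_crop(season: Season, calendar: CropCalendar,
                planted: pd.DataFrame | None = None) -> Season:
    """Label a season with its crop.

    Uses the planted record (parcel, SOS-year, season class) when
    available, otherwise falls back to the calendar crop of the matching
    class whose planting day most closely precedes the SOS. A season with
    no candidate crop is labelled "unknown", never dropped.
    """
    if not calendar.entries:
        raise ValueError("empty calendar")
    season.season_class = season_class_of_doy(season.sos_doy)
    if planted is not None and len(planted):
        hit = planted[(planted["parcel_id"] == season.parcel_id)
                      & (planted["year"] == season.year)
                      & (planted["season_class"] == season.season_class)]
        if len(hit):
            season.crop = str(hit["crop"].iloc[0])
            return season
    best, best_d = None, np.inf
    for crop in calendar.crops():
        if calendar.season_class(crop) != season.season_class:
            continue
        d = (season.sos_doy - calendar.planting_doy(crop)) % 365.0
        if d < best_d:
            best, best_d = crop, d
    season.crop = best or "unknown"
    return season


def extract_seasons(series: SampledSeries, cfg: DetectionConfig = DetectionConfig(),
                    calendar: CropCalendar | None = None,
                    planted: pd.DataFrame | None = None) -> list[Season]:
    """find_seasons + threshold method + metrics (+ crop label) in one call."""
    peaks = find_seasons(series, cfg)
    if cfg.method == "seasonal":
        seasons = seasonal_threshold(series, peaks, cfg)
    else:
        seasons = relative_threshold(series, peaks, cfg)
    if calendar is not None:
        for s in seasons:
            assign_crop(s, calendar, planted)
    return seasons


def seasons_to_frame(seasons: list[Season], collection: str = "") -> pd.DataFrame:
    """Season list as the tabular export dialect."""
    rows = [{
        "parcel_id": s.parcel_id, "year": s.year, "method": s.method,
        "collection": collection, "crop": s.crop, "season_class": s.season_class,
        "sos_doy": round(s.sos_doy, 2), "eos_doy": round(s.eos_doy, 2),
        "eos_year": s.eos_year, "los_days": round(s.los, 2),
        "area": round(s.area, 3), "peak_doy": round(s.peak_doy, 2),
        "peak_lai": round(s.v_peak, 3), "amplitude": round(s.amplitude, 3),
        "sos_day": round(s.sos, 3), "eos_day": round(s.eos, 3),
    } for s in seasons]
    cols = ["parcel_id", "year", "method", "collection", "crop", "season_class",
            "sos_doy", "eos_doy", "eos_year", "los_days", "area", "peak_doy",
            "peak_lai", "amplitude", "sos_day", "eos_day"]
    return pd.DataFrame(rows, columns=cols)
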