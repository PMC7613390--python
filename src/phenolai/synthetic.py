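"""Synthetic cropland LAI dynamics, sensor sampling, scenes and spectra.

Every downstream stage (retrieval, collection building, phenology
extraction, mapping, evaluation) is exercised against data produced here,
so the generator records its own ground truth: per-season green-up and
senescence days, peak LAI, and per-pixel season counts.

Truth curves are sums of per-season double-logistic pulses on a constant
base level — the standard land-surface-phenology shape: a sigmoid rise at
green-up and a sigmoid fall at senescence. Two acquisition schedules
emulate a dense (~5-day) and a sparse (~16-day) revisit sensor, with
uniform date jitter, Bernoulli cloud-gap dropout and additive Gaussian
observation noise. A fixed exponential-saturation forward model maps LAI
to multiband reflectance (red decreasing, NIR increasing with LAI) to
create training pairs for the retrieval stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from shapely.geometry import Polygon, box, mapping, shape

from .bands import BandSet, get_band_set
from .calendar import CropCalendar, nile_delta_calendar
from .raster import SceneStack
from .series import SampledSeries, day_to_year, doy_to_day

__all__ = [
    "SeasonTruth",
    "TruthCurve",
    "AcquisitionSchedule",
    "lai_truth_curve",
    "parcel_truth",
    "sample_series",
    "render_scene",
    "spectra_lai_pairs",
    "forward_model",
    "build_parcel_set",
]

DEFAULT_PEAK_LAI = {"rice": 5.5, "maize": 5.0, "wheat": 4.5, "clover": 4.0}
DEFAULT_BASE_LAI = 0.2
TRUTH_AMPLITUDE_FRAC = 0.30  # fraction at which sos_true/eos_true are defined


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class SeasonTruth:
    """Ground truth for one growth cycle of one crop on one parcel."""

    crop: str
    year: int                 # calendar year of sos_true
    season_class: str         # "summer" | "winter"
    sos_true: float           # day since epoch of the 30%-amplitude up-crossing
    eos_true: float           # day since epoch of the 30%-amplitude down-crossing
    t_peak: float
    peak_lai: float
    base_lai: float
    # double-logistic parameters
    t_green: float            # green-up inflection day
    t_sen: float              # senescence inflection day
    r_green: float            # green-up rate (1/day)
    r_sen: float              # senescence rate (1/day)
    scale: float              # pulse scale A

    def component(self, t):
        """Season pulse above the base level."""
        t = np.asarray(t, dtype=float)
        return self.scale * (_sigmoid(self.r_green * (t - self.t_green))
                             - _sigmoid(self.r_sen * (t - self.t_sen)))

    def crossing(self, frac: float) -> tuple[float, float]:
        """Days where the pulse crosses frac * amplitude (up, down)."""
        amp = self.peak_lai - self.base_lai
        level = frac * amp
        f = lambda t: float(self.component(t) - level)
        lo = self.t_green - 12.0 / self.r_green
        hi = self.t_sen + 12.0 / self.r_sen
        up = brentq(f, lo, self.t_peak, xtol=1e-8)
        down = brentq(f, self.t_peak, hi, xtol=1e-8)
        return up, down


class TruthCurve:
    """Continuous day -> LAI function: constant base plus season pulses."""

    def __init__(self, seasons: list[SeasonTruth], base_lai: float,
                 epoch_year: int = 2016):
        if base_lai < 0:
            raise ValueError("base_lai must be >= 0")
        self.seasons = sorted(seasons, key=lambda s: s.t_peak)
        self.base_lai = float(base_lai)
        self.epoch_year = epoch_year

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.base_lai)
        for s in self.seasons:
            out = out + s.component(t)
        return out if out.ndim else float(out)

    def seasons_in(self, t0: float, t1: float) -> list[SeasonTruth]:
        """Seasons whose full cycle (sos..eos) lies inside [t0, t1]."""
        return [s for s in self.seasons if s.sos_true >= t0 and s.eos_true <= t1]


def _make_season(crop: str, year: int, calendar: CropCalendar, *,
                 peak_lai: float, base_lai: float, epoch_year: int,
                 rng: np.random.Generator | None = None,
                 jitter_days: float = 5.0,
                 peak_jitter_frac: float = 0.10) -> SeasonTruth | None:
    p_doy = calendar.planting_doy(crop)
    h_doy = calendar.harvest_doy(crop)
    p = doy_to_day(p_doy, year, epoch_year)
    h_year = year + 1 if h_doy <= p_doy else year
    h = doy_to_day(h_doy, h_year, epoch_year)
    if rng is not None:
        p += rng.uniform(-jitter_days, jitter_days)
        h += rng.uniform(-jitter_days, jitter_days)
        peak_lai *= 1.0 + rng.uniform(-peak_jitter_frac, peak_jitter_frac)
    amp = peak_lai - base_lai
    if amp <= 0:
        return None  # degenerate: no pulse, curve stays at base
    length = h - p
    # Pulse shape by season class: summer cereals green up ~1 month after
    # planting and senesce before/around harvest (threshold-level season
    # length ~60% of the planting-harvest window); winter wheat/clover hold
    # a high canopy for most of their half-year cycle (~80% of the window).
    # The winter pulse is symmetric and domed: its maximum sits mid-window,
    # keeping truth peaks of consecutive seasons well over 90 days apart.
    if calendar.season_class(crop) == "winter":
        fg, fs, wg, ws = 0.15, 0.85, 0.28, 0.28
    else:
        fg, fs, wg, ws = 0.30, 0.80, 0.25, 0.20
    t_green = p + fg * length
    t_sen = p + fs * length
    r_green = 4.4 / (wg * length)   # 10-90% rise over wg * cycle length
    r_sen = 4.4 / (ws * length)

    raw = lambda t: (_sigmoid(r_green * (t - t_green))
                     - _sigmoid(r_sen * (t - t_sen)))
    res = minimize_scalar(lambda t: -raw(t), bounds=(t_green, t_sen),
                          method="bounded", options={"xatol": 1e-8})
    t_peak = float(res.x)
    scale = amp / raw(t_peak)

    s = SeasonTruth(
        crop=crop, year=year, season_class=calendar.season_class(crop),
        sos_true=np.nan, eos_true=np.nan, t_peak=t_peak,
        peak_lai=base_lai + amp, base_lai=base_lai,
        t_green=t_green, t_sen=t_sen, r_green=r_green, r_sen=r_sen,
        scale=scale,
    )
    s.sos_true, s.eos_true = s.crossing(TRUTH_AMPLITUDE_FRAC)
    s.year = day_to_year(s.sos_true, epoch_year)
    return s


def lai_truth_curve(crop: str, year: int, calendar: CropCalendar,
                    params: dict | None = None,
                    seed: int | None = None) -> TruthCurve:
    """Single-season truth curve for `crop` planted in `year`.

    `params` may override peak_lai, base_lai, epoch_year, jitter_days and
    peak_jitter_frac. With a seed, planting/harvest days and the peak are
    jittered reproducibly; without one the calendar dates are used exactly.
    """
    params = dict(params or {})
    if crop not in calendar:
        raise KeyError(f"crop {crop!r} not in calendar")
    epoch_year = int(params.pop("epoch_year", year))
    base_lai = float(params.pop("base_lai", DEFAULT_BASE_LAI))
    peak_lai = float(params.pop("peak_lai", DEFAULT_PEAK_LAI.get(crop, 5.0)))
    jd = float(params.pop("jitter_days", 5.0))
    pj = float(params.pop("peak_jitter_frac", 0.10))
    if params:
        raise ValueError(f"unknown truth-curve params: {sorted(params)}")
    rng = np.random.default_rng(seed) if seed is not None else None
    s = _make_season(crop, year, calendar, peak_lai=peak_lai, base_lai=base_lai,
                     epoch_year=epoch_year, rng=rng, jitter_days=jd,
                     peak_jitter_frac=pj)
    return TruthCurve([s] if s else [], base_lai, epoch_year=epoch_year)


def parcel_truth(rotation: list[tuple[int, str]], calendar: CropCalendar,
                 epoch_year: int, base_lai: float = DEFAULT_BASE_LAI,
                 peak_lai: dict | None = None,
                 seed: int | None = None, jitter_days: float = 5.0,
                 peak_jitter_frac: float = 0.10) -> TruthCurve:
    """Multi-season truth curve from a rotation [(year, crop), ...]."""
    peaks = dict(DEFAULT_PEAK_LAI)
    peaks.update(peak_lai or {})
    rng = np.random.default_rng(seed) if seed is not None else None
    seasons = []
    for year, crop in rotation:
        s = _make_season(crop, year, calendar,
                         peak_lai=peaks.get(crop, 5.0), base_lai=base_lai,
                         epoch_year=epoch_year, rng=rng, jitter_days=jitter_days,
                         peak_jitter_frac=peak_jitter_frac)
        if s is not None:
            seasons.append(s)
    return TruthCurve(seasons, base_lai, epoch_year=epoch_year)


# ---------------------------------------------------------------------------
# sampling


@dataclass
class AcquisitionSchedule:
    """Nominal revisit pattern of one sensor over [start, end] days."""

    sensor: str
    nominal_revisit: float
    jitter: float = 1.0
    gap_prob: float = 0.0
    start: float = 0.0
    end: float = 730.0
    seed: int | None = None

    def __post_init__(self):
        if self.nominal_revisit <= 0:
            raise ValueError("nominal_revisit must be > 0")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ValueError("gap_prob must be in [0,1]")

    def dates(self, seed: int | None = None) -> np.ndarray:
        """Strictly increasing acquisition days after jitter and dropout."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        base = np.arange(self.start, self.end + 1e-9, self.nominal_revisit)
        d = base + rng.uniform(-self.jitter, self.jitter, size=base.shape)
        d = d[(d >= self.start) & (d <= self.end)]
        keep = rng.random(d.shape) >= self.gap_prob
        d = np.sort(d[keep])
        if len(d) > 1:  # enforce strict monotonicity after jitter
            d = d[np.concatenate([[True], np.diff(d) > 1e-9])]
        return d


def sample_series(truth, schedule: AcquisitionSchedule, noise_sd: float = 0.0,
                  seed: int | None = None, parcel_id: str = "parcel",
                  epoch_year: int | None = None) -> SampledSeries:
    """Observe a truth curve through a schedule with Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(schedule.seed if seed is None else seed)
    t = schedule.dates(seed=rng.integers(2**31))
    if len(t) == 0:
        raise ValueError(
            f"schedule for sensor {schedule.sensor!r} produced an empty series")
    v = np.asarray(truth(t), dtype=float)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    ey = epoch_year or getattr(truth, "epoch_year", 2016)
    return SampledSeries(t, v, sensor=np.full(t.shape, schedule.sensor, dtype=object),
                         parcel_id=parcel_id, epoch_year=ey)


# ---------------------------------------------------------------------------
# scenes


def render_scene(parcels: dict[str, Polygon], truths: dict[str, TruthCurve],
                 schedule: AcquisitionSchedule, grid_shape: tuple[int, int],
                 seed: int = 0, noise_sd: float = 0.0,
                 noise_mode: str = "parcel",
                 background_lai: float = DEFAULT_BASE_LAI,
                 epoch_year: int | None = None):
    """Rasterize parcel truth curves into an LAI scene stack.

    Pixels whose centre falls inside a parcel polygon carry that parcel's
    sampled series (noise drawn once per parcel, or per pixel when
    noise_mode="pixel"); background pixels carry the constant background
    LAI, which sits below the vegetation-mask threshold. Returns
    (SceneStack, truth_maps) where truth_maps holds per-pixel season count
    and first-season SOS/EOS days.
    """
    h, w = grid_shape
    if h <= 0 or w <= 0:
        raise ValueError("zero-area grid")
    if noise_mode not in ("parcel", "pixel"):
        raise ValueError("noise_mode must be 'parcel' or 'pixel'")
    ey = epoch_year or next(iter(truths.values())).epoch_year if truths else 2016
    rng = np.random.default_rng(seed)
    times = schedule.dates(seed=rng.integers(2**31))
    if len(times) == 0:
        raise ValueError("schedule produced no acquisition dates")

    data = np.full((len(times), h, w), float(background_lai))
    parcel_map = np.full((h, w), -1, dtype=int)
    count = np.zeros((h, w), dtype=int)
    sos = np.full((h, w), np.nan)
    eos = np.full((h, w), np.nan)

    import shapely

    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    for idx, (pid, poly) in enumerate(sorted(parcels.items())):
        inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel()).reshape(h, w)
        if not inside.any():
            continue
        parcel_map[inside] = idx
        truth = truths[pid]
        clean = np.asarray(truth(times), dtype=float)
        if noise_sd > 0 and noise_mode == "parcel":
            vals = clean + rng.normal(0.0, noise_sd, size=clean.shape)
            data[:, inside] = vals[:, None]
        elif noise_sd > 0:
            n = int(inside.sum())
            data[:, inside] = clean[:, None] + rng.normal(
                0.0, noise_sd, size=(len(times), n))
        else:
            data[:, inside] = clean[:, None]
        count[inside] = len(truth.seasons)
        if truth.seasons:
            sos[inside] = truth.seasons[0].sos_true
            eos[inside] = truth.seasons[0].eos_true

    stack = SceneStack(data=data, times=times,
                       sensors=np.full(times.shape, schedule.sensor, dtype=object),
                       epoch_year=ey, parcel_map=parcel_map)
    return stack, {"season_count": count, "sos": sos, "eos": eos}


# ---------------------------------------------------------------------------
# spectra

# Per-wavelength soil reflectance, dense-canopy asymptote and extinction
# coefficient of the exponential-saturation forward model
# r(LAI) = r_veg + (r_soil - r_veg) * exp(-k * LAI).
_BAND_OPTICS = {
    480: (0.080, 0.032, 0.60),
    490: (0.082, 0.033, 0.60),
    560: (0.105, 0.060, 0.55),
    655: (0.120, 0.030, 0.65),
    665: (0.122, 0.031, 0.65),
    705: (0.130, 0.100, 0.50),
    740: (0.160, 0.280, 0.45),
    783: (0.180, 0.420, 0.45),
    842: (0.200, 0.500, 0.42),
    865: (0.205, 0.520, 0.42),
    1610: (0.250, 0.120, 0.50),
    2190: (0.220, 0.075, 0.55),
    2200: (0.218, 0.074, 0.55),
}


def forward_model(lai, band_set: BandSet | str) -> np.ndarray:
    """Map LAI to reflectance, one column per band of the dialect."""
    bs = get_band_set(band_set)
    lai = np.atleast_1d(np.asarray(lai, dtype=float))
    out = np.empty((len(lai), bs.nbands))
    for j, wl in enumerate(bs.center_wavelengths):
        r_soil, r_veg, k = _BAND_OPTICS[wl]
        out[:, j] = r_veg + (r_soil - r_veg) * np.exp(-k * lai)
    return out


def invert_band(reflectance, band_set: BandSet | str, band: str) -> np.ndarray:
    """Closed-form LAI from one band of the noiseless forward model."""
    bs = get_band_set(band_set)
    j = bs.band_names.index(band)
    r_soil, r_veg, k = _BAND_OPTICS[bs.center_wavelengths[j]]
    ratio = (np.asarray(reflectance, dtype=float) - r_veg) / (r_soil - r_veg)
    return -np.log(np.clip(ratio, 1e-12, None)) / k


def spectra_lai_pairs(n: int, band_set: BandSet | str, seed: int = 0,
                      noise_sd: float = 0.005,
                      lai_range: tuple[float, float] = (0.0, 6.0)) -> pd.DataFrame:
    """Paired (reflectance, LAI) training table for the retrieval stage."""
    if n < 10:
        raise ValueError("need n >= 10 training pairs")
    bs = get_band_set(band_set)
    rng = np.random.default_rng(seed)
    lai = rng.uniform(lai_range[0], lai_range[1], size=n)
    refl = forward_model(lai, bs)
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    df = pd.DataFrame(refl, columns=list(bs.band_names))
    df["lai"] = lai
    return df


# ---------------------------------------------------------------------------
# study scenarios


#: rotations of the emulated cropping system: double-cropping parcels grow a
#: summer and a winter crop each year; single-cropping parcels one crop.
DOUBLE_ROTATIONS = [("rice", "wheat"), ("maize", "clover"),
                    ("rice", "clover"), ("maize", "wheat")]
SINGLE_CROPS = ["rice", "maize", "wheat", "clover"]


def build_parcel_set(n_parcels: int, years: list[int], seed: int = 0,
                     double_frac: float = 0.34,
                     calendar: CropCalendar | None = None,
                     epoch_year: int | None = None,
                     base_lai: float = DEFAULT_BASE_LAI):
    """Random parcels with rotations, their truth curves and planted record.

    Returns (truths, planted) where truths maps parcel_id -> TruthCurve and
    planted is the reference table (parcel_id, year, season_class, crop)
    against which detection accuracy is scored. The double-cropping
    fraction defaults to roughly a third, matching an intensifying
    irrigated delta system.
    """
    calendar = calendar or nile_delta_calendar()
    epoch_year = epoch_year or years[0]
    rng = np.random.default_rng(seed)
    truths: dict[str, TruthCurve] = {}
    rows = []
    for i in range(n_parcels):
        pid = f"p{i:03d}"
        rotation: list[tuple[int, str]] = []
        if rng.random() < double_frac:
            summer, winter = DOUBLE_ROTATIONS[rng.integers(len(DOUBLE_ROTATIONS))]
            for y in years:
                rotation += [(y, summer), (y, winter)]
        else:
            crop = SINGLE_CROPS[rng.integers(len(SINGLE_CROPS))]
            for y in years:
                rotation.append((y, crop))
        truths[pid] = parcel_truth(rotation, calendar, epoch_year,
                                   base_lai=base_lai,
                                   seed=int(rng.integers(2**31)))
        for s in truths[pid].seasons:
            rows.append({"parcel_id": pid, "year": s.year,
                         "season_class": s.season_class, "crop": s.crop})
    planted = pd.DataFrame(rows)
    return truths, planted


def grid_parcels(n_parcels: int, parcel_size: int = 4,
                 gap: int = 2) -> tuple[dict[str, Polygon], tuple[int, int]]:
    """Square parcels laid out on a grid; returns polygons and grid shape."""
    per_row = int(np.ceil(np.sqrt(n_parcels)))
    step = parcel_size + gap
    parcels = {}
    for i in range(n_parcels):
        r, c = divmod(i, per_row)
        x0, y0 = gap + c * step, gap + r * step
        parcels[f"p{i:03d}"] = box(x0, y0, x0 + parcel_size, y0 + parcel_size)
    extent = gap + per_row * step
    return parcels, (extent, extent)


def write_parcels_geojson(parcels: dict[str, Polygon], path,
                          crs: str = "pixel",
                          properties: dict[str, dict] | None = None) -> None:
    features = []
    for pid, poly in sorted(parcels.items()):
        props = {"parcel_id": pid}
        props.update((properties or {}).get(pid, {}))
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(poly)})
    doc = {"type": "FeatureCollection", "crs_note": crs, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_parcels_geojson(path) -> dict[str, Polygon]:
    with open(path) as fh:
        doc = json.load(fh)
    return {f["properties"]["parcel_id"]: shape(f["geometry"])
            for f in doc["features"]}
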