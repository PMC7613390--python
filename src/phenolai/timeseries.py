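"""Building the four analysis collections from sensor LAI streams.

S30 and L30 are the single-sensor series, each Savitzky-Golay smoothed.
The combined collections merge both streams into one series and either
smooth it (SL30_SG) or GPR-gap-fill it onto a regular grid (SL30_GPR).

The SG window is index-based (a fixed number of consecutive observations,
default 7, quadratic fit), which is the standard convention for unevenly
spaced acquisitions; edges shrink the window symmetrically down to
degree+1 points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.signal import savgol_coeffs

from .gpr import GaussianProcess
from .raster import SceneStack
from .series import SampledSeries

__all__ = [
    "SGConfig",
    "parcel_average",
    "merge_streams",
    "savgol_smooth",
    "gpr_gapfill",
    "build_collections",
]

SAME_DAY_TOL = 0.5  # observations closer than half a day are coincident


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay filter settings: odd window span, polynomial degree."""

    span: int = 7
    degree: int = 2

    def __post_init__(self):
        if self.span % 2 == 0:
            raise ValueError("span must be odd")
        if self.span <= self.degree:
            raise ValueError("span must exceed polynomial degree")


def parcel_average(pixels, polygon=None, parcel_id: str | None = None) -> SampledSeries:
    """Spatially average pixel LAI series over one parcel.

    `pixels` is either a SceneStack (then `polygon` selects pixels whose
    centres fall inside) or a list of per-pixel SampledSeries on a shared
    date axis. Dates where every contributing pixel is NaN are dropped.
    """
    if isinstance(pixels, SceneStack):
        if polygon is None:
            raise ValueError("polygon required with a SceneStack input")
        x, y = pixels.pixel_xy()
        inside = shapely.contains_xy(polygon, x.ravel(), y.ravel()).reshape(x.shape)
        if not inside.any():
            raise ValueError(f"no pixel centres intersect parcel {parcel_id!r}")
        vals = pixels.data[:, inside]  # (T, npix)
        times = pixels.times
        sensors = pixels.sensors
        epoch_year = pixels.epoch_year
    else:
        series = list(pixels)
        if not series:
            raise ValueError(f"no pixel series for parcel {parcel_id!r}")
        times = series[0].times
        for s in series[1:]:
            if not np.array_equal(s.times, times):
                raise ValueError("pixel series must share a common date axis")
        vals = np.stack([s.values for s in series], axis=1)
        sensors = series[0].sensor
        epoch_year = series[0].epoch_year

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=1)
    keep = np.isfinite(mean)
    return SampledSeries(
        times[keep], mean[keep],
        sensor=None if sensors is None else sensors[keep],
        parcel_id=parcel_id or "parcel", epoch_year=epoch_year)


def merge_streams(a: SampledSeries, b: SampledSeries) -> SampledSeries:
    """Merge two sensor streams of one parcel into a single series.

    The union of dates is sorted ascending; observations from both sensors
    falling on the same day (closer than half a day) are averaged and
    tagged "both". Commutative, and idempotent on its own output.
    """
    if a.parcel_id != b.parcel_id:
        raise ValueError(
            f"cannot merge different parcels: {a.parcel_id!r} vs {b.parcel_id!r}")
    t = np.concatenate([a.times, b.times])
    v = np.concatenate([a.values, b.values])
    sens = np.concatenate([
        a.sensor if a.sensor is not None else np.full(len(a), "a", dtype=object),
        b.sensor if b.sensor is not None else np.full(len(b), "b", dtype=object),
    ])
    order = np.argsort(t, kind="stable")
    t, v, sens = t[order], v[order], sens[order]

    # collapse runs of same-day coincidences
    group = np.zeros(len(t), dtype=int)
    group[1:] = np.cumsum(np.diff(t) >= SAME_DAY_TOL)
    out_t, out_v, out_s = [], [], []
    for g in range(group[-1] + 1):
        m = group == g
        tags = set(sens[m])
        out_t.append(t[m].mean())
        out_v.append(v[m].mean())
        out_s.append(tags.pop() if len(tags) == 1 else "both")
    return SampledSeries(np.array(out_t), np.array(out_v),
                         sensor=np.array(out_s, dtype=object),
                         parcel_id=a.parcel_id, epoch_year=a.epoch_year)


def savgol_smooth(series: SampledSeries, cfg: SGConfig = SGConfig()) -> SampledSeries:
    """Savitzky-Golay smoothing over a moving window of observations.

    Each value is replaced by the degree-`cfg.degree` least-squares fit
    over its `cfg.span`-observation window, evaluated at the centre. At the
    series edges the window shrinks to the largest odd span that fits; a
    window of fewer than degree+1 points leaves the value unchanged (the
    fit would interpolate). Dates are unchanged.
    """
    n = len(series)
    if n < cfg.degree + 1:
        raise ValueError(
            f"series of length {n} is shorter than degree+1={cfg.degree + 1}")
    h = cfg.span // 2
    coeffs = {}
    out = series.values.copy()
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        if 2 * hi + 1 <= cfg.degree:
            continue  # underdetermined: fit reproduces the point
        if hi not in coeffs:
            coeffs[hi] = savgol_coeffs(2 * hi + 1, cfg.degree, use="dot")
        out[i] = coeffs[hi] @ series.values[i - hi:i + hi + 1]
    return series.with_values(out)


def gpr_gapfill(series: SampledSeries, grid_spacing: float = 10.0,
                seed: int = 0, n_restarts: int = 3) -> SampledSeries:
    """GPR fit of the series and prediction on a regular day grid.

    A 1-D GP (squared-exponential kernel in time) is trained on the
    observations by marginal-likelihood maximisation; the mean and
    predictive sd are evaluated every `grid_spacing` days from the first
    observation to the last one it can reach. Output times are strictly
    regular.
    """
    if len(series) < 5:
        raise ValueError("gap-filling needs at least 5 observations")
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    model = GaussianProcess(series.times[:, None], series.values,
                            input_names=["t"])
    try:
        res = model.fit(seed=seed, n_restarts=n_restarts)
    except (RuntimeError, np.linalg.LinAlgError) as err:
        raise RuntimeError(
            f"GPR gap-filling failed for parcel {series.parcel_id!r}: {err}"
        ) from err
    t0, t1 = series.times[0], series.times[-1]
    k = int(np.floor((t1 - t0) / grid_spacing + 1e-9))
    grid = t0 + grid_spacing * np.arange(k + 1)
    mean, var = res.predict(grid[:, None])
    return SampledSeries(grid, mean, sd=np.sqrt(var),
                         sensor=np.full(grid.shape, "gpr", dtype=object),
                         parcel_id=series.parcel_id, epoch_year=series.epoch_year)


def build_collections(s2_series: SampledSeries, l8_series: SampledSeries,
                      sg: SGConfig = SGConfig(), grid_spacing: float = 10.0,
                      seed: int = 0) -> dict[str, SampledSeries]:
    """The four analysis collections for one parcel.

    S30 / L30: each single-sensor stream SG-smoothed. SL30_SG: the merged
    stream SG-smoothed. SL30_GPR: the merged stream GPR-gap-filled onto the
    regular grid (default 10-day).
    """
    merged = merge_streams(s2_series, l8_series)
    return {
        "S30": savgol_smooth(s2_series, sg),
        "L30": savgol_smooth(l8_series, sg),
        "SL30_SG": savgol_smooth(merged, sg),
        "SL30_GPR": gpr_gapfill(merged, grid_spacing=grid_spacing, seed=seed),
    }
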