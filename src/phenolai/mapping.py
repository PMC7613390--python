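"""Per-pixel phenology mapping: cropping frequency, seasonal LSP maps.

Maps are produced on the scene grid from per-pixel season tables. Pixels
whose LAI never exceeds the vegetation threshold (default 1 m2/m2) are
masked and carry no metrics. Summer and winter growth cycles are mapped
separately; a single-cropping pixel carries the same value in both map
sets for its year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calendar import CropCalendar
from .phenology import DetectionConfig, extract_seasons, seasons_to_frame
from .raster import SceneStack
from .series import SampledSeries

__all__ = [
    "vegetation_mask",
    "pixel_phenology",
    "cropping_frequency",
    "lsp_maps",
]

LSP_METRICS = ("sos_doy", "eos_doy", "los_days", "area")


def vegetation_mask(stack, threshold: float = 1.0) -> np.ndarray:
    """True where a pixel is masked: max LAI over time does not exceed
    the threshold."""
    data = stack.data if isinstance(stack, SceneStack) else np.asarray(stack)
    if data.size == 0:
        raise ValueError("empty stack")
    return np.nanmax(data, axis=0) <= threshold


def pixel_phenology(stack: SceneStack, cfg: DetectionConfig = DetectionConfig(),
                    calendar: CropCalendar | None = None,
                    mask: np.ndarray | None = None,
                    mask_threshold: float = 1.0) -> pd.DataFrame:
    """Season table for every unmasked pixel of an LAI stack.

    Returns the season export table with added integer `row` / `col`
    columns locating each season's pixel.
    """
    if stack.data.ndim != 3:
        raise ValueError("pixel phenology expects an LAI stack (T,H,W)")
    if mask is None:
        mask = vegetation_mask(stack, mask_threshold)
    h, w = stack.shape
    frames = []
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                continue
            vals = stack.data[:, r, c]
            ok = np.isfinite(vals)
            if ok.sum() < 5:
                continue
            series = SampledSeries(stack.times[ok], vals[ok],
                                   parcel_id=f"px_{r}_{c}",
                                   epoch_year=stack.epoch_year)
            seasons = extract_seasons(series, cfg, calendar=calendar)
            if seasons:
                df = seasons_to_frame(seasons)
                df["row"], df["col"] = r, c
                frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def cropping_frequency(pixel_seasons: pd.DataFrame, year: int,
                       shape: tuple[int, int],
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Number of growth cycles with SOS in `year` per pixel.

    Masked or never-observed pixels are NaN (no-data).
    """
    freq = np.zeros(shape, dtype=float)
    if len(pixel_seasons):
        sel = pixel_seasons[pixel_seasons["year"] == year]
        for (r, c), grp in sel.groupby(["row", "col"]):
            freq[int(r), int(c)] = len(grp)
    if mask is not None:
        freq[mask] = np.nan
    return freq


def lsp_maps(pixel_seasons: pd.DataFrame, year: int, shape: tuple[int, int],
             mask: np.ndarray | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Summer/winter map sets of SOS, EOS, LOS and Area for one year.

    Double-cropping pixels route each season to its class map; pixels with
    a single season that year carry it in both map sets; pixels with no
    season of a class stay no-data (NaN).
    """
    maps = {cls: {m: np.full(shape, np.nan) for m in LSP_METRICS}
            for cls in ("summer", "winter")}
    if len(pixel_seasons):
        sel = pixel_seasons[pixel_seasons["year"] == year]
        for (r, c), grp in sel.groupby(["row", "col"]):
            r, c = int(r), int(c)
            targets = {}
            if len(grp) == 1:
                targets["summer"] = targets["winter"] = grp.iloc[0]
            else:
                for cls in ("summer", "winter"):
                    g = grp[grp["season_class"] == cls]
                    if len(g):
                        targets[cls] = g.iloc[0]
            for cls, row in targets.items():
                for m in LSP_METRICS:
                    maps[cls][m][r, c] = row[m]
    if mask is not None:
        for cls in maps:
            for m in maps[cls]:
                maps[cls][m][mask] = np.nan
    return maps
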