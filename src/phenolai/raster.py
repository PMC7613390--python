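"""Small raster time-series container with TIFF + JSON-manifest persistence.

A SceneStack holds one image per acquisition date: either a single-band LAI
(or LAI-sd) layer, shape (T, H, W), or a multiband reflectance layer, shape
(T, B, H, W). Georeferencing is carried as an affine 6-tuple plus a CRS
string in the JSON manifest; pixel (row, col) centres map to world
coordinates via the transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["SceneStack"]

IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)  # x = c + col, y = f + row


@dataclass
class SceneStack:
    data: np.ndarray                      # (T, H, W) or (T, B, H, W)
    times: np.ndarray                     # days since epoch
    sensors: np.ndarray                   # per-date sensor tag
    epoch_year: int = 2016
    band_names: tuple[str, ...] | None = None
    transform: tuple = IDENTITY_TRANSFORM  # (a, b, c, d, e, f): x=a*col+b*row+c
    crs: str = "pixel"
    parcel_map: np.ndarray | None = None  # (H, W) int parcel index, -1 outside
    nodata: float = np.nan

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.sensors = np.asarray(self.sensors, dtype=object)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (T,H,W) or (T,B,H,W)")
        if self.data.shape[0] != len(self.times):
            raise ValueError("first axis must match number of dates")
        h, w = self.shape
        if h == 0 or w == 0:
            raise ValueError("zero-area grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    @property
    def ntimes(self) -> int:
        return len(self.times)

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        """Time series at one pixel; (T,) for LAI stacks, (T,B) for spectral."""
        if self.data.ndim == 3:
            return self.data[:, row, col]
        return self.data[:, :, row, col]

    def pixel_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """World x/y coordinates of all pixel centres, each (H, W)."""
        h, w = self.shape
        cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
        a, b, c, d, e, f = self.transform
        return a * cols + b * rows + c, d * cols + e * rows + f

    # -- persistence --------------------------------------------------------

    def save(self, directory, prefix: str = "scene") -> Path:
        """Write one TIFF per date plus a JSON manifest; returns manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from .series import day_to_date

        dates = day_to_date(self.times, self.epoch_year).strftime("%Y-%m-%d")
        entries = []
        for i, (date, sensor) in enumerate(zip(dates, self.sensors)):
            fname = f"{prefix}_{i:04d}_{date}_{sensor}.tif"
            tifffile.imwrite(directory / fname, self.data[i].astype(np.float32))
            entries.append({"file": fname, "date": str(date),
                            "sensor": str(sensor), "time_days": self.times[i]})
        manifest = {
            "epoch_year": self.epoch_year,
            "transform": list(self.transform),
            "crs": self.crs,
            "band_names": list(self.band_names) if self.band_names else None,
            "images": entries,
        }
        if self.parcel_map is not None:
            tifffile.imwrite(directory / f"{prefix}_parcels.tif",
                             self.parcel_map.astype(np.int32))
            manifest["parcel_map"] = f"{prefix}_parcels.tif"
        mpath = directory / f"{prefix}_manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return mpath

    @classmethod
    def load(cls, manifest_path) -> "SceneStack":
        manifest_path = Path(manifest_path)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        directory = manifest_path.parent
        data = np.stack([
            tifffile.imread(directory / e["file"]) for e in manifest["images"]
        ]).astype(float)
        parcel_map = None
        if manifest.get("parcel_map"):
            parcel_map = tifffile.imread(directory / manifest["parcel_map"])
        bn = manifest.get("band_names")
        return cls(
            data=data,
            times=np.array([e["time_days"] for e in manifest["images"]]),
            sensors=np.array([e["sensor"] for e in manifest["images"]], dtype=object),
            epoch_year=manifest["epoch_year"],
            band_names=tuple(bn) if bn else None,
            transform=tuple(manifest["transform"]),
            crs=manifest["crs"],
            parcel_map=parcel_map,
        )
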