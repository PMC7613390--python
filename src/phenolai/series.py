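"""Time-stamped LAI series and calendar-day helpers.

The whole workflow runs on a continuous time axis of *days since epoch*,
where the epoch is 1 January of the first simulated/observed year. Calendar
conversions (day-of-year reporting, season-year assignment) go through real
dates, but length-of-season arithmetic on reported DOY statistics uses a
365-day year, which is the convention of the field's summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SampledSeries",
    "day_to_date",
    "day_to_doy",
    "day_to_year",
    "doy_to_day",
    "los_from_doy",
]


def day_to_date(day: float | np.ndarray, epoch_year: int):
    """Convert days-since-epoch to pandas timestamps (epoch = 1 Jan epoch_year)."""
    epoch = pd.Timestamp(year=epoch_year, month=1, day=1)
    return epoch + pd.to_timedelta(np.asarray(day, dtype=float), unit="D")


def day_to_doy(day: float | np.ndarray, epoch_year: int) -> np.ndarray:
    """1-based day-of-year of the calendar date at `day` (fractional part kept)."""
    d = np.atleast_1d(np.asarray(day, dtype=float))
    dates = day_to_date(np.floor(d), epoch_year)
    doy = np.asarray(dates.dayofyear, dtype=float) + (d - np.floor(d))
    return doy if np.ndim(day) else float(doy[0])


def day_to_year(day: float | np.ndarray, epoch_year: int):
    d = np.atleast_1d(np.asarray(day, dtype=float))
    years = np.asarray(day_to_date(np.floor(d), epoch_year).year, dtype=int)
    return years if np.ndim(day) else int(years[0])


def doy_to_day(doy: float, year: int, epoch_year: int) -> float:
    """Absolute day (days since epoch) of a 1-based DOY in `year`."""
    start = (pd.Timestamp(year=year, month=1, day=1)
             - pd.Timestamp(year=epoch_year, month=1, day=1)).days
    return start + float(doy) - 1.0


def los_from_doy(sos_doy: float, eos_doy: float) -> float:
    """Length of season from reported SOS/EOS day-of-year values.

    Winter seasons green up in autumn and senesce the following spring, so
    EOS DOY < SOS DOY; the wrap across 31 December uses a 365-day year:
    ``los = (eos - sos) mod 365``.
    """
    return float((eos_doy - sos_doy) % 365.0)


@dataclass
class SampledSeries:
    """An irregularly sampled LAI time series for one parcel or pixel.

    Parameters
    ----------
    times : array of float
        Days since epoch, strictly increasing.
    values : array of float
        Green LAI (m2/m2).
    sd : array of float, optional
        Per-point 1-sigma uncertainty (e.g. GPR predictive sd).
    sensor : array of str, optional
        Per-point sensor tag ("S2", "L8", "both", "gpr", ...).
    """

    times: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    sensor: np.ndarray | None = None
    parcel_id: str = "parcel"
    epoch_year: int = 2016

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) == 0:
            raise ValueError(f"empty series for parcel {self.parcel_id!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd length mismatch")
        if self.sensor is not None:
            self.sensor = np.asarray(self.sensor, dtype=object)
            if self.sensor.shape != self.times.shape:
                raise ValueError("sensor length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    def with_values(self, values, sd=None) -> "SampledSeries":
        return replace(self, values=np.asarray(values, dtype=float), sd=sd)

    @property
    def doy(self) -> np.ndarray:
        return day_to_doy(self.times, self.epoch_year)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                # full ISO-8601 timestamps: day-of-year jitter survives a
                # CSV round trip without collapsing distinct acquisitions
                "date": day_to_date(self.times, self.epoch_year)
                .strftime("%Y-%m-%dT%H:%M:%S"),
                "sensor": self.sensor if self.sensor is not None else "",
                "lai": self.values,
                "lai_sd": self.sd if self.sd is not None else np.nan,
            }
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch_year: int | None = None) -> "SampledSeries":
        dates = pd.to_datetime(df["date"])
        if epoch_year is None:
            epoch_year = int(dates.dt.year.min())
        epoch = pd.Timestamp(year=epoch_year, month=1, day=1)
        times = (dates - epoch).dt.total_seconds().to_numpy() / 86400.0
        order = np.argsort(times)
        sd = df["lai_sd"].to_numpy()[order] if "lai_sd" in df else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        sensor = df["sensor"].astype(str).to_numpy()[order] if "sensor" in df else None
        pid = str(df["parcel_id"].iloc[0]) if "parcel_id" in df else "parcel"
        return cls(times[order], df["lai"].to_numpy()[order], sd=sd, sensor=sensor,
                   parcel_id=pid, epoch_year=epoch_year)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch_year: int | None = None) -> "SampledSeries":
        return cls.from_frame(pd.read_csv(path), epoch_year=epoch_year)


def read_series_csv(path, epoch_year: int | None = None) -> dict[str, SampledSeries]:
    """Read a multi-parcel series CSV into a dict keyed by parcel id."""
    df = pd.read_csv(path)
    if epoch_year is None:
        epoch_year = int(pd.to_datetime(df["date"]).dt.year.min())
    return {
        str(pid): SampledSeries.from_frame(g, epoch_year=epoch_year)
        for pid, g in df.groupby("parcel_id")
    }


def write_series_csv(path, series: dict[str, SampledSeries] | list[SampledSeries]) -> None:
    items = series.values() if isinstance(series, dict) else series
    pd.concat([s.to_frame() for s in items], ignore_index=True).to_csv(path, index=False)
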