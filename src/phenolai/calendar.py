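"""Crop calendars: reference planting/harvest days per crop.

A calendar provides the fixed agronomic reference frame against which
detected growing seasons are labelled and scored. Winter crops wrap the
year boundary (harvest DOY < planting DOY).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CropCalendar", "nile_delta_calendar", "SUMMER_DOY_RANGE"]

# A start-of-season falling in [SUMMER_DOY_RANGE) is a summer-class season;
# anything else (autumn green-up, or a delayed winter green-up in Jan-Mar)
# is winter-class.
SUMMER_DOY_RANGE = (91, 245)  # 1 Apr .. 1 Sep (non-leap)


@dataclass(frozen=True)
class CropCalendar:
    """Map crop name -> (planting_doy, harvest_doy), 1-based day of year."""

    entries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for crop, (p, h) in self.entries.items():
            if not (1 <= p <= 366 and 1 <= h <= 366):
                raise ValueError(f"calendar DOYs out of [1,366] for crop {crop!r}")

    def __contains__(self, crop: str) -> bool:
        return crop in self.entries

    def planting_doy(self, crop: str) -> int:
        self._check(crop)
        return self.entries[crop][0]

    def harvest_doy(self, crop: str) -> int:
        self._check(crop)
        return self.entries[crop][1]

    def season_class(self, crop: str) -> str:
        """'summer' or 'winter' depending on the planting window."""
        p = self.planting_doy(crop)
        return "summer" if SUMMER_DOY_RANGE[0] <= p < SUMMER_DOY_RANGE[1] else "winter"

    def crops(self) -> list[str]:
        return list(self.entries)

    def _check(self, crop: str) -> None:
        if crop not in self.entries:
            raise KeyError(
                f"crop {crop!r} not in calendar (known: {sorted(self.entries)})"
            )


def nile_delta_calendar() -> CropCalendar:
    """Reference calendar for the Nile-Delta cropping system.

    Summer: rice (15 May - 10 Oct), maize (1 May - 10 Aug).
    Winter: wheat (10 Nov - 1 May), clover (1 Oct - 1 May).
    DOYs on a non-leap year.
    """
    return CropCalendar(
        entries={
            "rice": (135, 283),
            "maize": (121, 222),
            "wheat": (314, 121),
            "clover": (274, 121),
        }
    )


def season_class_of_doy(sos_doy: float) -> str:
    """Season class of a start-of-season day-of-year."""
    return "summer" if SUMMER_DOY_RANGE[0] <= sos_doy < SUMMER_DOY_RANGE[1] else "winter"
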