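"""Spectral band sets for the two sensor dialects.

Two harmonized 30 m reflectance dialects are supported: a Sentinel-2-like
10-band set (visible, red edge, NIR, SWIR) and a Landsat-8-like 6-band set
(the shared bands only). Band order is fixed and documented here; the
S2 -> L8 mapping pairs shared bands by nearest centre wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandSet", "S2_10BAND", "L8_6BAND", "get_band_set", "S2_TO_L8_COLUMNS"]


@dataclass(frozen=True)
class BandSet:
    dialect: str
    band_names: tuple[str, ...]
    center_wavelengths: tuple[int, ...]  # nm

    def __post_init__(self):
        if len(self.band_names) != len(self.center_wavelengths):
            raise ValueError("band names / wavelengths length mismatch")

    @property
    def nbands(self) -> int:
        return len(self.band_names)


S2_10BAND = BandSet(
    dialect="S2-10band",
    band_names=("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"),
    center_wavelengths=(490, 560, 665, 705, 740, 783, 842, 865, 1610, 2190),
)

L8_6BAND = BandSet(
    dialect="L8-6band",
    band_names=("B2", "B3", "B4", "B5", "B6", "B7"),
    center_wavelengths=(480, 560, 655, 865, 1610, 2200),
)

# Columns of the 10-band table that correspond to the 6 shared bands
# (S2 B2,B3,B4,B8A,B11,B12 -> L8 B2,B3,B4,B5,B6,B7 by nearest wavelength).
S2_TO_L8_COLUMNS = (0, 1, 2, 7, 8, 9)

_REGISTRY = {bs.dialect: bs for bs in (S2_10BAND, L8_6BAND)}


def get_band_set(band_set: "BandSet | str") -> BandSet:
    if isinstance(band_set, BandSet):
        return band_set
    try:
        return _REGISTRY[band_set]
    except KeyError:
        raise ValueError(
            f"unknown band set {band_set!r}; known: {sorted(_REGISTRY)}"
        ) from None
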