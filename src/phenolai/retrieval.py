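"""Multiband green-LAI retrieval with per-sensor GPR models.

A GPR model is trained on paired (reflectance, LAI) samples for each
sensor dialect (10-band S2-like, 6-band L8-like) and applied per pixel or
per table row, yielding an LAI estimate plus its predictive standard
deviation. The inverse lengthscale of each band measures that band's
relevance in the trained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandSet, S2_TO_L8_COLUMNS, get_band_set
from .gpr import GaussianProcess, GPRResults
from .raster import SceneStack

__all__ = [
    "train_lai_model",
    "resample_pairs_to_l8",
    "band_relevance",
    "retrieve_lai",
    "RetrievalResult",
]

log = logging.getLogger(__name__)


@dataclass
class RetrievalResult:
    """Retrieved LAI and its predictive sd, same shape as the input."""

    lai: np.ndarray
    lai_sd: np.ndarray
    model_id: str
    n_clipped: int = 0  # negative predictions clipped to zero


def train_lai_model(pairs: pd.DataFrame, band_set: BandSet | str,
                    seed: int = 0, n_restarts: int = 3) -> GPRResults:
    """Fit a GPR LAI model on a spectra-LAI table for one dialect.

    The table must contain one column per band of the dialect (in band
    order) and a 'lai' column.
    """
    bs = get_band_set(band_set)
    missing = [b for b in bs.band_names if b not in pairs.columns]
    width = len([c for c in pairs.columns if c != "lai"])
    if missing:
        raise ValueError(
            f"pairs table (width {width}) does not match dialect "
            f"{bs.dialect!r}: missing bands {missing}"
        )
    X = pairs[list(bs.band_names)].to_numpy(dtype=float)
    y = pairs["lai"].to_numpy(dtype=float)
    model = GaussianProcess(X, y, input_names=list(bs.band_names),
                            metadata={"dialect": bs.dialect})
    return model.fit(seed=seed, n_restarts=n_restarts)


def resample_pairs_to_l8(pairs10: pd.DataFrame) -> pd.DataFrame:
    """Resample a 10-band training table to the 6-band dialect.

    With synthetic spectra the band adaptation reduces to selecting the six
    shared-band columns by nearest centre wavelength
    (S2 B2,B3,B4,B8A,B11,B12 -> L8 B2..B7).
    """
    from .bands import L8_6BAND, S2_10BAND

    cols = [S2_10BAND.band_names[i] for i in S2_TO_L8_COLUMNS]
    out = pairs10[cols].copy()
    out.columns = list(L8_6BAND.band_names)
    out["lai"] = pairs10["lai"].to_numpy()
    return out


def band_relevance(model: GPRResults) -> dict[str, float]:
    """Per-band relevance 1/sigma_b, keyed by band name."""
    return model.band_relevance()


def _model_dialect(model: GPRResults) -> str:
    return model.model.metadata.get("dialect", f"D={model.model.ndim}")


def retrieve_lai(model: GPRResults, stack) -> RetrievalResult:
    """Apply a trained LAI model to a reflectance stack or table.

    Accepts a SceneStack with data (T, B, H, W), a DataFrame with band
    columns, or a plain (n, B) array. NaN inputs propagate to NaN outputs;
    negative LAI predictions are clipped to 0 and counted.
    """
    nb = model.model.ndim
    if isinstance(stack, SceneStack):
        if stack.data.ndim != 4 or stack.data.shape[1] != nb:
            raise ValueError(
                f"stack band count does not match model dialect "
                f"{_model_dialect(model)!r} (expected {nb} bands)")
        t, b, h, w = stack.data.shape
        flat = stack.data.transpose(0, 2, 3, 1).reshape(-1, nb)
        res = _predict_rows(model, flat)
        return RetrievalResult(
            lai=res.lai.reshape(t, h, w), lai_sd=res.lai_sd.reshape(t, h, w),
            model_id=res.model_id, n_clipped=res.n_clipped)
    if isinstance(stack, pd.DataFrame):
        names = model.model.input_names
        if not all(n in stack.columns for n in names):
            raise ValueError(
                f"table columns do not match model dialect {_model_dialect(model)!r}")
        return _predict_rows(model, stack[names].to_numpy(dtype=float))
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != nb:
        raise ValueError(
            f"input width {arr.shape[-1]} does not match model dialect "
            f"{_model_dialect(model)!r} (expected {nb})")
    return _predict_rows(model, arr)


def _predict_rows(model: GPRResults, X: np.ndarray) -> RetrievalResult:
    lai = np.full(len(X), np.nan)
    sd = np.full(len(X), np.nan)
    ok = np.all(np.isfinite(X), axis=1)
    if ok.any():
        mean, var = model.predict(X[ok])
        sd[ok] = np.sqrt(var)
        lai[ok] = mean
    neg = lai < 0
    n_clipped = int(np.nansum(neg))
    if n_clipped:
        log.info("clipped %d negative LAI predictions to 0", n_clipped)
        lai[neg] = 0.0
    return RetrievalResult(lai=lai, lai_sd=sd,
                           model_id=_model_dialect(model), n_clipped=n_clipped)
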