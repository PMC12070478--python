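"""Photoreceptor spectral sensitivity and reflectance handling.

Sensitivity curves use the standard A1 visual-pigment template
(Govardovskii et al. 2000): the alpha band is

    S(x) = 1 / (exp(A*(a - x)) + exp(B*(b - x)) + exp(C*(c - x)) + D)

with x = lambda_max / lambda, A = 69.7, B = 28, C = -14.9, D = 0.674,
b = 0.922, c = 1.104 and a = 0.8795 + 0.0459 * exp(-(lambda_max - 300)**2
/ 11940).  The beta (short-wavelength) band is available behind a flag and
is off by default.  Reflectance spectra are averaged pointwise on a common
1 nm grid and max-normalised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCurve",
    "pigment_sensitivity",
    "sensitivity_curve",
    "load_and_average_reflectance",
    "quantum_catch",
]

logger = logging.getLogger(__name__)

_WL_MIN, _WL_MAX = 250.0, 900.0

# A1 alpha-band template constants
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


@dataclass(frozen=True)
class SpectralCurve:
    """A spectrum on an ascending wavelength grid, max-normalised to 1."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.size == 0 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be nonempty and equal length")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(vals < 0) or np.any(vals > 1 + 1e-12):
            raise ValueError("values must lie in [0, 1]")
        if not np.isclose(vals.max(), 1.0):
            raise ValueError("curve must be normalised to max 1")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_raw(cls, wavelengths_nm, values) -> "SpectralCurve":
        """Build a curve from raw values, max-normalising them."""
        vals = np.asarray(values, dtype=float)
        peak = vals.max()
        if peak <= 0:
            raise ValueError("cannot normalise a non-positive spectrum")
        return cls(np.asarray(wavelengths_nm, dtype=float), vals / peak)

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "value": self.values}
        )


def _alpha_band(lam: np.ndarray, lambda_max_nm: float) -> np.ndarray:
    x = lambda_max_nm / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )


def _beta_band(lam: np.ndarray, lambda_max_nm: float) -> np.ndarray:
    lam_mb = 189.0 + 0.315 * lambda_max_nm
    b_beta = -40.5 + 0.195 * lambda_max_nm
    return 0.26 * np.exp(-(((lam - lam_mb) / b_beta) ** 2))


def pigment_sensitivity(lambda_nm: float, lambda_max_nm: float) -> float:
    """A1 alpha-band template sensitivity at ``lambda_nm`` for a pigment
    peaking at ``lambda_max_nm``.  Peak-normalised: equals 1 at the peak."""
    for name, v in (("lambda_nm", lambda_nm), ("lambda_max_nm", lambda_max_nm)):
        if not _WL_MIN <= v <= _WL_MAX:
            raise ValueError(f"{name}={v} nm outside [{_WL_MIN}, {_WL_MAX}] nm")
    raw = float(_alpha_band(np.asarray([lambda_nm], dtype=float), lambda_max_nm)[0])
    # the template's maximum over lambda is its value at lambda_max
    peak = float(_alpha_band(np.asarray([lambda_max_nm], dtype=float), lambda_max_nm)[0])
    return raw / peak


def sensitivity_curve(
    lambda_max_nm: float,
    grid: Sequence[float] | np.ndarray,
    beta_band: bool = False,
) -> SpectralCurve:
    """Spectral-sensitivity curve on ``grid`` for a pigment peaking at
    ``lambda_max_nm``; optionally adds the short-wavelength beta band."""
    lam = np.asarray(grid, dtype=float)
    if lam.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(lam < _WL_MIN) or np.any(lam > _WL_MAX):
        raise ValueError(f"grid must lie within [{_WL_MIN}, {_WL_MAX}] nm")
    vals = _alpha_band(lam, lambda_max_nm)
    if beta_band:
        vals = vals + _beta_band(lam, lambda_max_nm)
    return SpectralCurve.from_raw(lam, vals)


def _as_spectrum(measurement) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(measurement, (str, Path)):
        df = pd.read_csv(measurement)
        cols = df.columns[:2]
        return df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float)
    if isinstance(measurement, pd.DataFrame):
        cols = measurement.columns[:2]
        return (
            measurement[cols[0]].to_numpy(float),
            measurement[cols[1]].to_numpy(float),
        )
    wl, vals = measurement
    return np.asarray(wl, dtype=float), np.asarray(vals, dtype=float)


def load_and_average_reflectance(measurements: Iterable) -> SpectralCurve:
    """Average repeat reflectance measurements into one normalised curve.

    Each measurement is a two-column CSV path, a DataFrame, or a
    ``(wavelengths, values)`` pair.  Spectra are linearly interpolated onto
    a 1 nm grid spanning the intersection of their wavelength ranges,
    averaged pointwise, clamped at zero (negative spectrometer readings are
    noise) and max-normalised.
    """
    spectra = [_as_spectrum(m) for m in measurements]
    if not spectra:
        raise ValueError("at least one measurement is required")
    lo = max(wl.min() for wl, _ in spectra)
    hi = min(wl.max() for wl, _ in spectra)
    if lo > hi:
        raise ValueError(
            f"wavelength ranges are disjoint (common range [{lo}, {hi}] empty)"
        )
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    if grid.size == 0:
        raise ValueError("common wavelength range narrower than 1 nm")
    stack = np.vstack([np.interp(grid, wl, vals) for wl, vals in spectra])
    mean = stack.mean(axis=0)
    if np.any(mean < 0):
        warnings.warn(
            "negative reflectance values clamped to 0", UserWarning, stacklevel=2
        )
        logger.info(
            "clamped %d negative reflectance values to 0", int(np.sum(mean < 0))
        )
        mean = np.clip(mean, 0.0, None)
    return SpectralCurve.from_raw(grid, mean)


def quantum_catch(*args, **kwargs):
    """Receptor quantum catch / receptor contrast is intentionally not
    implemented: the toolkit overlays sensitivity and reflectance curves but
    performs no receptor-noise colour modelling."""
    raise NotImplementedError(
        "quantum-catch computation is outside the scope of this toolkit"
    )
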