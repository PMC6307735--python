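"""Line-shape primitives shared by the spectrum renderers and the fitters.

1D peaks are pseudo-Voigt (Lorentzian fraction ``eta``); 2D HSQC peaks are
Gaussian in both dimensions.  All shapes are parameterized by *area* so that
fitted amplitudes are integrals directly.
"""

from __future__ import annotations

import numpy as np

#: default 1D full width at half maximum, Hz
FWHM_1D_HZ = 1.5
#: default Lorentzian fraction of 1D peaks
ETA_1D = 0.3

_GAUSS_NORM = 2.0 * np.sqrt(np.log(2.0) / np.pi)


def gaussian(x: np.ndarray, area: float, center: float, fwhm: float) -> np.ndarray:
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return area * _GAUSS_NORM / fwhm * np.exp(-0.5 * ((x - center) / s) ** 2)


def lorentzian(x: np.ndarray, area: float, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return area * hwhm / (np.pi * ((x - center) ** 2 + hwhm ** 2))


def pseudo_voigt(x: np.ndarray, area: float, center: float, fwhm: float,
                 eta: float = ETA_1D) -> np.ndarray:
    return (eta * lorentzian(x, area, center, fwhm)
            + (1.0 - eta) * gaussian(x, area, center, fwhm))


def doublet(x: np.ndarray, area: float, center: float, j_ppm: float,
            fwhm: float, eta: float = ETA_1D) -> np.ndarray:
    """Symmetric 1:1 doublet with splitting ``j_ppm`` and total area ``area``."""
    return (pseudo_voigt(x, area / 2.0, center - j_ppm / 2.0, fwhm, eta)
            + pseudo_voigt(x, area / 2.0, center + j_ppm / 2.0, fwhm, eta))


def multiplet(x: np.ndarray, area: float, center: float, spacing_ppm: float,
              weights: tuple[float, ...], fwhm: float,
              eta: float = ETA_1D) -> np.ndarray:
    """Symmetric multiplet: lines at center + k*spacing with given weights."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    n = len(w)
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing_ppm
    out = np.zeros_like(x)
    for wi, oi in zip(w, offsets):
        out += pseudo_voigt(x, area * wi, center + oi, fwhm, eta)
    return out


def gaussian2d(h: np.ndarray, c: np.ndarray, volume: float,
               h_center: float, c_center: float,
               h_fwhm: float, c_fwhm: float) -> np.ndarray:
    """2D Gaussian peak of integral ``volume`` on the (c, h) grid (outer product)."""
    sh = h_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sc = c_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gh = np.exp(-0.5 * ((h - h_center) / sh) ** 2) / (sh * np.sqrt(2 * np.pi))
    gc = np.exp(-0.5 * ((c - c_center) / sc) ** 2) / (sc * np.sqrt(2 * np.pi))
    return volume * np.outer(gc, gh)
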