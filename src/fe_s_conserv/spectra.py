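"""UV absorbance derivative spectroscopy and simple spectro-chemistry.

Fourth-derivative analysis sharpens the aromatic fine structure of a protein
absorbance spectrum: the tryptophan band of a folded protein red-shifts to
~293 nm relative to free-chromophore references (NATA/NAYA/Phe mixed at the
protein's aromatic composition).  Derivatives are computed with a
Savitzky-Golay filter; peak positions are refined below the sampling step by
parabolic interpolation.  Also here: the composition-matched reference
mixture and Ellman (DTNB) thiol stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Spectrum",
    "derivative_spectrum",
    "band_positions",
    "reference_mixture",
    "thiol_ratio",
]


@dataclass
class Spectrum:
    """Uniformly sampled spectrum: wavelengths (nm) vs values."""

    wavelengths: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D")
        if len(self.wavelengths) < 3:
            raise ValueError("spectrum too short")
        steps = np.diff(self.wavelengths)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.ptp(steps) > 1e-6:
            warnings.warn("non-uniform sampling; resampling by linear "
                          "interpolation", stacklevel=2)
            step = float(np.median(steps))
            grid = np.arange(self.wavelengths[0], self.wavelengths[-1] + 0.5 * step,
                             step)
            self.values = np.interp(grid, self.wavelengths, self.values)
            self.wavelengths = grid
            self.metadata["resampled"] = True

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


def derivative_spectrum(s: Spectrum, window_points: int = 11,
                        poly_order: int = 5, deriv_order: int = 4) -> Spectrum:
    """Savitzky-Golay derivative of a spectrum.

    The half-window edge regions, where the convolution kernel runs off the
    data, are set to NaN and listed in the output metadata.
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if poly_order < deriv_order:
        raise ValueError("poly_order must be >= deriv_order")
    if window_points <= poly_order:
        raise ValueError("window_points must exceed poly_order")
    vals = savgol_filter(s.values, window_points, poly_order,
                         deriv=deriv_order, delta=s.step)
    half = window_points // 2
    vals = vals.astype(float)
    vals[:half] = np.nan
    vals[-half:] = np.nan
    meta = dict(s.metadata)
    meta.update({"window_points": window_points, "poly_order": poly_order,
                 "deriv_order": deriv_order, "invalid_edge_points": half})
    return Spectrum(wavelengths=s.wavelengths.copy(), values=vals, metadata=meta)


def band_positions(d4: Spectrum, range_nm: tuple[float, float] | None = None,
                   min_prominence: float = 0.05) -> list[float]:
    """Local maxima of a (derivative) spectrum, sub-step refined.

    ``min_prominence`` is a fraction of the value range within ``range_nm``;
    peaks are refined by fitting a parabola through the three points around
    each maximum.  A flat spectrum yields an empty list.
    """
    wl, v = d4.wavelengths, d4.values
    if range_nm is not None:
        lo, hi = range_nm
        if hi <= lo:
            raise ValueError("empty wavelength range")
        mask = (wl >= lo) & (wl <= hi)
        wl, v = wl[mask], v[mask]
    ok = np.isfinite(v)
    wl, v = wl[ok], v[ok]
    if len(v) < 3:
        return []
    span = float(v.max() - v.min())
    if span == 0.0:
        return []
    idx, _ = find_peaks(v, prominence=min_prominence * span)
    out = []
    for i in idx:
        if 0 < i < len(v) - 1:
            y0, y1, y2 = v[i - 1], v[i], v[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            out.append(float(wl[i] + delta * (wl[1] - wl[0])))
        else:
            out.append(float(wl[i]))
    return out


def reference_mixture(protein_conc_uM: float, n_trp: int, n_tyr: int,
                      n_phe: int) -> tuple[float, float, float]:
    """Chromophore concentrations (uM NATA, NAYA, Phe) matching a protein.

    Each free-chromophore concentration is the protein concentration times
    the count of the corresponding aromatic residue.
    """
    if protein_conc_uM < 0 or min(n_trp, n_tyr, n_phe) < 0:
        raise ValueError("inputs must be non-negative")
    return (protein_conc_uM * n_trp, protein_conc_uM * n_tyr,
            protein_conc_uM * n_phe)


def thiol_ratio(delta_A: float, epsilon_TNB: float, protein_conc_M: float,
                path_cm: float = 1.0) -> float:
    """Free thiols per protein molecule from an Ellman endpoint.

    ratio = dA / (epsilon_TNB * [protein] * path).  epsilon_TNB must be
    supplied for the detection wavelength actually used (the assay here was
    monitored at 425 nm, not the canonical 412 nm, so no default is safe).
    """
    if epsilon_TNB <= 0 or protein_conc_M <= 0 or path_cm <= 0:
        raise ValueError("epsilon, concentration and path must be positive")
    return delta_A / (epsilon_TNB * protein_conc_M * path_cm)
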