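"""Spectral preprocessing: region exclusion, Savitzky-Golay derivatives,
and the three normalization schemes (area, min-max, vector).

The composed pipeline (:func:`run_preprocess`) runs, in order:
transmittance -> absorbance; Savitzky-Golay differentiation on the full
contiguous grid (vector path only); exclusion of the water-vapor and the
two CO2 regions; then the configured normalization computed over the
retained points only.  Derivatives are taken before region removal so the
sliding polynomial filter never straddles an excision boundary, and
normalization comes last so its constants use only retained points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet, SpectrumError, to_absorbance

#: Regions the workflow excises before statistics: water vapor
#: (4000-3500 cm^-1) and the two atmospheric CO2 windows.
DEFAULT_EXCLUDED_REGIONS: tuple[tuple[float, float], ...] = (
    (4000.0, 3500.0),
    (2442.0, 2208.0),
    (914.0, 600.0),
)

NORMALIZATION_METHODS = ("area", "minmax", "vector")


class ConfigError(ValueError):
    """Raised for inconsistent preprocessing configurations."""


def _canon_region(r) -> tuple[float, float]:
    lo, hi = sorted(float(v) for v in r)
    return (hi, lo)  # stored (high, low) to match descending grids


@dataclass
class PreprocessConfig:
    """One preprocessing recipe.

    ``method`` selects the normalization; derivatives (``derivative_order``
    1 or 2, Savitzky-Golay with ``sg_window`` points, default 9, and a
    polynomial of ``sg_poly_order``) are only meaningful on the vector
    path, mirroring the workflow where area/min-max operate on plain
    absorbance spectra.
    """

    method: str = "vector"
    derivative_order: int = 0
    sg_window: int = 9
    sg_poly_order: int = 2
    excluded_regions: tuple = DEFAULT_EXCLUDED_REGIONS

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ConfigError(f"unknown normalization method {self.method!r}")
        if self.derivative_order not in (0, 1, 2):
            raise ConfigError("derivative_order must be 0, 1 or 2")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_poly_order:
            raise ConfigError("sg_window must be odd and > sg_poly_order")
        if self.sg_poly_order < self.derivative_order:
            raise ConfigError("sg_poly_order must be >= derivative_order")
        if self.derivative_order > 0 and self.method != "vector":
            raise ConfigError(
                "derivatives are applied on the vector-normalization path only; "
                f"method={self.method!r} with derivative_order="
                f"{self.derivative_order} is inconsistent")
        regions = tuple(_canon_region(r) for r in self.excluded_regions)
        for i, (hi_a, lo_a) in enumerate(regions):
            for hi_b, lo_b in regions[i + 1:]:
                if not (hi_a < lo_b or hi_b < lo_a):
                    raise ConfigError(
                        f"excluded regions overlap: [{lo_a},{hi_a}] and [{lo_b},{hi_b}]")
        self.excluded_regions = regions

    # serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "derivative_order": self.derivative_order,
            "sg_window": self.sg_window,
            "sg_poly_order": self.sg_poly_order,
            "excluded_regions": [[hi, lo] for hi, lo in self.excluded_regions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if "excluded_regions" in d:
            d["excluded_regions"] = tuple(tuple(r) for r in d["excluded_regions"])
        return cls(**d)


def remove_regions(s: SpectrumSet, regions=DEFAULT_EXCLUDED_REGIONS) -> SpectrumSet:
    """Drop grid points lying inside any closed interval of ``regions``."""
    if not regions:
        return s
    wn = s.wavenumbers
    keep = np.ones(wn.size, dtype=bool)
    for r in regions:
        hi, lo = _canon_region(r)
        keep &= ~((wn >= lo) & (wn <= hi))
    if not keep.any():
        raise SpectrumError("region removal would drop every grid point")
    return s.with_intensities(s.intensities[:, keep], wavenumbers=wn[keep])


def sg_derivative(s: SpectrumSet, derivative_order: int, sg_window: int = 9,
                  sg_poly_order: int = 2) -> SpectrumSet:
    """Savitzky-Golay derivative with respect to wavenumber.

    Requires a uniformly spaced contiguous grid (apply before region
    removal).  Units of the output are absorbance * cm^d.  Edge points use
    polynomial extrapolation of the terminal fitted window (scipy's
    ``mode='interp'``).
    """
    if s.mode != "absorbance":
        raise SpectrumError("derivatives are taken on absorbance spectra")
    if derivative_order < 1:
        raise ValueError("derivative_order must be >= 1")
    wn = s.wavenumbers
    steps = np.diff(wn)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6 * abs(steps[0])):
        raise SpectrumError("Savitzky-Golay derivative requires a uniform grid")
    if sg_window > wn.size:
        raise SpectrumError(
            f"window of {sg_window} points exceeds grid of {wn.size}")
    delta = abs(steps[0])
    deriv = savgol_filter(s.intensities, window_length=sg_window,
                          polyorder=sg_poly_order, deriv=derivative_order,
                          delta=delta, axis=1, mode="interp")
    # grid is descending, so the sample spacing along the axis is -delta
    if derivative_order % 2 == 1:
        deriv = -deriv
    return s.with_intensities(deriv, mode="derivative")


def _check_normalizable(s: SpectrumSet, allow_derivative: bool) -> None:
    ok = ("absorbance", "derivative") if allow_derivative else ("absorbance",)
    if s.mode not in ok:
        raise SpectrumError(f"cannot normalize spectra in mode {s.mode!r}")


def normalize_area(s: SpectrumSet) -> SpectrumSet:
    """Divide each sample by its trapezoidal integral over the retained
    grid, computed piecewise per contiguous segment; each output sample
    integrates to 1."""
    _check_normalizable(s, allow_derivative=False)
    areas = _piecewise_trapezoid(s.intensities, s.wavenumbers)
    bad = areas <= 0
    if bad.any():
        sid = s.metadata["sample_id"].iloc[int(np.argmax(bad))]
        raise SpectrumError(f"non-positive spectral area for sample {sid!r}")
    return s.with_intensities(s.intensities / areas[:, None])


def _piecewise_trapezoid(y: np.ndarray, wn: np.ndarray) -> np.ndarray:
    """Trapezoidal integral w.r.t. |d(nu)|, split at gaps in the grid."""
    steps = -np.diff(wn)  # positive widths on a descending grid
    typical = np.median(steps)
    breaks = np.where(steps > 1.5 * typical)[0] + 1
    segments = np.split(np.arange(wn.size), breaks)
    total = np.zeros(y.shape[0])
    for seg in segments:
        if seg.size >= 2:
            total += np.trapezoid(y[:, seg], x=-wn[seg], axis=1)
    return total


def normalize_minmax(s: SpectrumSet) -> SpectrumSet:
    """Divide each sample by its (max - min); division only, no min
    subtraction, so every output sample has unit range."""
    _check_normalizable(s, allow_derivative=False)
    rng = s.intensities.max(axis=1) - s.intensities.min(axis=1)
    bad = rng <= 0
    if bad.any():
        sid = s.metadata["sample_id"].iloc[int(np.argmax(bad))]
        raise SpectrumError(f"constant spectrum (zero range) for sample {sid!r}")
    return s.with_intensities(s.intensities / rng[:, None])


def normalize_vector(s: SpectrumSet) -> SpectrumSet:
    """Divide each sample by its Euclidean norm over the retained points."""
    _check_normalizable(s, allow_derivative=True)
    norms = np.linalg.norm(s.intensities, axis=1)
    bad = norms <= 0
    if bad.any():
        sid = s.metadata["sample_id"].iloc[int(np.argmax(bad))]
        raise SpectrumError(f"zero-norm spectrum for sample {sid!r}")
    return s.with_intensities(s.intensities / norms[:, None])


_NORMALIZERS = {"area": normalize_area, "minmax": normalize_minmax,
                "vector": normalize_vector}


def atr_correction_hook(s: SpectrumSet) -> SpectrumSet:
    """Placeholder for a user-supplied ATR penetration-depth correction.

    The instrument vendors implement proprietary corrections; none is
    bundled here.  Replace or wrap this no-op to slot a correction into
    :func:`run_preprocess` on the area/min-max paths.
    """
    return s


def run_preprocess(s: SpectrumSet, cfg: PreprocessConfig,
                   atr_correction=atr_correction_hook) -> SpectrumSet:
    """Run the full preprocessing chain for one configuration.

    Order: to_absorbance (if the input is transmittance), Savitzky-Golay
    derivative (vector path with ``derivative_order`` > 0), ATR-correction
    hook (area/min-max paths; identity by default), region removal, then
    the configured normalization.
    """
    out = to_absorbance(s) if s.mode == "percent_transmittance" else s
    if cfg.derivative_order > 0:
        out = sg_derivative(out, cfg.derivative_order, cfg.sg_window,
                            cfg.sg_poly_order)
    elif cfg.method in ("area", "minmax"):
        out = atr_correction(out)
    out = remove_regions(out, cfg.excluded_regions)
    return _NORMALIZERS[cfg.method](out)
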