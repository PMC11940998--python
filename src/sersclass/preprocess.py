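"""Spectral preprocessing chain: Savitzky-Golay smoothing, iterative
polynomial background removal, and standard normal variate normalization,
applied in that fixed order on the cropped wavenumber window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synth import SpectraDataset, Spectrum, WavenumberAxis

__all__ = [
    "PreprocessConfig",
    "savgol_smooth",
    "polynomial_baseline",
    "snv_normalize",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults: 15-point Savitzky-Golay window with a degree-1 polynomial and
    no derivative; degree-15 iterative polynomial background; crop to the
    517-1913 cm^-1 fingerprint window.
    """

    sg_window: int = 15
    sg_polyorder: int = 1
    sg_deriv: int = 0
    baseline_degree: int = 15
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    crop: tuple[float, float] = (517.0, 1913.0)

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window must be odd and > sg_polyorder, got window={self.sg_window}, polyorder={self.sg_polyorder}"
            )
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError(f"sg_deriv ({self.sg_deriv}) must be <= sg_polyorder ({self.sg_polyorder})")
        if self.baseline_degree < 0:
            raise ValueError(f"baseline_degree must be >= 0, got {self.baseline_degree}")
        if self.baseline_max_iter < 1:
            raise ValueError(f"baseline_max_iter must be >= 1, got {self.baseline_max_iter}")
        if self.baseline_tol <= 0:
            raise ValueError(f"baseline_tol must be > 0, got {self.baseline_tol}")
        if not self.crop[0] < self.crop[1]:
            raise ValueError(f"crop interval must satisfy start < end, got {self.crop}")


def savgol_smooth(intensities: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Savitzky-Golay smoothing: each point replaced by the value (or
    ``sg_deriv``-th derivative) of the local least-squares polynomial over
    the centered window. Edges are handled by evaluating the edge-window
    polynomial, not by truncation.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < cfg.sg_window:
        raise ValueError(
            f"savgol_smooth needs at least sg_window={cfg.sg_window} points, got {x.size}"
        )
    return savgol_filter(x, cfg.sg_window, cfg.sg_polyorder, deriv=cfg.sg_deriv, mode="interp")


class _ChebyshevBaselineFitter:
    """Iterative modified-polynomial (peak-clipping) background estimator.

    A plain least-squares fit of the stated degree would be pulled up into
    the peaks, so the standard chemometric iteration is used: fit, clip the
    working spectrum to min(spectrum, fit), refit, until the fit stabilizes.
    The polynomial is fitted in a Chebyshev basis on wavenumber rescaled to
    [-1, 1]; degree 15 on raw cm^-1 values is numerically hopeless.

    The least-squares projector for a fixed grid is precomputed so the
    fitter can be reused across all spectra of a dataset.
    """

    def __init__(self, grid: np.ndarray, cfg: PreprocessConfig):
        grid = np.asarray(grid, dtype=float)
        if cfg.baseline_degree >= grid.size:
            raise ValueError(
                f"baseline_degree ({cfg.baseline_degree}) must be < number of grid points ({grid.size})"
            )
        self.cfg = cfg
        x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
        self._V = np.polynomial.chebyshev.chebvander(x, cfg.baseline_degree)
        self._solver = np.linalg.pinv(self._V)

    def __call__(self, intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(intensities, dtype=float)
        if y.shape != (self._V.shape[0],):
            raise ValueError(f"expected vector of length {self._V.shape[0]}, got shape {y.shape}")
        if not np.all(np.isfinite(y)):
            raise ValueError("polynomial_baseline: input contains non-finite values")
        work = y.copy()
        fit = self._V @ (self._solver @ work)
        for _ in range(self.cfg.baseline_max_iter - 1):
            work = np.minimum(work, fit)
            new_fit = self._V @ (self._solver @ work)
            denom = max(float(np.linalg.norm(fit)), 1e-300)
            delta = float(np.linalg.norm(new_fit - fit)) / denom
            fit = new_fit
            if delta < self.cfg.baseline_tol:
                break
        return fit, y - fit


def polynomial_baseline(
    intensities: np.ndarray, axis: WavenumberAxis, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract the smooth background of one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = intensities - baseline``.
    """
    return _ChebyshevBaselineFitter(axis.grid(), cfg)(intensities)


def snv_normalize(intensities: np.ndarray) -> np.ndarray:
    """Standard normal variate: center to mean 0 and scale to sample
    standard deviation 1 (n-1 denominator), per spectrum."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError(f"snv_normalize needs >= 2 points, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance under SNV")
    return (x - np.mean(x)) / sd


def _crop_axis(axis: WavenumberAxis, crop: tuple[float, float]) -> tuple[np.ndarray, WavenumberAxis]:
    grid = axis.grid()
    mask = (grid >= crop[0]) & (grid <= crop[1])
    if mask.sum() < 2:
        raise ValueError(f"crop {crop} leaves fewer than 2 grid points")
    sub = grid[mask]
    return mask, WavenumberAxis(start=float(sub[0]), end=float(sub[-1]), n_points=int(mask.sum()))


def cropped_axis(axis: WavenumberAxis, cfg: PreprocessConfig) -> WavenumberAxis:
    """The axis that :func:`preprocess_dataset` will emit for ``axis``."""
    return _crop_axis(axis, cfg.crop)[1]


def preprocess_dataset(ds: SpectraDataset, cfg: PreprocessConfig) -> SpectraDataset:
    """Apply crop -> smooth -> baseline-correct -> SNV to every spectrum.

    Metadata is unchanged; the output axis contains exactly the grid points
    inside the closed crop interval.
    """
    if not ds.spectra:
        return SpectraDataset(axis=ds.axis, spectra=[], class_of_patient=dict(ds.class_of_patient))
    mask, new_axis = _crop_axis(ds.axis, cfg.crop)
    fitter = _ChebyshevBaselineFitter(new_axis.grid(), cfg)
    out: list[Spectrum] = []
    for s in ds.spectra:
        try:
            y = savgol_smooth(s.intensities[mask], cfg)
            _, y = fitter(y)
            y = snv_normalize(y)
        except ValueError as err:
            raise ValueError(f"preprocessing spectrum {s.spectrum_id!r}: {err}") from err
        out.append(
            Spectrum(
                spectrum_id=s.spectrum_id,
                patient_id=s.patient_id,
                class_label=s.class_label,
                intensities=y,
            )
        )
    result = SpectraDataset(axis=new_axis, spectra=out, class_of_patient=dict(ds.class_of_patient))
    result.validate()
    return result
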