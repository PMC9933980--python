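"""Spectral preprocessing: black/white reflectance correction, ROI mean
spectra, multiplicative scatter correction, Savitzky–Golay smoothing and the
first-difference derivative.

The pretreatment chain applied before regression is MSC → S-G → 1stD:
scatter removal first (so smoothing does not blur affine distortion into the
signal), then noise smoothing, then differencing to remove residual baseline
shifts and sharpen absorption features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu

from .simulate import SpectralCube, SpectrumMatrix


class PreprocessError(ValueError):
    pass


class SegmentationError(PreprocessError):
    pass


@dataclass
class PreprocessConfig:
    sg_window: int = 11
    sg_polyorder: int = 2
    apply_msc: bool = True
    apply_sg: bool = True
    apply_derivative: bool = True
    derivative_dx: float | None = None  # nm; None = mean wavelength spacing

    def __post_init__(self) -> None:
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise PreprocessError("sg_window must be an odd integer >= 3")
        if not (0 <= self.sg_polyorder < self.sg_window):
            raise PreprocessError("sg_polyorder must be < sg_window")


def reflectance_correction(
    raw: np.ndarray,
    dark: np.ndarray,
    white: np.ndarray,
    clip: bool = False,
) -> np.ndarray:
    """Correct a raw frame to reflectance: C = (R − D) / (W − D).

    ``dark`` is the lens-cap (~0% reflectance) reference, ``white`` the
    standard whiteboard (~100%) reference. The correction is invariant to a
    common affine rescaling of all three frames.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.broadcast_to(np.asarray(dark, dtype=float), raw.shape)
    white = np.broadcast_to(np.asarray(white, dtype=float), raw.shape)
    denom = white - dark
    bad = np.isclose(denom, 0.0)
    if np.any(bad):
        where = np.argwhere(bad)[0]
        raise PreprocessError(
            f"white minus dark reference is zero at position {tuple(int(i) for i in where)}"
        )
    corrected = (raw - dark) / denom
    if clip:
        corrected = np.clip(corrected, 0.0, 1.0)
    return corrected


def extract_roi_mean(
    cube: SpectralCube, threshold: float | str = "otsu"
) -> tuple[np.ndarray, np.ndarray]:
    """Segment leaf pixels by mean-over-bands intensity and average their spectra.

    Returns ``(mean_spectrum, mask)``. The default threshold is Otsu's on the
    mean-intensity image; an explicit numeric threshold may be given instead.
    """
    intensity = cube.values.mean(axis=2)
    if threshold == "otsu":
        thr = float(threshold_otsu(intensity))
    else:
        thr = float(threshold)
    mask = intensity > thr
    if not mask.any():
        raise SegmentationError(f"no pixel exceeds the segmentation threshold {thr:.4g}")
    mean_spectrum = cube.values[mask].mean(axis=0)
    return mean_spectrum, mask


def msc(
    spectra: SpectrumMatrix, reference: np.ndarray | None = None, b_tol: float = 1e-8
) -> SpectrumMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum s is regressed on the reference, s ≈ b·ref + a, and the
    fitted affine distortion inverted: corrected = (s − a)/b. The default
    reference is the mean spectrum of the input set; pass the calibration-set
    mean explicitly when correcting held-out spectra.
    """
    X = spectra.values
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if np.ptp(ref) == 0:
        raise PreprocessError("MSC reference spectrum is constant")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    Xc = X - X.mean(axis=1, keepdims=True)
    b = (Xc @ ref_c) / denom
    small = np.abs(b) < b_tol
    if np.any(small):
        idx = int(np.flatnonzero(small)[0])
        raise PreprocessError(
            f"degenerate spectrum {spectra.sample_ids[idx]!r}: fitted MSC slope ~ 0"
        )
    a = X.mean(axis=1) - b * ref.mean()
    corrected = (X - a[:, None]) / b[:, None]
    out = spectra.copy()
    out.values = corrected
    out.provenance = spectra.provenance + ["msc"]
    return out


def savitzky_golay(
    spectra: SpectrumMatrix, window: int = 11, polyorder: int = 2
) -> SpectrumMatrix:
    """Savitzky–Golay smoothing: local least-squares polynomial per window.

    Edges are handled by polynomial extrapolation of the terminal windows.
    """
    if window % 2 == 0 or window < 3:
        raise PreprocessError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise PreprocessError("polyorder must be < window")
    if window > spectra.n_bands:
        raise PreprocessError(
            f"window {window} exceeds the number of bands {spectra.n_bands}"
        )
    out = spectra.copy()
    out.values = savgol_filter(spectra.values, window, polyorder, axis=1, mode="interp")
    out.provenance = spectra.provenance + [f"sg({window},{polyorder})"]
    return out


def first_derivative(spectra: SpectrumMatrix, dx: float | None = None) -> SpectrumMatrix:
    """First-difference derivative (y_{i+1} − y_i)/Δx; output has B−1 bands.

    The derivative spectra keep midpoint wavelengths as their axis. Δx
    defaults to the mean wavelength spacing of the input axis.
    """
    if spectra.n_bands < 2:
        raise PreprocessError("need at least two bands to differentiate")
    if dx is None:
        dx = float(np.mean(np.diff(spectra.wavelengths)))
    if dx <= 0:
        raise PreprocessError("wavelength interval must be positive")
    out = spectra.copy()
    out.values = np.diff(spectra.values, axis=1) / dx
    out.wavelengths = 0.5 * (spectra.wavelengths[:-1] + spectra.wavelengths[1:])
    out.informative_bands = None  # band indexing no longer aligned with planted truth
    out.provenance = spectra.provenance + [f"d1(dx={dx:.4g})"]
    return out


def derivative_vector(y: np.ndarray, dx: float) -> np.ndarray:
    """Derivative of a single spectrum vector (convenience for oracles)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise PreprocessError("need at least two points")
    if dx <= 0:
        raise PreprocessError("wavelength interval must be positive")
    return np.diff(y) / dx


def preprocess_chain(
    spectra: SpectrumMatrix,
    config: PreprocessConfig | None = None,
    msc_reference: np.ndarray | None = None,
) -> SpectrumMatrix:
    """Apply the configured pretreatments in order MSC → S-G → 1stD."""
    config = config or PreprocessConfig()
    out = spectra
    if config.apply_msc:
        out = msc(out, reference=msc_reference)
    if config.apply_sg:
        out = savitzky_golay(out, config.sg_window, config.sg_polyorder)
    if config.apply_derivative:
        out = first_derivative(out, config.derivative_dx)
    return out
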