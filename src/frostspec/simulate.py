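"""Synthetic biochemistry and reflectance spectra with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-treatment component means following the observed stress-response
trends (chlorophyll falling with stress severity, soluble sugar and
malondialdehyde rising, antioxidant enzymes rising under chilling then
falling under freezing), and leaf reflectance built as a smooth vegetation
baseline minus component-linked Gaussian absorption features, distorted by
per-sample multiplicative/additive scatter and band noise.  The set of
informative bands (within one feature width of any signature center) is
recorded so selection methods can be scored against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import (
    COMPONENTS,
    SEVERITY_ORDER,
    SampleRecord,
    TREATMENT_BY_LABEL,
)

WAVELENGTH_MIN_NM = 397.0
WAVELENGTH_MAX_NM = 1008.0
N_BANDS = 176


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


class FixtureError(ValueError):
    """Raised when a requested synthetic cube cannot be segmented."""


def default_wavelengths(n_bands: int = N_BANDS) -> np.ndarray:
    """Uniform wavelength axis over the instrument range (~3.5 nm step at 176 bands)."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_bands)


@dataclass(frozen=True)
class SpectralSignature:
    """One component-linked Gaussian absorption feature."""

    component: str
    center_nm: float
    width_nm: float
    strength: float  # absorption depth when the component sits at its range maximum


@dataclass
class GeneratorConfig:
    """Defaults encode the study conditions the analysis is exercised under.

    ``treatment_means[component]`` maps each treatment label to the cell mean;
    the defaults respect the response trends (SPAD decreasing with severity,
    SS/MDA increasing, CAT/POD/SOD peaking at chilling) and stay inside the
    observed min–max envelope of each component.
    """

    treatment_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "SPAD": {"CK8": 72.0, "CK12": 69.0, "C8": 64.0, "C12": 61.0, "F8": 56.0, "F12": 51.0},
            "SS": {"CK8": 20.0, "CK12": 22.0, "C8": 26.0, "C12": 29.0, "F8": 33.0, "F12": 35.5},
            "MDA": {"CK8": 19.5, "CK12": 21.0, "C8": 25.0, "C12": 28.0, "F8": 32.0, "F12": 35.0},
            "CAT": {"CK8": 20.0, "CK12": 22.0, "C8": 30.0, "C12": 33.0, "F8": 27.0, "F12": 23.0},
            "POD": {"CK8": 3.0, "CK12": 4.0, "C8": 8.0, "C12": 9.5, "F8": 6.0, "F12": 4.5},
            "SOD": {"CK8": 300.0, "CK12": 320.0, "C8": 390.0, "C12": 410.0, "F8": 360.0, "F12": 330.0},
        }
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "SPAD": 3.0, "SS": 1.5, "MDA": 1.5, "CAT": 1.5, "POD": 0.8, "SOD": 12.0,
        }
    )
    #: Observed per-component (min, max) used to scale absorption amplitudes.
    component_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SPAD": (39.675, 81.267),
            "SS": (17.000, 39.120),
            "MDA": (16.000, 39.703),
            "CAT": (17.159, 38.170),
            "POD": (1.000, 12.700),
            "SOD": (242.000, 438.268),
        }
    )
    #: Cultivar offsets added to every component mean (default: pooled cultivars).
    cultivar_offset: Mapping[str, float] = field(default_factory=dict)
    signatures: Sequence[SpectralSignature] = field(
        default_factory=lambda: (
            SpectralSignature("SPAD", 665.0, 35.0, 0.15),  # chlorophyll red absorption
            SpectralSignature("SS", 960.0, 30.0, 0.06),
            SpectralSignature("MDA", 800.0, 30.0, 0.06),
            SpectralSignature("CAT", 540.0, 25.0, 0.05),
            SpectralSignature("POD", 715.0, 20.0, 0.05),
            SpectralSignature("SOD", 890.0, 25.0, 0.05),
        )
    )
    gain_range: tuple[float, float] = (0.97, 1.03)
    offset_range: tuple[float, float] = (-0.01, 0.01)
    band_noise_sd: float = 0.003
    n_bands: int = N_BANDS
    positivity_epsilon: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for sig in self.signatures:
            if not (WAVELENGTH_MIN_NM <= sig.center_nm <= WAVELENGTH_MAX_NM):
                raise ConfigError(
                    f"signature center {sig.center_nm} nm outside the "
                    f"{WAVELENGTH_MIN_NM}-{WAVELENGTH_MAX_NM} nm axis"
                )
        _check_trends(self.treatment_means)

    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.n_bands)


def _check_trends(means: Mapping[str, Mapping[str, float]]) -> None:
    """Validate the monotone / rise-then-fall trend flags on the mean curves."""
    for comp in COMPONENTS:
        if comp not in means:
            raise ConfigError(f"missing treatment means for component {comp}")
        curve = [means[comp][t] for t in SEVERITY_ORDER]
        if comp == "SPAD":
            ok = all(a > b for a, b in zip(curve, curve[1:]))
        elif comp in ("SS", "MDA"):
            ok = all(a < b for a, b in zip(curve, curve[1:]))
        else:  # enzymes: peak at the chilling level
            peak = int(np.argmax(curve))
            ok = peak in (2, 3) and curve[0] < curve[peak] and curve[-1] < curve[peak]
        if not ok:
            raise ConfigError(f"treatment-mean curve for {comp} violates its trend flag")


@dataclass
class SpectrumMatrix:
    """Samples × bands reflectance with its wavelength axis."""

    values: np.ndarray  # (n_samples, n_bands)
    wavelengths: np.ndarray  # (n_bands,)
    sample_ids: list[str]
    provenance: list[str] = field(default_factory=list)
    informative_bands: np.ndarray | None = None  # planted ground-truth indices

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "SpectrumMatrix":
        return SpectrumMatrix(
            self.values.copy(),
            self.wavelengths.copy(),
            list(self.sample_ids),
            list(self.provenance),
            None if self.informative_bands is None else self.informative_bands.copy(),
        )


@dataclass
class SpectralCube:
    """H × W × B reflectance cube with a leaf mask and wavelength metadata."""

    values: np.ndarray  # (H, W, B)
    wavelengths: np.ndarray  # (B,)
    leaf_mask: np.ndarray  # (H, W) boolean


def _cell_mean(config: GeneratorConfig, component: str, cultivar: str, label: str) -> float:
    if label not in config.treatment_means[component]:
        raise ConfigError(f"no configured mean for treatment {label!r}")
    return config.treatment_means[component][label] + config.cultivar_offset.get(cultivar, 0.0)


def simulate_biochemistry(
    design: Sequence[SampleRecord],
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Fill each record's six-component vector: treatment mean + Gaussian noise.

    Values are clipped at a small positive epsilon; at the default noise level
    essentially all draws fall inside the observed component envelopes.
    """
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng(config.seed)
    out = []
    for rec in design:
        label = rec.treatment.label
        if label not in TREATMENT_BY_LABEL:
            raise ConfigError(f"unknown treatment label {label!r}")
        values = np.empty(len(COMPONENTS))
        for i, comp in enumerate(COMPONENTS):
            mean = _cell_mean(config, comp, rec.cultivar, label)
            values[i] = mean + rng.normal(0.0, config.noise_sd[comp])
        new = rec.copy()
        new.biochem = np.clip(values, config.positivity_epsilon, None)
        out.append(new)
    return out


def baseline_reflectance(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like baseline: low in the visible, rising at the red edge."""
    return 0.12 + 0.45 / (1.0 + np.exp(-(wavelengths - 720.0) / 25.0))


def pure_spectrum(
    biochem: np.ndarray, config: GeneratorConfig, wavelengths: np.ndarray | None = None
) -> np.ndarray:
    """Noise-free mixture spectrum for one sample (closed form, used by tests)."""
    wl = config.wavelengths() if wavelengths is None else wavelengths
    spectrum = baseline_reflectance(wl).copy()
    comp_index = {c: i for i, c in enumerate(COMPONENTS)}
    for sig in config.signatures:
        lo, hi = config.component_ranges[sig.component]
        frac = (biochem[comp_index[sig.component]] - lo) / (hi - lo)
        depth = sig.strength * frac
        spectrum -= depth * np.exp(-0.5 * ((wl - sig.center_nm) / sig.width_nm) ** 2)
    return spectrum


def informative_band_indices(config: GeneratorConfig) -> np.ndarray:
    """Planted ground truth: bands within one width of any signature center."""
    wl = config.wavelengths()
    mask = np.zeros(wl.shape, dtype=bool)
    for sig in config.signatures:
        mask |= np.abs(wl - sig.center_nm) <= sig.width_nm
    return np.flatnonzero(mask)


def simulate_spectra(
    records: Sequence[SampleRecord],
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SpectrumMatrix:
    """Simulate reflectance spectra for records with filled biochemistry.

    Each spectrum is the pure mixture, then per-sample affine scatter
    ``a * s + b`` (the distortion class multiplicative scatter correction is
    designed to remove), then i.i.d. band noise.
    """
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng(config.seed + 1)
    wl = config.wavelengths()
    values = np.empty((len(records), config.n_bands))
    ids = []
    for i, rec in enumerate(records):
        if rec.biochem is None:
            raise ValueError(f"record {rec.sample_id} has no biochemistry; simulate it first")
        s = pure_spectrum(rec.biochem, config, wl)
        gain = rng.uniform(*config.gain_range)
        offset = rng.uniform(*config.offset_range)
        noise = rng.normal(0.0, config.band_noise_sd, size=config.n_bands)
        values[i] = gain * s + offset + noise
        ids.append(rec.sample_id)
    return SpectrumMatrix(
        values=values,
        wavelengths=wl,
        sample_ids=ids,
        provenance=["simulated"],
        informative_bands=informative_band_indices(config),
    )


def simulate_cube(
    spectrum: np.ndarray,
    shape: tuple[int, int],
    background_level: float = 0.02,
    wavelengths: np.ndarray | None = None,
    pixel_noise_sd: float = 0.002,
    leaf_fraction: float = 0.4,
    rng: np.random.Generator | None = None,
) -> SpectralCube:
    """Build a small cube: a central leaf region carrying ``spectrum`` on a dark background.

    The background must sit clearly below the leaf intensity so threshold
    segmentation can separate the two regions.
    """
    H, W = shape
    if H < 2 or W < 2:
        raise ValueError("cube spatial dimensions must be >= 2")
    spectrum = np.asarray(spectrum, dtype=float)
    if background_level >= spectrum.mean() - 3 * pixel_noise_sd:
        raise FixtureError(
            "background level overlaps the leaf intensity range; segmentation would fail"
        )
    rng = rng or np.random.default_rng(0)
    B = spectrum.size
    wl = default_wavelengths(B) if wavelengths is None else np.asarray(wavelengths)
    mask = np.zeros((H, W), dtype=bool)
    h = max(1, int(round(H * np.sqrt(leaf_fraction))))
    w = max(1, int(round(W * np.sqrt(leaf_fraction))))
    r0, c0 = (H - h) // 2, (W - w) // 2
    mask[r0 : r0 + h, c0 : c0 + w] = True
    values = np.full((H, W, B), background_level, dtype=float)
    values[mask] = spectrum
    if pixel_noise_sd > 0:
        values = values + rng.normal(0.0, pixel_noise_sd, size=values.shape)
    return SpectralCube(values=values, wavelengths=wl, leaf_mask=mask)
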