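"""Synthetic three-class spectra and cross-section images.

The generators exist so that every downstream stage (encoding, quantification,
selection, classification) can be exercised without any external dataset.
Spectral shapes are qualitative stand-ins: a smooth baseline plus Gaussian
transmission peaks in the 600-900 nm band, with the whole clean signal scaled
by a per-class attenuation factor so that amplitude decreases strictly with
mold severity. Cross-section images carry a dark low-blue-channel mold blob of
exactly known pixel area inside a bright elliptical flesh region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .prep import Spectrum

CLASS_LABELS = ("healthy", "slight", "severe")

#: default per-class scaling of the clean signal (strictly decreasing with
#: severity; free knobs, not measured values)
DEFAULT_ATTENUATION = {"healthy": 1.0, "slight": 0.7, "severe": 0.4}


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Parameters of the synthetic spectrum generator."""

    n_wavelengths: int = 1044
    wavelength_range: tuple[float, float] = (350.0, 1150.0)
    class_label: str = "healthy"
    peak_band: tuple[float, float] = (600.0, 900.0)
    severity_attenuation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wavelengths < 2:
            raise ConfigurationError("n_wavelengths must be >= 2")
        if self.class_label not in CLASS_LABELS:
            raise ConfigurationError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        att = self.severity_attenuation
        missing = set(CLASS_LABELS) - set(att)
        if missing:
            raise ConfigurationError(f"attenuation factors missing for {sorted(missing)}")
        if not (att["healthy"] > att["slight"] > att["severe"]):
            raise ConfigurationError(
                "attenuation factors must be strictly ordered healthy > slight > severe"
            )


@dataclass(frozen=True)
class CrossSectionSimConfig:
    """Parameters of the synthetic cross-section image generator."""

    image_size: int = 256
    fruit_radius: int = 100
    mold_fraction_true: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mold_fraction_true <= 100.0):
            raise ConfigurationError("mold_fraction_true must lie in [0, 100]")
        if self.fruit_radius * 2 + 8 > self.image_size:
            raise ConfigurationError("fruit does not fit inside the image")


@dataclass(frozen=True)
class CrossSection:
    """A generated cross-section image plus its ground-truth masks."""

    image: np.ndarray  # HxWx3 uint8
    flesh_mask: np.ndarray  # HxW bool
    mold_mask: np.ndarray  # HxW bool
    mold_fraction_true: float  # percent, from pixel-exact mask counts


def _wavelength_grid(config: SpectrumSimConfig) -> np.ndarray:
    lo, hi = config.wavelength_range
    return np.linspace(lo, hi, config.n_wavelengths)


#: class-dependent amplitudes of the two marker shoulders that sit outside
#: the peak band (short- and long-wavelength side). They give each class a
#: distinct spectral *shape* — required for rank/shape-based encoders to see
#: class structure — without perturbing peak-band maxima beyond ~1e-13.
MARKER_AMPLITUDES = {
    "healthy": (0.55, 0.10),
    "slight": (0.35, 0.30),
    "severe": (0.15, 0.50),
}


def clean_signal(config: SpectrumSimConfig) -> np.ndarray:
    """Noise-free signal before class attenuation.

    Smooth quadratic baseline + three Gaussian transmission peaks centered
    inside the peak band (identical for all classes) + two class-dependent
    marker shoulders outside the band. All amplitudes are arbitrary
    instrument-like units.
    """
    wl = _wavelength_grid(config)
    lo, hi = config.wavelength_range
    t = (wl - lo) / (hi - lo)  # 0..1 across the range
    baseline = 0.05 + 0.08 * t * (1.0 - t)

    b_lo, b_hi = config.peak_band
    center = 0.5 * (b_lo + b_hi)
    width = b_hi - b_lo
    bumps = (
        1.00 * np.exp(-0.5 * ((wl - center) / (0.18 * width)) ** 2)
        + 0.35 * np.exp(-0.5 * ((wl - (center - 0.22 * width)) / (0.10 * width)) ** 2)
        + 0.25 * np.exp(-0.5 * ((wl - (center + 0.25 * width)) / (0.08 * width)) ** 2)
    )
    a_short, a_long = MARKER_AMPLITUDES[config.class_label]
    span = hi - lo
    markers = (
        a_short * np.exp(-0.5 * ((wl - (lo + 0.15 * span)) / (0.04 * span)) ** 2)
        + a_long * np.exp(-0.5 * ((wl - (lo + 0.84 * span)) / (0.04 * span)) ** 2)
    )
    return baseline + bumps + markers


def generate_spectrum(config: SpectrumSimConfig) -> Spectrum:
    """Generate one synthetic spectrum.

    intensity = attenuation(class) * clean_signal + N(0, noise_sd^2).
    Deterministic for a fixed seed. Scaling the whole clean signal (rather
    than the peaks alone) keeps peak-band amplitude ratios exactly equal to
    attenuation ratios, mirroring reduced transmittance of moldier tissue.
    """
    wl = _wavelength_grid(config)
    rng = np.random.default_rng(config.seed)
    factor = config.severity_attenuation[config.class_label]
    intensities = factor * clean_signal(config)
    if config.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, config.noise_sd, size=wl.size)
    return Spectrum(
        wavelengths=wl,
        intensities=intensities,
        sample_id=f"sim-{config.class_label}-{config.seed}",
        label=config.class_label,
    )


def generate_dataset(
    n_per_class: tuple[int, int, int],
    config: SpectrumSimConfig | None = None,
    seed: int = 0,
) -> list[Spectrum]:
    """Generate a labeled collection with the requested per-class counts.

    Per-sample seeds are spawned from the master seed so the whole dataset is
    reproducible and individual samples are independent.
    """
    if config is None:
        config = SpectrumSimConfig()
    if len(n_per_class) != len(CLASS_LABELS):
        raise ConfigurationError("n_per_class must have one count per class")
    if any(n < 1 for n in n_per_class):
        raise ConfigurationError("each class count must be >= 1")
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(int(sum(n_per_class)))
    out: list[Spectrum] = []
    k = 0
    for label, n in zip(CLASS_LABELS, n_per_class):
        for _ in range(n):
            sample_seed = int(children[k].generate_state(1)[0])
            cfg = replace(config, class_label=label, seed=sample_seed)
            spec = generate_spectrum(cfg)
            out.append(replace(spec, sample_id=f"sim-{label}-{k:04d}"))
            k += 1
    return out


FLESH_RGB = (225, 205, 160)
MOLD_RGB = (95, 60, 35)  # browning: blue channel drops the most
BACKGROUND_RGB = (18, 18, 20)


def generate_cross_section(config: CrossSectionSimConfig) -> CrossSection:
    """Generate an RGB cross-section image with a known-area mold blob.

    The flesh is a bright ellipse on a dark background. The mold blob is
    built by taking exactly ``round(fraction/100 * flesh_area)`` flesh pixels
    nearest to a randomly placed interior center, so the true area fraction
    is exact up to that single rounding. Mild per-pixel texture noise is added
    without crossing channel thresholds.
    """
    rng = np.random.default_rng(config.seed)
    n = config.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0

    # mildly eccentric ellipse
    a = float(config.fruit_radius)
    b = 0.92 * a
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    flesh = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    flesh_area = int(flesh.sum())

    mold = np.zeros_like(flesh)
    target = int(round(config.mold_fraction_true / 100.0 * flesh_area))
    if target > 0:
        # place the blob center so a disk of the required area fits inside
        blob_r = np.sqrt(target / np.pi)
        margin = blob_r + 5.0
        scale = max(0.0, 1.0 - margin / b)
        ang = rng.uniform(0, 2 * np.pi)
        rad = scale * rng.uniform(0.0, 1.0)
        bu, bv = rad * a * np.cos(ang), rad * b * np.sin(ang)
        bx = cx + bu * ct - bv * st
        by = cy + bu * st + bv * ct
        d2 = (xx - bx) ** 2 + (yy - by) ** 2
        d2 = np.where(flesh, d2, np.inf)
        order = np.argsort(d2, axis=None, kind="stable")[:target]
        mold.flat[order] = True

    true_frac = 100.0 * mold.sum() / flesh_area if flesh_area else 0.0

    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    img[flesh] = FLESH_RGB
    img[mold] = MOLD_RGB
    # low-amplitude texture; far smaller than the flesh/mold contrast
    img += rng.normal(0.0, 2.0, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return CrossSection(
        image=img, flesh_mask=flesh, mold_mask=mold, mold_fraction_true=true_frac
    )
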