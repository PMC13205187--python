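"""Spectra table I/O, replicate averaging, outlier flags, and normalization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd


class SpectraParseError(ValueError):
    """Raised when a spectra table cannot be parsed."""


class DegenerateInputError(ValueError):
    """Raised on constant series where min-max normalization is undefined."""


@dataclass(frozen=True)
class Spectrum:
    """One sample: a wavelength grid plus an intensity vector.

    Wavelengths must be strictly increasing, intensities finite, and both the
    same length.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        inten = np.asarray(self.intensities, dtype=np.float64)
        if wl.ndim != 1 or inten.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if wl.size != inten.size:
            raise ValueError("wavelengths and intensities must have equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.wavelengths.size


RangeMode = Literal["[-1,1]", "[0,1]"]


@dataclass(frozen=True)
class NormalizedSeries:
    """Min-max normalized intensity vector with stored source extrema.

    The source min/max make the transform invertible; ``range_mode`` declares
    whether values live in [-1, 1] (the arccos-encoding convention) or [0, 1].
    """

    values: np.ndarray
    range_mode: RangeMode
    source_min: float
    source_max: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        lo, hi = (-1.0, 1.0) if self.range_mode == "[-1,1]" else (0.0, 1.0)
        if vals.size and (vals.min() < lo - 1e-12 or vals.max() > hi + 1e-12):
            raise ValueError(f"values outside declared range {self.range_mode}")
        object.__setattr__(self, "values", vals)

    def denormalize(self) -> np.ndarray:
        """Map values back to the original intensity scale."""
        span = self.source_max - self.source_min
        if self.range_mode == "[-1,1]":
            return (self.values + 1.0) / 2.0 * span + self.source_min
        return self.values * span + self.source_min


def read_spectra_table(path: str | Path) -> list[Spectrum]:
    """Read a CSV spectra table: numeric wavelength columns + optional label.

    The header holds wavelengths in nm (plus ``label`` / ``sample_id``
    columns); each row is one sample.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraParseError(f"malformed spectra table {path}: {exc}") from exc
    meta_cols = [c for c in df.columns if c in ("label", "sample_id")]
    wl_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraParseError(f"non-numeric wavelength header in {path}: {exc}") from exc
    spectra: list[Spectrum] = []
    for i, row in df.iterrows():
        vals = row[wl_cols].to_numpy()
        try:
            intensities = vals.astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise SpectraParseError(f"non-numeric cell in row {i} of {path}") from exc
        if not np.all(np.isfinite(intensities)):
            raise SpectraParseError(f"non-finite value in row {i} of {path}")
        spectra.append(
            Spectrum(
                wavelengths=wavelengths,
                intensities=intensities,
                sample_id=str(row["sample_id"]) if "sample_id" in meta_cols else str(i),
                label=str(row["label"]) if "label" in meta_cols else None,
            )
        )
    return spectra


def write_spectra_table(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to CSV with full float precision (round-trips to 1e-12)."""
    if not spectra:
        raise ValueError("empty spectra collection")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid")
    data = {"sample_id": [s.sample_id for s in spectra]}
    if any(s.label is not None for s in spectra):
        data["label"] = [s.label if s.label is not None else "" for s in spectra]
    mat = np.stack([s.intensities for s in spectra])
    for j, w in enumerate(wl):
        data[repr(float(w))] = mat[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def average_replicates(scans: Sequence[Spectrum]) -> Spectrum:
    """Elementwise arithmetic mean of replicate scans on one wavelength grid."""
    if not scans:
        raise ValueError("no scans given")
    wl = scans[0].wavelengths
    for s in scans[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("replicate scans must share an identical wavelength grid")
    mean = np.mean([s.intensities for s in scans], axis=0)
    return Spectrum(
        wavelengths=wl,
        intensities=mean,
        sample_id=scans[0].sample_id,
        label=scans[0].label,
    )


def flag_outliers(spectra: Sequence[Spectrum], z_threshold: float = 3.0) -> np.ndarray:
    """Flag samples far from the collection mean (automated stand-in rule).

    A sample is flagged when its mean absolute wavelength-wise z-score against
    the collection mean/SD exceeds ``z_threshold``. Data are never mutated.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 samples to flag outliers")
    mat = np.stack([s.intensities for s in spectra])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant wavelengths contribute zero deviation
    z = np.abs((mat - mu) / sd).mean(axis=1)
    return z > z_threshold


def minmax_normalize(spectrum: Spectrum, range_mode: RangeMode = "[-1,1]") -> NormalizedSeries:
    """Min-max normalize a spectrum into [-1, 1] or [0, 1].

    Endpoints map exactly onto the range bounds. A constant series is
    rejected: the downstream arccos encoding has no defined direction there.
    """
    x = spectrum.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateInputError("constant series cannot be min-max normalized")
    unit = (x - lo) / (hi - lo)
    if range_mode == "[-1,1]":
        vals = 2.0 * unit - 1.0
    elif range_mode == "[0,1]":
        vals = unit
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    return NormalizedSeries(values=vals, range_mode=range_mode, source_min=lo, source_max=hi)
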