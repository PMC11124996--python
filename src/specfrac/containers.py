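"""Core in-memory containers for canopy reflectance data.

A :class:`SpectraSet` holds a sample-by-band reflectance matrix on a shared,
uniform wavelength grid; a :class:`DerivativeSet` holds the same matrix after
fractional-order differentiation and remembers the order it was produced at.
Both are thin, validated wrappers around numpy arrays so that every pipeline
stage can rely on grid uniformity and finiteness without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "DerivativeSet", "GridError"]


class GridError(ValueError):
    """Raised when a wavelength grid is not uniform ascending."""


def _validate_grid(wavelengths: np.ndarray) -> float:
    """Return the (constant) grid step or raise :class:`GridError`."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise GridError("wavelength grid must be a non-empty 1-D array")
    if wl.size == 1:
        return 1.0
    steps = np.diff(wl)
    if np.any(steps <= 0):
        bad = wl[1:][steps <= 0]
        raise GridError(f"wavelengths not strictly increasing at {bad[:5].tolist()}")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        bad_idx = np.nonzero(~np.isclose(steps, steps[0], rtol=0, atol=1e-9))[0]
        cols = wl[bad_idx + 1][:5].tolist()
        raise GridError(f"non-uniform wavelength grid near columns {cols}")
    return float(steps[0])


@dataclass
class SpectraSet:
    """Reflectance spectra for a set of samples on one uniform grid.

    Parameters
    ----------
    sample_ids
        Unique identifier per row.
    wavelengths
        Strictly increasing, constant-step grid in nm.
    reflectance
        ``(n_samples, n_bands)`` matrix, dimensionless, finite.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    reflectance: np.ndarray
    step: float = field(init=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.step = _validate_grid(self.wavelengths)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (n_samples, n_bands)")
        n, b = self.reflectance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} reflectance rows"
            )
        if b != self.wavelengths.size:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths but {b} reflectance columns"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample_id")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of an exact on-grid wavelength (no interpolation)."""
        idx = int(np.searchsorted(self.wavelengths, wavelength_nm))
        if idx >= self.wavelengths.size or self.wavelengths[idx] != wavelength_nm:
            raise KeyError(
                f"wavelength {wavelength_nm} nm is not on the grid "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] "
                f"step {self.step:g}"
            )
        return idx

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Per-sample reflectance at one exact grid wavelength."""
        return self.reflectance[:, self.band_index(wavelength_nm)]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: one row per sample, one column per wavelength."""
        return pd.DataFrame(
            self.reflectance,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.wavelengths,
        )

    def copy_with(self, reflectance: np.ndarray) -> "SpectraSet":
        return SpectraSet(list(self.sample_ids), self.wavelengths.copy(), reflectance)


@dataclass
class DerivativeSet:
    """An order-``alpha`` fractional derivative of a :class:`SpectraSet`.

    ``values`` has units of reflectance per nm^alpha and the same shape as
    the source reflectance matrix.
    """

    order: float
    sample_ids: list[str]
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _validate_grid(self.wavelengths)
        if self.values.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError("values shape inconsistent with ids/wavelengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("derivative values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def band_index(self, wavelength_nm: float) -> int:
        idx = int(np.searchsorted(self.wavelengths, wavelength_nm))
        if idx >= self.wavelengths.size or self.wavelengths[idx] != wavelength_nm:
            raise KeyError(f"wavelength {wavelength_nm} nm is not on the grid")
        return idx

    def band(self, wavelength_nm: float) -> np.ndarray:
        return self.values[:, self.band_index(wavelength_nm)]
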