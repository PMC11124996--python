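"""Spectral feature families: empirical indices, trilateral parameters,
and arbitrary two-band indices.

Three feature families feed the chlorophyll models:

* **Empirical vegetation indices** — fixed-band formulas (CARI, GRVI, PRI,
  IPVI, PRI1, SR1, SR3, SR705, SR680, SIPI) evaluated on the smoothed
  reflectance.
* **Trilateral parameters** — scalar descriptors of the blue edge
  (490-530 nm), yellow edge and red edge (670-760 nm): first-derivative
  maxima (Db, Dy, Dr), reflectance extrema (Rg on 510-560, Rr on 650-690),
  derivative-sum areas (SDb, SDy, SDr) and the derived SDr-SDb and SDr/SDy.
* **Two-band indices** — the difference index DI(i,j) = Ri - Rj and the
  soil-adjusted index SAVI(i,j) = (1+L)(Ri - Rj)/(Ri + Rj + L) with
  L = 0.16, where R is the reflectance at any derivative order; these are
  the raw material of the exhaustive band-pair search.

Band lookup is exact integer-nm matching on the grid (no interpolation).
Division by zero yields NaN, flagged and propagated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DerivativeSet, SpectraSet

__all__ = [
    "TwoBandIndexSpec",
    "EMPIRICAL_INDEX_NAMES",
    "TRILATERAL_NAMES",
    "compute_empirical_indices",
    "compute_trilateral",
    "two_band_values",
    "SAVI_L",
    "YELLOW_EDGE_PRINTED",
    "YELLOW_EDGE_CONVENTIONAL",
]

SAVI_L = 0.16

EMPIRICAL_INDEX_NAMES = (
    "CARI", "GRVI", "PRI", "IPVI", "PRI1",
    "SR1", "SR3", "SR705", "SR680", "SIPI",
)
TRILATERAL_NAMES = (
    "Db", "Dy", "Dr", "Rg", "Rr",
    "SDb", "SDy", "SDr", "SDr-SDb", "SDr/SDy",
)

BLUE_EDGE = (490.0, 530.0)
#: yellow-edge window as printed in the source index table
YELLOW_EDGE_PRINTED = (462.0, 642.0)
#: conventional yellow-edge window, offered as an alternative
YELLOW_EDGE_CONVENTIONAL = (560.0, 640.0)
RED_EDGE = (670.0, 760.0)
GREEN_PEAK = (510.0, 560.0)
RED_VALLEY = (650.0, 690.0)


class CoverageError(ValueError):
    """A required wavelength lies outside the spectra grid."""


def _band(spectra: SpectraSet, wl: float) -> np.ndarray:
    try:
        return spectra.band(wl)
    except KeyError as exc:
        raise CoverageError(str(exc)) from exc


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(np.isfinite(out), out, np.nan)


def compute_empirical_indices(
    smoothed: SpectraSet, ipvi_as_printed: bool = False
) -> pd.DataFrame:
    """Evaluate the ten fixed-band empirical indices per sample.

    Parameters
    ----------
    smoothed
        Smoothed reflectance covering at least 445-800 nm.
    ipvi_as_printed
        Use the product form R800*(R800+R670) instead of the conventional
        ratio R800/(R800+R670).

    Returns
    -------
    DataFrame indexed by sample_id with one column per index; cells with a
    zero denominator are NaN.
    """
    r = {
        wl: _band(smoothed, wl)
        for wl in (445, 530, 531, 550, 570, 670, 680, 700, 705, 750, 800)
    }
    if ipvi_as_printed:
        ipvi = r[800] * (r[800] + r[670])
    else:
        ipvi = _safe_divide(r[800], r[800] + r[670])
    out = {
        "CARI": (r[700] - r[670]) - 0.2 * (r[700] + r[670]),
        "GRVI": _safe_divide(r[800], r[550]),
        "PRI": _safe_divide(r[570] - r[530], r[570] + r[530]),
        "IPVI": ipvi,
        "PRI1": _safe_divide(r[531] - r[570], r[531] + r[570]),
        "SR1": _safe_divide(r[750], r[700]),
        "SR3": _safe_divide(r[750], r[550]),
        "SR705": _safe_divide(r[750], r[705]),
        "SR680": _safe_divide(r[800], r[680]),
        "SIPI": _safe_divide(r[800] - r[445], r[800] - r[680]),
    }
    return pd.DataFrame(out, index=pd.Index(smoothed.sample_ids, name="sample_id"))


def _window(wavelengths: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise CoverageError(f"grid does not cover [{lo:g}, {hi:g}] nm")
    return mask


def compute_trilateral(
    smoothed: SpectraSet,
    first_deriv: DerivativeSet,
    yellow_edge: tuple[float, float] = YELLOW_EDGE_PRINTED,
) -> pd.DataFrame:
    """Blue/yellow/red-edge scalar parameters per sample.

    ``first_deriv`` must be the order-1 derivative of ``smoothed``. Sums are
    over inclusive wavelength windows. SDr/SDy is NaN where SDy == 0.
    """
    if first_deriv.order != 1.0:
        raise ValueError(
            f"trilateral parameters need the order-1 derivative, got "
            f"order {first_deriv.order}"
        )
    wl = smoothed.wavelengths
    d = first_deriv.values
    refl = smoothed.reflectance

    blue = _window(wl, *BLUE_EDGE)
    yellow = _window(wl, *yellow_edge)
    red = _window(wl, *RED_EDGE)
    green = _window(wl, *GREEN_PEAK)
    valley = _window(wl, *RED_VALLEY)

    sdb = d[:, blue].sum(axis=1)
    sdy = d[:, yellow].sum(axis=1)
    sdr = d[:, red].sum(axis=1)
    out = {
        "Db": d[:, blue].max(axis=1),
        "Dy": d[:, yellow].max(axis=1),
        "Dr": d[:, red].max(axis=1),
        "Rg": refl[:, green].max(axis=1),
        "Rr": refl[:, valley].min(axis=1),
        "SDb": sdb,
        "SDy": sdy,
        "SDr": sdr,
        "SDr-SDb": sdr - sdb,
        "SDr/SDy": _safe_divide(sdr, sdy),
    }
    return pd.DataFrame(out, index=pd.Index(smoothed.sample_ids, name="sample_id"))


@dataclass(frozen=True)
class TwoBandIndexSpec:
    """One arbitrary two-band index: kind, source derivative order, bands."""

    kind: str
    order: float
    i: float
    j: float

    def __post_init__(self) -> None:
        if self.kind not in ("DI", "SAVI"):
            raise ValueError(f"kind must be 'DI' or 'SAVI', got {self.kind!r}")

    @property
    def name(self) -> str:
        return f"{self.kind}[{self.order:g}]({self.i:g},{self.j:g})"


def two_band_values(deriv: DerivativeSet, spec: TwoBandIndexSpec) -> np.ndarray:
    """Per-sample DI or SAVI value from an order-``alpha`` derivative set.

    DI(i,j) = Ri - Rj; SAVI(i,j) = (1+L)(Ri - Rj)/(Ri + Rj + L), L = 0.16.
    A SAVI denominator of exactly 0 yields NaN for that sample.
    """
    if spec.order != deriv.order:
        raise ValueError(
            f"index spec is for order {spec.order} but derivative set has "
            f"order {deriv.order}"
        )
    ri = deriv.band(spec.i)
    rj = deriv.band(spec.j)
    if spec.kind == "DI":
        return ri - rj
    return _safe_divide((1.0 + SAVI_L) * (ri - rj), ri + rj + SAVI_L)
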