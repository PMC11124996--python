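"""Chlorophyll quantification from ethanol-extract absorbances.

Pigment concentrations in the extract follow the classic two-wavelength
spectrophotometric equations (mg/L):

    Ca = 12.7 D663 - 2.69 D645
    Cb = 22.9 D645 - 4.68 D663
    Ct = 20.21 D645 + 8.02 D663

The coefficients satisfy (12.7 - 4.68) = 8.02 and (22.9 - 2.69) = 20.21, so
Ca + Cb == Ct identically. Concentration converts to content per unit basis
m as C * (V / 1000) / m with extract volume V in mL (default 25 mL, i.e. a
factor 1/(40 m)). With m the leaf area (dm^2) this yields chlorophyll per
unit area (LCC_A, mg/dm^2); with m the fresh weight (g), per unit fresh
weight (LCC_W, mg/g). Specific leaf weight SLW = LCC_A / LCC_W (g/dm^2).

A published variant transposes the Cb coefficients onto the wrong
absorbances; it is available via ``as_printed=True`` for fidelity testing
but breaks the Ca + Cb == Ct identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChlorophyllRecord",
    "chlorophyll_content",
    "lcc_pair",
    "absorbances_from_total",
    "DEFAULT_LEAF_DISK_AREA_DM2",
    "DEFAULT_EXTRACT_VOLUME_ML",
]

DEFAULT_EXTRACT_VOLUME_ML = 25.0
#: nine 1-cm-diameter leaf disks: 9 * pi * 0.25 cm^2, in dm^2
DEFAULT_LEAF_DISK_AREA_DM2 = 9 * np.pi * 0.25 / 100.0


def chlorophyll_content(
    d663,
    d645,
    m,
    volume_ml: float = DEFAULT_EXTRACT_VOLUME_ML,
    as_printed: bool = False,
):
    """Chlorophyll a, b and total content (mg per unit ``m``).

    Parameters
    ----------
    d663, d645
        Extract absorbances at 663 and 645 nm (scalars or arrays, >= 0).
    m
        Normalising basis: leaf area in dm^2 (giving mg/dm^2) or fresh
        weight in g (giving mg/g). Must be positive.
    volume_ml
        Final extract volume in mL.
    as_printed
        Use the transposed chlorophyll-b coefficient ordering
        (22.9 D663 - 4.68 D645) instead of the standard one.

    Returns
    -------
    (chl_a, chl_b, chl_total)
        Contents in mg per unit of ``m``. Negative values (physically
        impossible absorbance pairs) are returned as-is for the caller to
        flag.
    """
    d663 = np.asarray(d663, dtype=float)
    d645 = np.asarray(d645, dtype=float)
    if np.any(d663 < 0) or np.any(d645 < 0):
        raise ValueError("absorbances must be non-negative")
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("normalising basis m must be positive")
    if volume_ml <= 0:
        raise ValueError("extract volume must be positive")
    ca = 12.7 * d663 - 2.69 * d645
    if as_printed:
        cb = 22.9 * d663 - 4.68 * d645
    else:
        cb = 22.9 * d645 - 4.68 * d663
    ct = 20.21 * d645 + 8.02 * d663
    factor = (volume_ml / 1000.0) / m
    return ca * factor, cb * factor, ct * factor


@dataclass
class ChlorophyllRecord:
    """Per-sample absorbances plus the derived chlorophyll traits."""

    sample_id: str
    d663: float
    d645: float
    fresh_weight: float | None = None
    leaf_area: float | None = None
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_ML
    chl_a: float | None = None
    chl_b: float | None = None
    chl_total: float | None = None
    lcc_area: float | None = None
    lcc_weight: float | None = None
    slw: float | None = None


def lcc_pair(record: ChlorophyllRecord) -> ChlorophyllRecord:
    """Fill a record's LCC_A, LCC_W and SLW from its absorbances.

    ``lcc_area`` normalises total chlorophyll by ``leaf_area`` (dm^2),
    ``lcc_weight`` by ``fresh_weight`` (g); ``slw = lcc_area / lcc_weight``.
    Also fills chl_a/chl_b/chl_total on the area basis when available.
    """
    if record.leaf_area is None and record.fresh_weight is None:
        raise ValueError("record needs leaf_area and/or fresh_weight")
    if record.leaf_area is not None:
        if record.leaf_area <= 0:
            raise ValueError("leaf_area must be positive")
        a, b, t = chlorophyll_content(
            record.d663, record.d645, record.leaf_area, record.extract_volume
        )
        record.chl_a, record.chl_b, record.chl_total = float(a), float(b), float(t)
        record.lcc_area = float(t)
    if record.fresh_weight is not None:
        if record.fresh_weight <= 0:
            raise ValueError("fresh_weight must be positive")
        _, _, t = chlorophyll_content(
            record.d663, record.d645, record.fresh_weight, record.extract_volume
        )
        record.lcc_weight = float(t)
    if record.lcc_area is not None and record.lcc_weight is not None:
        record.slw = record.lcc_area / record.lcc_weight
    return record


def absorbances_from_total(
    chl_total_conc_mg_l, ab_ratio: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the extract equations for a given total concentration.

    Given the total pigment concentration in the extract (mg/L) and an
    assumed chlorophyll a:b ratio, solve the 2x2 linear system for the
    absorbance pair (D663, D645). Used by the synthetic-data generator to
    back-fill self-consistent absorbances.
    """
    ct = np.asarray(chl_total_conc_mg_l, dtype=float)
    fa = ab_ratio / (1.0 + ab_ratio)
    # [12.7 -2.69] [d663]   [fa * ct]
    # [-4.68 22.9] [d645] = [(1-fa) * ct]
    det = 12.7 * 22.9 - (-2.69) * (-4.68)
    d663 = (22.9 * fa * ct + 2.69 * (1 - fa) * ct) / det
    d645 = (12.7 * (1 - fa) * ct + 4.68 * fa * ct) / det
    return d663, d645
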