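"""Reading, writing and aligning spectra and label tables.

The interchange format is a wavelength-headed wide CSV: first column
``sample_id``, remaining column headers are wavelengths in nm, one row per
sample. Label tables are ordinary CSVs keyed by ``sample_id`` with trait
columns (``lcc_area`` in mg/dm^2, ``lcc_weight`` in mg/g, optional
absorbances ``d663``/``d645``, ``fresh_weight`` in g, ``leaf_area`` in dm^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GridError, SpectraSet

__all__ = [
    "LabelTable",
    "AlignmentError",
    "read_spectra",
    "write_spectra",
    "read_labels",
    "write_labels",
    "align",
]

DEFAULT_GRID = np.arange(350.0, 1831.0, 1.0)
"""Default expected wavelength grid: 350-1830 nm at 1 nm (1481 bands)."""


class AlignmentError(ValueError):
    """Raised when spectra and labels share no sample ids."""


@dataclass
class LabelTable:
    """Per-sample trait table keyed by unique ``sample_id``."""

    table: pd.DataFrame

    REQUIRED = ("sample_id",)
    TRAITS = ("lcc_area", "lcc_weight")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"label table missing column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicated sample_id {dup!r} in label table")
        for col in self.TRAITS:
            if col in df.columns:
                vals = df[col].dropna()
                if (vals <= 0).any():
                    raise ValueError(f"non-positive values in {col}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]

    def __len__(self) -> int:
        return len(self.table)


def read_spectra(path: str | Path, expected_grid: np.ndarray | None = None) -> SpectraSet:
    """Load a wavelength-headed wide CSV into a validated :class:`SpectraSet`.

    Parameters
    ----------
    path
        CSV with header ``sample_id,<wl0>,<wl1>,...`` and one row per sample.
    expected_grid
        Optional grid the file must match exactly (e.g. ``DEFAULT_GRID``).

    Raises
    ------
    GridError
        Non-uniform or mismatching wavelength header.
    ValueError
        Duplicate ids or non-numeric cells (with row/column location).
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected sample_id plus wavelength columns")
    id_col = df.columns[0]
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise GridError(f"{path}: non-numeric wavelength header: {exc}") from exc
    matrix = np.empty((len(df), wavelengths.size))
    for j, col in enumerate(df.columns[1:]):
        try:
            matrix[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.nonzero(bad.isna().to_numpy())[0][0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row} (sample "
                f"{df[id_col].iloc[row]!r}), column {col}"
            ) from exc
    spectra = SpectraSet(list(df[id_col]), wavelengths, matrix)
    if expected_grid is not None:
        expected = np.asarray(expected_grid, dtype=float)
        if spectra.wavelengths.size != expected.size or not np.array_equal(
            spectra.wavelengths, expected
        ):
            raise GridError(
                f"{path}: grid [{wavelengths[0]:g}..{wavelengths[-1]:g}] "
                f"({wavelengths.size} bands) does not match the expected grid "
                f"[{expected[0]:g}..{expected[-1]:g}] ({expected.size} bands)"
            )
    return spectra


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Write a wide CSV with full (repr round-trip safe) float precision."""
    df = spectra.to_frame()
    df.columns = [f"{w:g}" for w in spectra.wavelengths]
    df.to_csv(path, float_format="%.17g")


def read_labels(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    return LabelTable(df)


def write_labels(labels: LabelTable, path: str | Path) -> None:
    labels.table.to_csv(path, index=False, float_format="%.17g")


def align(
    spectra: SpectraSet, labels: LabelTable
) -> tuple[SpectraSet, pd.DataFrame, list[str]]:
    """Inner-join spectra and labels on ``sample_id``, preserving spectra order.

    Returns the aligned spectra, the aligned label rows (same order) and the
    list of sample ids dropped from either side.

    Raises
    ------
    AlignmentError
        If the two id sets are disjoint.
    """
    if spectra.n_samples == 0 or len(labels) == 0:
        raise AlignmentError("cannot align: empty spectra or label table")
    label_ids = set(labels.sample_ids)
    keep = [i for i, s in enumerate(spectra.sample_ids) if s in label_ids]
    if not keep:
        raise AlignmentError("no sample ids shared between spectra and labels")
    kept_ids = [spectra.sample_ids[i] for i in keep]
    dropped = sorted(
        (set(spectra.sample_ids) | label_ids) - set(kept_ids)
    )
    sub = SpectraSet(
        kept_ids, spectra.wavelengths.copy(), spectra.reflectance[keep]
    )
    lab = (
        labels.table.set_index("sample_id")
        .loc[kept_ids]
        .reset_index()
    )
    return sub, lab, dropped
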