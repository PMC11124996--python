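"""Correlation screening: feature ranking and exhaustive two-band search.

Every candidate feature is scored by its Pearson correlation with the trait
(chlorophyll per unit area or per unit fresh weight). For the two-band
families the search is exhaustive: the index is evaluated for every ordered
band pair (i, j) of a derivative-transformed spectra matrix and correlated
with the trait, blockwise so peak memory stays O(block_size x n_bands x
n_samples). The |r| argmax identifies the optimal pair; ties break to the
smallest i, then smallest j, for determinism.

:class:`TwoBandCorrelationSelector` is the scikit-learn-shaped core
(``fit(X, y)`` with fitted ``r_matrix_``, ``r_max_``, ``i_max_``,
``j_max_``); :func:`two_band_correlation` wraps it for
:class:`~specfrac.containers.DerivativeSet` inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import DerivativeSet
from .indices import SAVI_L, TwoBandIndexSpec

__all__ = [
    "SelectionError",
    "pearson_r",
    "TwoBandCorrelationSelector",
    "TwoBandCorrelationResult",
    "two_band_correlation",
    "rank_features",
    "FeatureCombination",
    "build_combinations",
]


class SelectionError(ValueError):
    """No defined correlation available to select from."""


def _pair_correlations(
    X: np.ndarray,
    Y: np.ndarray,
    kind: str,
    block_size: int,
    triangular: bool,
) -> np.ndarray:
    """Pearson r of index(i, j) with every target column, blockwise.

    Evaluates the two-band index explicitly for every ordered pair in
    blocks of ``block_size`` rows (peak memory O(block_size * n_bands *
    n_samples)) and correlates it with each column of ``Y``. Returns an
    ``(n_bands, n_bands, n_targets)`` array with NaN where the correlation
    is undefined (zero variance or a non-finite index value).
    """
    n_samples, n_bands = X.shape
    n_targets = Y.shape[1]
    Yc = Y - Y.mean(axis=0)
    y_ss = (Yc ** 2).sum(axis=0)  # (T,)
    R = np.empty((n_bands, n_bands, n_targets))
    XT = np.ascontiguousarray(X.T)           # (B, n)
    XcT = XT - XT.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        for start in range(0, n_bands, block_size):
            stop = min(start + block_size, n_bands)
            b = stop - start
            if kind == "DI":
                # differences of centred bands are already centred
                v = XcT[start:stop, None, :] - XcT[None, :, :]
            else:
                xi = XT[start:stop, None, :]
                xj = XT[None, :, :]
                v = (1.0 + SAVI_L) * (xi - xj)
                v /= xi + xj + SAVI_L
                v -= v.mean(axis=2, keepdims=True)
            num = v.reshape(-1, n_samples) @ Yc          # (b*B, T)
            den = np.einsum("ijk,ijk->ij", v, v)         # (b, B)
            blk = num.reshape(b, n_bands, n_targets)
            blk = blk / np.sqrt(den[:, :, None] * y_ss)
            R[start:stop] = blk
    R[~np.isfinite(R)] = np.nan
    if triangular:
        rows, cols = np.tril_indices(n_bands)
        R[rows, cols] = np.nan
    return R


def _argmax_abs(r: np.ndarray) -> tuple[int, int]:
    """|r| argmax with row-major tie-breaking (smallest i, then smallest j)."""
    if np.all(np.isnan(r)):
        raise SelectionError(
            "every band pair has an undefined correlation (constant index values)"
        )
    best = int(np.nanargmax(np.abs(r).ravel()))
    return divmod(best, r.shape[1])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN if either side is constant.

    >>> pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
    0.8
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0.0:
        return float("nan")
    return float((xc @ yc) / den)


class TwoBandCorrelationSelector(BaseEstimator):
    """Exhaustive band-pair screen for one index kind on one derivative order.

    Parameters
    ----------
    kind : {'DI', 'SAVI'}, default 'DI'
        Two-band index evaluated at every ordered pair.
    block_size : int, default 64
        Rows of the pair matrix computed per block.
    triangular : bool, default False
        Compute only pairs i < j (DI is antisymmetric, so the full matrix
        carries no extra information); the full square is the default to
        mirror the published correlation heatmaps.

    Attributes
    ----------
    r_matrix_ : ndarray of shape (n_bands, n_bands)
        Pearson r of index(i, j) with y; NaN where undefined.
    r_max_ : float
        Signed r at the |r| argmax over defined cells.
    i_max_, j_max_ : int
        Band indices (into the fitted X's columns) of the argmax.
    """

    def __init__(self, kind: str = "DI", block_size: int = 64,
                 triangular: bool = False):
        self.kind = kind
        self.block_size = block_size
        self.triangular = triangular

    def fit(self, X, y):
        if self.kind not in ("DI", "SAVI"):
            raise ValueError(f"kind must be 'DI' or 'SAVI', got {self.kind!r}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_bands)")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must equal n_samples")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")

        r = _pair_correlations(
            X, y[:, None], self.kind, self.block_size, self.triangular
        )[:, :, 0]
        self.i_max_, self.j_max_ = _argmax_abs(r)
        self.r_matrix_ = r
        self.r_max_ = float(r[self.i_max_, self.j_max_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Column vector of the selected index at the argmax pair."""
        check_is_fitted(self, "r_matrix_")
        X = np.asarray(X, dtype=float)
        ri, rj = X[:, self.i_max_], X[:, self.j_max_]
        if self.kind == "DI":
            return (ri - rj)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (1.0 + SAVI_L) * (ri - rj) / (ri + rj + SAVI_L)
        return np.where(np.isfinite(v), v, np.nan)[:, None]


@dataclass
class TwoBandCorrelationResult:
    """Argmax summary of one exhaustive band-pair screen."""

    kind: str
    order: float
    r_matrix: np.ndarray
    r_max: float
    i_max: float  # wavelength, nm
    j_max: float  # wavelength, nm

    @property
    def spec(self) -> TwoBandIndexSpec:
        return TwoBandIndexSpec(self.kind, self.order, self.i_max, self.j_max)

    def to_long_frame(self, wavelengths: np.ndarray) -> pd.DataFrame:
        """Heatmap-ready long table (i, j, r)."""
        wl = np.asarray(wavelengths, dtype=float)
        ii, jj = np.meshgrid(wl, wl, indexing="ij")
        return pd.DataFrame(
            {"i": ii.ravel(), "j": jj.ravel(), "r": self.r_matrix.ravel()}
        )

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "order": self.order,
            "r_max": self.r_max,
            "i_max": self.i_max,
            "j_max": self.j_max,
        }


def two_band_correlation(
    deriv: DerivativeSet,
    kind: str,
    target: np.ndarray,
    block_size: int = 64,
    triangular: bool = False,
) -> TwoBandCorrelationResult:
    """Exhaustive band-pair correlation screen on a derivative set."""
    sel = TwoBandCorrelationSelector(
        kind=kind, block_size=block_size, triangular=triangular
    ).fit(deriv.values, np.asarray(target, dtype=float))
    return TwoBandCorrelationResult(
        kind=kind,
        order=deriv.order,
        r_matrix=sel.r_matrix_,
        r_max=sel.r_max_,
        i_max=float(deriv.wavelengths[sel.i_max_]),
        j_max=float(deriv.wavelengths[sel.j_max_]),
    )


def two_band_correlation_multi(
    deriv: DerivativeSet,
    kind: str,
    targets: dict[str, np.ndarray],
    block_size: int = 64,
    triangular: bool = False,
    keep_matrix: bool = False,
) -> dict[str, TwoBandCorrelationResult]:
    """Screen one derivative set against several traits in a single pass.

    The expensive explicit pair-index evaluation is shared across traits;
    the result per trait is identical to :func:`two_band_correlation`.
    Matrices are dropped by default (argmax summaries only) to bound memory
    over many kind/order/trait screens.
    """
    names = list(targets)
    Y = np.column_stack([np.asarray(targets[t], dtype=float) for t in names])
    R = _pair_correlations(deriv.values, Y, kind, block_size, triangular)
    out = {}
    for t_idx, name in enumerate(names):
        r = R[:, :, t_idx]
        i, j = _argmax_abs(r)
        out[name] = TwoBandCorrelationResult(
            kind=kind,
            order=deriv.order,
            r_matrix=r if keep_matrix else np.empty((0, 0)),
            r_max=float(r[i, j]),
            i_max=float(deriv.wavelengths[i]),
            j_max=float(deriv.wavelengths[j]),
        )
    return out


def rank_features(
    features: pd.DataFrame, target: np.ndarray, k: int | None = None
) -> pd.DataFrame:
    """Rank feature columns by |Pearson r| with the target, descending.

    NaN feature cells drop the affected samples pairwise; columns whose
    correlation is undefined are excluded from the ranking.

    Returns a DataFrame with columns ``feature`` and ``r`` (signed).
    """
    if features.shape[1] == 0:
        raise SelectionError("empty feature table")
    y = np.asarray(target, dtype=float)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        r = pearson_r(x[ok], y[ok])
        if np.isfinite(r):
            rows.append((name, r))
    if not rows:
        raise SelectionError("no feature has a defined correlation")
    out = pd.DataFrame(rows, columns=["feature", "r"])
    out = out.reindex(
        out["r"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    if k is not None:
        if k > len(out):
            raise SelectionError(
                f"requested top {k} but only {len(out)} ranked features"
            )
        out = out.head(k)
    return out


@dataclass
class FeatureCombination:
    """A named model-input design: features sorted by |r| descending."""

    name: str
    members: pd.DataFrame  # columns: feature, r

    def __post_init__(self) -> None:
        absr = self.members["r"].abs().to_numpy()
        if np.any(np.diff(absr) > 1e-12):
            raise ValueError("members must be sorted by |r| descending")

    @property
    def feature_names(self) -> list[str]:
        return list(self.members["feature"])


def build_combinations(
    empirical: pd.DataFrame,
    trilateral: pd.DataFrame,
    twoband: pd.DataFrame,
    k: int = 7,
) -> dict[str, FeatureCombination]:
    """Assemble the four model-input combinations from ranked families.

    1. top-k empirical indices,
    2. top-k trilateral parameters,
    3. top-k two-band derivative-order features,
    4. top-k of the pooled union of all three families.

    Raises :class:`SelectionError` naming the family when one has fewer
    than ``k`` ranked features.
    """
    fams = {
        "combination 1": empirical,
        "combination 2": trilateral,
        "combination 3": twoband,
    }
    out: dict[str, FeatureCombination] = {}
    for name, fam in fams.items():
        if len(fam) < k:
            raise SelectionError(
                f"{name} family has {len(fam)} features, fewer than k={k}"
            )
        out[name] = FeatureCombination(name, fam.head(k).reset_index(drop=True))
    pooled = pd.concat([empirical, trilateral, twoband], ignore_index=True)
    pooled = pooled.drop_duplicates(subset="feature", keep="first")
    pooled = pooled.reindex(
        pooled["r"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    if len(pooled) < k:
        raise SelectionError(f"pooled family has {len(pooled)} features < k={k}")
    out["combination 4"] = FeatureCombination(
        "combination 4", pooled.head(k).reset_index(drop=True)
    )
    return out
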