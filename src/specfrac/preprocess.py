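"""Savitzky-Golay smoothing and Grünwald-Letnikov fractional differentiation.

Spectra are smoothed first, then differentiated at orders alpha in [0, 2]
(default grid 0, 0.5, 1, 1.5, 2). The fractional derivative of order alpha
of a discrete series R on a uniform grid with step h is the Grünwald-
Letnikov construction

    D^alpha R(t) = h^(-alpha) * sum_{k=0..t} w_k R(t - k),
    w_0 = 1,  w_k = w_{k-1} * (k - 1 - alpha) / k,

using the full available history from the series start (expanding window at
the left boundary). alpha = 0 is the identity; alpha = 1 reproduces the
backward first difference divided by h at every interior point.

Both steps are exposed as scikit-learn transformers (:class:`SavitzkyGolay`,
:class:`GrunwaldLetnikov`) operating on ``(n_samples, n_bands)`` arrays; the
module-level functions wrap them for :class:`~specfrac.containers.SpectraSet`
inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import DerivativeSet, SpectraSet

__all__ = [
    "SavitzkyGolay",
    "GrunwaldLetnikov",
    "gl_weights",
    "sg_smooth",
    "fractional_derivative",
    "DEFAULT_ORDERS",
]

DEFAULT_ORDERS = (0.0, 0.5, 1.0, 1.5, 2.0)


def gl_weights(alpha: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` Grünwald-Letnikov weights for order ``alpha``.

    ``w_0 = 1``; ``w_k = w_{k-1} (k - 1 - alpha) / k``. For integer alpha the
    weights vanish beyond index alpha (signed binomial coefficients).

    >>> gl_weights(1.0, 3)
    array([ 1., -1.,  0.])
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    w = np.empty(n_terms)
    w[0] = 1.0
    for k in range(1, n_terms):
        w[k] = w[k - 1] * (k - 1 - alpha) / k
    return w


class SavitzkyGolay(BaseEstimator, TransformerMixin):
    """Savitzky-Golay local polynomial least-squares smoother.

    Each spectrum is replaced bandwise by the value of the least-squares
    polynomial of degree ``polyorder`` fitted over a sliding window of
    ``window_length`` bands; terminal windows use polynomial extrapolation
    (scipy's ``mode='interp'``). Polynomials of degree <= ``polyorder`` pass
    through unchanged.

    Parameters
    ----------
    window_length : int, default 9
        Odd window size in bands.
    polyorder : int, default 2
        Degree of the fitted polynomial; must be < ``window_length``.
    """

    def __init__(self, window_length: int = 9, polyorder: int = 2):
        self.window_length = window_length
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = check_array(X)
        if self.window_length % 2 != 1:
            raise ValueError("window_length must be odd")
        if self.polyorder >= self.window_length:
            raise ValueError("polyorder must be < window_length")
        if X.shape[1] < self.window_length:
            raise ValueError(
                f"spectrum has {X.shape[1]} bands, shorter than "
                f"window_length={self.window_length}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        return savgol_filter(
            X, self.window_length, self.polyorder, axis=1, mode="interp"
        )


class GrunwaldLetnikov(BaseEstimator, TransformerMixin):
    """Fractional-order differentiation transformer (GL construction).

    Parameters
    ----------
    alpha : float, default 1.0
        Differentiation order, in [0, 2].
    step : float, default 1.0
        Grid spacing h in nm; output is scaled by ``h**-alpha``.
    truncation : int or None, default None
        If given, only the first ``truncation`` GL weights are used
        (a finite memory window); ``None`` means full history.
    """

    def __init__(self, alpha: float = 1.0, step: float = 1.0,
                 truncation: int | None = None):
        self.alpha = alpha
        self.step = step
        self.truncation = truncation

    def fit(self, X, y=None):
        X = check_array(X)
        if not 0.0 <= self.alpha <= 2.0:
            raise ValueError(f"alpha={self.alpha} outside the supported [0, 2]")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.truncation is not None and self.truncation < 1:
            raise ValueError("truncation must be >= 1")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if self.alpha == 0.0:
            # identity operator: return exactly, not via convolution round-off
            return X.copy()
        n_bands = X.shape[1]
        n_terms = n_bands if self.truncation is None else min(self.truncation, n_bands)
        w = gl_weights(self.alpha, n_terms)
        # drop exactly-zero tail weights (integer orders) so the causal
        # convolution stays exact there
        nonzero = np.nonzero(w)[0]
        w = w[: nonzero[-1] + 1]
        out = np.empty_like(X)
        for s in range(X.shape[0]):
            # expanding-window weighted sum over history == causal convolution
            out[s] = np.convolve(X[s], w)[:n_bands]
        out *= self.step ** (-self.alpha)
        return out


def sg_smooth(spectra: SpectraSet, window_length: int = 9, polyorder: int = 2) -> SpectraSet:
    """Smooth a :class:`SpectraSet`, keeping ids and grid unchanged."""
    est = SavitzkyGolay(window_length, polyorder).fit(spectra.reflectance)
    return spectra.copy_with(est.transform(spectra.reflectance))


def fractional_derivative(
    spectra: SpectraSet, alpha: float, truncation: int | None = None
) -> DerivativeSet:
    """Order-``alpha`` GL derivative of every spectrum in a set."""
    est = GrunwaldLetnikov(alpha=alpha, step=spectra.step, truncation=truncation)
    values = est.fit(spectra.reflectance).transform(spectra.reflectance)
    return DerivativeSet(
        order=float(alpha),
        sample_ids=list(spectra.sample_ids),
        wavelengths=spectra.wavelengths.copy(),
        values=values,
    )
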