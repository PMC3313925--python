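"""SVD analysis of time-resolved difference-spectra matrices.

Decomposes a wavelength x delay matrix into spectral components (U),
singular values and temporal amplitude courses (V); ranks components as
physically meaningful by the lag-1 autocorrelation of their vectors (smooth
vectors correlate near 1, noise near 0); and characterizes the relaxation
carried by a selected temporal course with a stretched-exponential fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .fitting import MultiExponentialModel
from .synth import SpectraSet

__all__ = [
    "autocorrelation",
    "SVDResult",
    "SpectraSVD",
    "decompose",
    "select_components",
    "component_course_fit",
]


def autocorrelation(x: np.ndarray) -> float:
    """Lag-1 autocorrelation statistic c = sum_k x_k x_{k+1} of a unit-norm vector."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        return 0.0
    x = x / norm
    return float(np.sum(x[:-1] * x[1:]))


@dataclass
class SVDResult:
    """Full SVD of a spectra matrix with per-column autocorrelations.

    ``U`` is wavelength x rank, ``V`` delay x rank; columns are orthonormal
    and signs fixed so the largest-magnitude element of each U column is
    positive.  Component indices in reports are 1-based, following the
    U1/V1 numbering convention of the field.
    """

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray
    u_autocorr: np.ndarray
    v_autocorr: np.ndarray

    def reconstruct(self, rank: int | None = None) -> np.ndarray:
        r = rank or self.s.size
        return (self.U[:, :r] * self.s[:r]) @ self.V[:, :r].T


class SpectraSVD(BaseEstimator):
    """Scikit-learn-style wrapper for the decomposition + selection step.

    After :meth:`fit`: ``result_`` (an :class:`SVDResult`), ``U_``, ``s_``,
    ``V_``, ``significant_`` (1-based indices passing the autocorrelation
    threshold on both U and V columns).
    """

    def __init__(self, autocorr_threshold: float = 0.8):
        self.autocorr_threshold = autocorr_threshold

    def fit(self, spectra: SpectraSet | np.ndarray):
        matrix = spectra.dA if isinstance(spectra, SpectraSet) else np.asarray(spectra)
        self.result_ = decompose(matrix)
        self.U_, self.s_, self.V_ = self.result_.U, self.result_.s, self.result_.V
        self.significant_ = select_components(self.result_, self.autocorr_threshold)
        return self

    def transform(self, spectra: SpectraSet | np.ndarray) -> np.ndarray:
        """Project a matrix onto the fitted spectral basis (returns V * s layout)."""
        matrix = spectra.dA if isinstance(spectra, SpectraSet) else np.asarray(spectra)
        return matrix.T @ self.U_


def decompose(spectra: SpectraSet | np.ndarray) -> SVDResult:
    """Full SVD with the sign convention and autocorrelation statistics."""
    matrix = spectra.dA if isinstance(spectra, SpectraSet) else np.asarray(spectra)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("spectra matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(matrix, full_matrices=False)
    V = Vt.T
    # reproducible sign: largest-|.| element of each spectral column positive
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    u_ac = np.array([autocorrelation(U[:, j]) for j in range(U.shape[1])])
    v_ac = np.array([autocorrelation(V[:, j]) for j in range(V.shape[1])])
    return SVDResult(U=U, s=s, V=V, u_autocorr=u_ac, v_autocorr=v_ac)


def select_components(result: SVDResult, autocorr_threshold: float = 0.8) -> list[int]:
    """1-based indices whose U and V autocorrelations both exceed the threshold."""
    keep = (result.u_autocorr > autocorr_threshold) & (
        result.v_autocorr > autocorr_threshold
    )
    return [int(i) + 1 for i in np.flatnonzero(keep)]


def component_course_fit(
    v: np.ndarray,
    delays: np.ndarray,
    n_components: int = 3,
    stretched: bool = True,
    **kwargs,
) -> MultiExponentialModel:
    """Fit a temporal SVD course with a sum of (stretched) exponentials.

    A free offset is always included: whether measured amplitude courses
    are baseline-shifted is not knowable from the decomposition alone.
    """
    model = MultiExponentialModel(
        n_components=n_components, stretched=stretched, fit_offset=True, **kwargs
    )
    return model.fit(np.asarray(delays, float), np.asarray(v, float))
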