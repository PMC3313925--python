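"""Eyring transition-state machinery.

Activation free energies from rate constants, temperature scaling of whole
rate sets, and linear Eyring-plot regression for activation enthalpies and
entropies.  Conventions: energies in kcal/mol, a transmission coefficient
of 1, and second-order rates referred to a 1 M standard state.  Activation
free energies are reported at 298.15 K by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .scheme import RateSet

__all__ = [
    "R_KCAL",
    "T_REF",
    "dg_from_rate",
    "rate_at_temperature",
    "ActivationParams",
    "activation_from_rate",
    "EyringRegression",
    "fit_eyring",
    "ActivationSet",
    "rates_at_temperature",
    "default_activation_set",
]

R_KCAL = 1.987204259e-3  # gas constant, kcal/mol/K
K_B = 1.380649e-23       # Boltzmann constant, J/K
H_PLANCK = 6.62607015e-34  # Planck constant, J*s
T_REF = 298.15           # default reporting temperature, K


def dg_from_rate(k: float, T: float = T_REF) -> float:
    """Activation free energy (kcal/mol) of a rate constant at temperature T.

    dG = R*T*ln(kB*T / (h*k)); k in s^-1 (or M^-1 s^-1 on a 1 M standard
    state for second-order rates).
    """
    if k <= 0:
        raise ValueError(f"rate must be positive, got {k}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return R_KCAL * T * math.log(K_B * T / (H_PLANCK * k))


@dataclass(frozen=True)
class ActivationParams:
    """Activation enthalpy/entropy pair for one rate constant.

    dH in kcal/mol, dS in kcal/mol/K; dG(T) = dH - T*dS by construction.
    Standard errors are populated by :class:`EyringRegression`.
    """

    dh: float
    ds: float
    dh_stderr: float = float("nan")
    ds_stderr: float = float("nan")

    def dg(self, T: float = T_REF) -> float:
        return self.dh - T * self.ds

    def dg_stderr(self, T: float = T_REF) -> float:
        # slope/intercept errors treated as independent (upper bound)
        return math.hypot(self.dh_stderr, T * self.ds_stderr)

    def rate(self, T: float) -> float:
        return rate_at_temperature(self, T)


def rate_at_temperature(params: ActivationParams, T: float) -> float:
    """Eyring rate k(T) = (kB*T/h) * exp(-dH/(R*T) + dS/R)."""
    return (K_B * T / H_PLANCK) * math.exp(
        -params.dh / (R_KCAL * T) + params.ds / R_KCAL
    )


def activation_from_rate(k: float, T: float, dh: float) -> ActivationParams:
    """Activation parameters with a chosen enthalpy, anchored to k at T.

    Solves dS = (dH - dG(T)) / T so that the Eyring rate reproduces ``k``
    exactly at the anchor temperature; used to build synthetic temperature
    series.
    """
    dg = dg_from_rate(k, T)
    return ActivationParams(dh=dh, ds=(dh - dg) / T)


class EyringRegression(BaseEstimator):
    """Ordinary least squares of ln(k*h/(kB*T)) against 1/T.

    The slope is -dH/R and the intercept dS/R.  Follows the scikit-learn
    estimator protocol: ``fit(T, k)`` stores ``params_`` with standard
    errors propagated from the regression.
    """

    def __init__(self, min_span_K: float = 10.0):
        self.min_span_K = min_span_K

    def fit(self, T: Sequence[float], k: Sequence[float]) -> "EyringRegression":
        T = np.asarray(T, dtype=float)
        k = np.asarray(k, dtype=float)
        if T.shape != k.shape or T.ndim != 1:
            raise ValueError("T and k must be 1-d arrays of equal length")
        if T.size < 3:
            raise ValueError("Eyring fit needs at least 3 temperatures")
        if T.max() - T.min() < self.min_span_K:
            raise ValueError(
                f"temperature span {T.max() - T.min():.1f} K below "
                f"{self.min_span_K} K minimum"
            )
        if np.any(k <= 0):
            raise ValueError("all rates must be positive")
        x = 1.0 / T
        y = np.log(k * H_PLANCK / (K_B * T))
        res = stats.linregress(x, y)
        dh = -res.slope * R_KCAL
        ds = res.intercept * R_KCAL
        self.params_ = ActivationParams(
            dh=dh,
            ds=ds,
            dh_stderr=res.stderr * R_KCAL,
            ds_stderr=res.intercept_stderr * R_KCAL,
        )
        self.rvalue_ = res.rvalue
        self.n_ = T.size
        return self

    def dg(self, T: float = T_REF) -> float:
        return self.params_.dg(T)


def fit_eyring(
    rates_by_temperature: Sequence[tuple[float, float]]
) -> ActivationParams:
    """Functional wrapper over :class:`EyringRegression`."""
    T, k = zip(*rates_by_temperature)
    return EyringRegression().fit(np.array(T), np.array(k)).params_


# ---------------------------------------------------------------------------
# whole-RateSet temperature scaling

ActivationSet = Mapping[str, ActivationParams]

# Activation enthalpies (kcal/mol) used to synthesize temperature series.
# Chosen to reflect the qualitative pattern of the measured barriers: nearly
# athermal bound-state conversion, modest enthalpy for the deoxy conversion
# and ligand entry, a strongly activated solvent exit (the escape channel is
# thermally activated) and bond-breaking enthalpies dominating dissociation.
DEFAULT_DH = {
    "k1": 0.5, "km1": 0.5,
    "k2": 3.0, "km2": 3.0,
    "k3": 3.0, "km3": 3.0,
    "kin_r": 4.0, "kin_t": 4.0,
    "kout": 8.0,
    "kg_r": 5.0, "kg_t": 6.0,
    "kdiss_r": 15.0, "kdiss_t": 15.0,
    "kmig_r": 5.0, "kret_r": 5.0,
    "kmig_t": 5.0, "kret_t": 5.0,
}


def default_activation_set(
    rates: RateSet, T_anchor: float = 293.15, dh: Mapping[str, float] | None = None
) -> dict[str, ActivationParams]:
    """Activation parameters for every rate, anchored at ``T_anchor``.

    The enthalpies default to :data:`DEFAULT_DH`; entropies are solved so
    that each Eyring rate reproduces the anchor rate exactly.
    """
    dh = dict(DEFAULT_DH, **(dh or {}))
    return {
        name: activation_from_rate(value, T_anchor, dh[name])
        for name, value in rates.as_dict().items()
    }


def rates_at_temperature(activation: ActivationSet, T: float) -> RateSet:
    """Evaluate a full activation set into a :class:`RateSet` at T."""
    return RateSet(**{name: rate_at_temperature(p, T) for name, p in activation.items()})
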