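"""Regression machinery for kinetic traces.

Three layers: (multi/stretched-)exponential relaxation fits backed by lmfit,
the linear k_obs-vs-[CO] regression of pseudo-first-order apparent rates,
and the global least-squares fit of the reaction-scheme rate constants to
several traces measured under different conditions simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from . import scheme
from .scheme import Conditions, IntegrationError, KineticTrace, RateSet

__all__ = [
    "FitResult",
    "MultiExponentialModel",
    "fit_multiexponential",
    "kobs_vs_concentration",
    "GlobalSchemeFit",
    "global_fit",
]


@dataclass
class FitResult:
    """Container for any least-squares result in this package.

    ``params`` maps parameter names to best-fit values; ``stderr`` carries
    matching standard errors (NaN when unavailable).  ``chisqr`` is the
    residual sum of squares actually achieved on the stored data.
    """

    params: dict[str, float]
    stderr: dict[str, float]
    chisqr: float
    ndata: int
    nvarys: int
    success: bool
    message: str = ""
    residual_norms: dict[str, float] = field(default_factory=dict)
    covar: np.ndarray | None = None

    @property
    def redchi(self) -> float:
        dof = max(self.ndata - self.nvarys, 1)
        return self.chisqr / dof


# ---------------------------------------------------------------------------
# multi-exponential / stretched-exponential fits


def _multiexp_eval(t, params, n_components, stretched):
    y = np.full_like(t, params["offset"].value, dtype=float)
    for i in range(1, n_components + 1):
        tau = 10.0 ** params[f"logtau{i}"].value
        beta = params[f"beta{i}"].value if stretched else 1.0
        y += params[f"amp{i}"].value * np.exp(-((t / tau) ** beta))
    return y


class MultiExponentialModel(BaseEstimator):
    """Sum-of-exponentials relaxation model y(t) = y_inf + sum A_i exp[-(t/tau_i)^beta_i].

    With ``stretched=False`` every beta_i is fixed at 1 (plain
    multi-exponential); otherwise each beta_i is free on (0.2, 1].
    Lifetimes are fitted in log10 space and reported sorted ascending;
    amplitude fractions are available after fitting.  Several restarts with
    jittered initial lifetimes guard against local minima.

    Attributes set by :meth:`fit`: ``lifetimes_``, ``amplitudes_``,
    ``betas_``, ``offset_``, ``fractions_``, ``result_`` (a
    :class:`FitResult`), ``stderr_lifetimes_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        stretched: bool = False,
        fit_offset: bool = True,
        init_lifetimes: Sequence[float] | None = None,
        init_amplitudes: Sequence[float] | None = None,
        n_restarts: int = 4,
        seed: int = 0,
        max_nfev: int = 20000,
    ):
        self.n_components = n_components
        self.stretched = stretched
        self.fit_offset = fit_offset
        self.init_lifetimes = init_lifetimes
        self.init_amplitudes = init_amplitudes
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_nfev = max_nfev

    # -- helpers ----------------------------------------------------------
    def _make_params(self, t, y, logtaus, amps):
        lo, hi = np.log10(t[0]) - 1.5, np.log10(t[-1]) + 1.5
        params = lmfit.Parameters()
        span = float(y.max() - y.min()) or 1.0
        for i in range(self.n_components):
            params.add(f"logtau{i + 1}", value=float(logtaus[i]), min=lo, max=hi)
            params.add(
                f"amp{i + 1}", value=float(amps[i]),
                min=-3.0 * span, max=3.0 * span,
            )
            if self.stretched:
                params.add(f"beta{i + 1}", value=0.9, min=0.2, max=1.0)
        params.add(
            "offset", value=float(y[-1]) if self.fit_offset else 0.0,
            vary=self.fit_offset,
            min=float(y.min()) - span, max=float(y.max()) + span,
        )
        return params

    def fit(self, t: np.ndarray, y: np.ndarray, sigma: float | None = None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if t.size < 5 * self.n_components:
            raise ValueError(
                f"need at least {5 * self.n_components} points for "
                f"{self.n_components} components, got {t.size}"
            )
        nc = self.n_components
        if self.init_lifetimes is not None:
            if len(self.init_lifetimes) != nc:
                raise ValueError("init_lifetimes length must equal n_components")
            logtaus0 = np.log10(np.asarray(self.init_lifetimes, dtype=float))
        else:
            # spread initial lifetimes across the observed decades
            logtaus0 = np.linspace(np.log10(t[0]) + 0.5, np.log10(t[-1]) - 0.5, nc)
        if self.init_amplitudes is not None:
            amps0 = np.asarray(self.init_amplitudes, dtype=float)
        else:
            amps0 = np.full(nc, (y[0] - y[-1]) / nc)

        def residual(params):
            r = _multiexp_eval(t, params, nc, self.stretched) - y
            return r / sigma if sigma else r

        rng = np.random.default_rng(self.seed)
        best = None
        for trial in range(max(1, self.n_restarts)):
            jitter = 0.0 if trial == 0 else rng.uniform(-0.5, 0.5, size=nc)
            params = self._make_params(t, y, logtaus0 + jitter, amps0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = lmfit.minimize(
                    residual, params, method="least_squares",
                    max_nfev=self.max_nfev, nan_policy="omit",
                )
            if best is None or out.chisqr < best.chisqr:
                best = out
        out = best

        order = np.argsort([out.params[f"logtau{i + 1}"].value for i in range(nc)])
        self.lifetimes_ = np.array(
            [10.0 ** out.params[f"logtau{i + 1}"].value for i in order]
        )
        self.amplitudes_ = np.array(
            [out.params[f"amp{i + 1}"].value for i in order]
        )
        self.betas_ = (
            np.array([out.params[f"beta{i + 1}"].value for i in order])
            if self.stretched else np.ones(nc)
        )
        self.offset_ = out.params["offset"].value
        total = np.sum(np.abs(self.amplitudes_))
        self.fractions_ = (
            np.abs(self.amplitudes_) / total if total > 0 else np.zeros(nc)
        )
        self.stderr_lifetimes_ = np.array([
            (out.params[f"logtau{i + 1}"].stderr or np.nan)
            * np.log(10.0) * 10.0 ** out.params[f"logtau{i + 1}"].value
            for i in order
        ])
        pvals = {name: p.value for name, p in out.params.items()}
        perrs = {name: (p.stderr if p.stderr is not None else np.nan)
                 for name, p in out.params.items()}
        if not out.success:
            warnings.warn(f"multi-exponential fit did not converge: {out.message}")
        self.result_ = FitResult(
            params=pvals, stderr=perrs, chisqr=float(out.chisqr),
            ndata=t.size, nvarys=out.nvarys, success=bool(out.success),
            message=str(out.message),
            covar=getattr(out, "covar", None),
        )
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset_, dtype=float)
        for A, tau, beta in zip(self.amplitudes_, self.lifetimes_, self.betas_):
            y += A * np.exp(-((t / tau) ** beta))
        return y


def fit_multiexponential(
    trace: KineticTrace | tuple[np.ndarray, np.ndarray],
    n_components: int = 2,
    stretched: bool = False,
    init: Mapping[str, Sequence[float]] | None = None,
    **kwargs,
) -> MultiExponentialModel:
    """Fit a (stretched-)exponential sum to a trace; returns the fitted model."""
    if isinstance(trace, KineticTrace):
        t, y, sigma = trace.times, trace.signal, trace.sigma
    else:
        t, y = trace
        sigma = None
    init = init or {}
    model = MultiExponentialModel(
        n_components=n_components, stretched=stretched,
        init_lifetimes=init.get("lifetimes"),
        init_amplitudes=init.get("amplitudes"),
        **kwargs,
    )
    return model.fit(t, y, sigma=sigma)


def kobs_vs_concentration(
    pairs: Sequence[tuple[float, float]]
) -> dict[str, float]:
    """Second-order rate from the linear [CO] dependence of apparent rates.

    Ordinary least squares of k_obs against CO molarity; the slope is the
    apparent second-order binding constant (M^-1 s^-1).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 concentrations")
    conc, kobs = map(np.asarray, zip(*pairs))
    res = stats.linregress(conc.astype(float), kobs.astype(float))
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "slope_stderr": res.stderr,
        "intercept_stderr": res.intercept_stderr,
        "rvalue": res.rvalue,
    }


# ---------------------------------------------------------------------------
# global fit of the reaction scheme


class GlobalSchemeFit(BaseEstimator):
    """Simultaneous least-squares fit of scheme rate constants to several traces.

    Residuals are computed in linear signal space on each trace's stored
    (log-spaced) grid, so every decade of time contributes comparable
    weight.  Free rates are optimized in log10 space (positivity by
    construction) with a trust-region reflective solver; parameters are
    shared across all traces (the linkage the simultaneous-analysis design
    relies on).  Parameters not listed as free are returned bit-identical
    to their input values.  Optional multi-start jitters the starting point
    by up to half a decade to probe the multi-modal landscape.

    The search box defaults to one decade around the initial estimate:
    rate constants entering such fits are known to order of magnitude from
    the geminate/bimolecular phase positions, and an unbounded search lets
    a compensation branch of the sloppy t-channel parameters (kin_t down,
    kg_t up, their product roughly fixed) absorb noise at the expense of
    every other rate.

    Attributes after :meth:`fit`: ``rates_`` (best-fit :class:`RateSet`),
    ``result_`` (:class:`FitResult` with log10-space standard errors mapped
    to relative errors), ``per_trace_chisqr_``.
    """

    def __init__(
        self,
        free: Sequence[str] = ("kin_r", "kin_t", "kg_r", "kg_t", "k3", "km3", "kout"),
        bound_decades: float = 1.0,
        n_starts: int = 1,
        start_spread: float = 0.5,
        seed: int = 0,
        weighting: str = "none",
        rtol: float = 1e-8,
        max_nfev: int | None = None,
        xtol: float = 1e-10,
    ):
        self.free = free
        self.bound_decades = bound_decades
        self.n_starts = n_starts
        self.start_spread = start_spread
        self.seed = seed
        self.weighting = weighting
        self.rtol = rtol
        self.max_nfev = max_nfev
        self.xtol = xtol

    def _residuals(self, logx, traces, init_rates):
        rates = init_rates.replace(
            **{name: 10.0 ** v for name, v in zip(self.free, logx)}
        )
        out = []
        for tr in traces:
            try:
                model = scheme.simulate_trace(
                    rates, tr.conditions, tr.times, rtol=self.rtol, method="auto"
                ).signal
            except (IntegrationError, ValueError):
                # score this parameter vector as very bad but finite
                model = np.full_like(tr.signal, 1e3)
            r = model - tr.signal
            if self.weighting == "sigma" and tr.sigma:
                r = r / tr.sigma
            out.append(r)
        return np.concatenate(out)

    def fit(self, traces: Sequence[KineticTrace], init: RateSet | None = None):
        if len(traces) < 1:
            raise ValueError("need at least one trace")
        unknown = [n for n in self.free if n not in RateSet.__dataclass_fields__]
        if unknown:
            raise ValueError(f"unknown rate names in free list: {unknown}")
        init = init or scheme.SOLUTION_RATES
        x0 = np.array([np.log10(getattr(init, n)) for n in self.free])
        lo, hi = x0 - self.bound_decades, x0 + self.bound_decades

        rng = np.random.default_rng(self.seed)
        best = None
        self.start_points_ = []
        for s in range(max(1, self.n_starts)):
            xs = x0 if s == 0 else np.clip(
                x0 + rng.uniform(-self.start_spread, self.start_spread, x0.size),
                lo, hi,
            )
            self.start_points_.append(xs.copy())
            sol = optimize.least_squares(
                self._residuals, xs, bounds=(lo, hi), method="trf",
                args=(traces, init), xtol=self.xtol, ftol=1e-12, gtol=1e-12,
                max_nfev=self.max_nfev,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        sol = best

        self.rates_ = init.replace(
            **{name: 10.0 ** v for name, v in zip(self.free, sol.x)}
        )
        # covariance in log10 space from the Gauss-Newton approximation
        ndata = sum(len(tr) for tr in traces)
        dof = max(ndata - sol.x.size, 1)
        s2 = 2.0 * sol.cost / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            log_err = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            cov, log_err = None, np.full(sol.x.size, np.nan)
        self.log10_stderr_ = dict(zip(self.free, log_err))

        params = init.as_dict()
        params.update({n: 10.0 ** v for n, v in zip(self.free, sol.x)})
        stderr = {n: np.nan for n in params}
        for n, le, v in zip(self.free, log_err, sol.x):
            # relative error ~ ln(10) * sigma_log10; report absolute
            stderr[n] = np.log(10.0) * le * 10.0 ** v

        per_trace = {}
        resid = self._residuals(sol.x, traces, init)
        i = 0
        for k, tr in enumerate(traces):
            r = resid[i:i + len(tr)]
            per_trace[f"trace{k}"] = float(np.sum(r**2))
            i += len(tr)
        self.per_trace_chisqr_ = per_trace
        self.result_ = FitResult(
            params=params, stderr=stderr, chisqr=float(2.0 * sol.cost),
            ndata=ndata, nvarys=sol.x.size, success=bool(sol.success),
            message=str(sol.message), residual_norms=per_trace, covar=cov,
        )
        return self


def global_fit(
    traces: Sequence[KineticTrace],
    init: RateSet | None = None,
    free: Sequence[str] = ("kin_r", "kin_t", "kg_r", "kg_t", "k3", "km3", "kout"),
    **kwargs,
) -> GlobalSchemeFit:
    """Functional wrapper over :class:`GlobalSchemeFit`."""
    return GlobalSchemeFit(free=free, **kwargs).fit(traces, init=init)
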