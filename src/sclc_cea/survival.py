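"""Parametric survival fitting for right-censored pseudo-IPD.

Five candidate families are fitted by maximum likelihood — exponential,
Weibull, logistic, log-logistic and log-normal — and compared by AIC/BIC.
The Weibull uses the rate parameterisation ``S(t) = exp(-lambda * t**gamma)``
(lambda > 0, gamma > 0); helpers convert to and from the conventional scale
``sigma = lambda**(-1/gamma)``.  The "logistic" family is a plain
location-scale logistic on time, which leaks probability mass to t < 0; its
survival values are naturally inside (0, 1) and are reported as-is.

The censored log-likelihood is ``sum_events log f(t) + sum_censored log S(t)``.
Optimisation runs on unconstrained log-transformed parameters with a small
multi-start from moment-based initial values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SurvivalFit",
    "FitConvergenceError",
    "MedianUndefinedError",
    "fit_distribution",
    "select_model",
    "criterion_table",
    "survival_at",
    "median_survival",
    "weibull_rate_to_scale",
    "weibull_scale_to_rate",
]

FAMILIES = ("exponential", "weibull", "logistic", "log-logistic", "log-normal")

_GRAD_TOL = 1e-8


class FitConvergenceError(RuntimeError):
    """Raised when no optimiser start reaches the convergence tolerance."""


class MedianUndefinedError(ValueError):
    """Raised when S(t) never falls below 0.5 on the searched range."""


def weibull_rate_to_scale(lambda_: float, gamma: float) -> tuple[float, float]:
    """(lambda, gamma) rate form -> (scale sigma, shape gamma)."""
    return lambda_ ** (-1.0 / gamma), gamma


def weibull_scale_to_rate(sigma: float, gamma: float) -> tuple[float, float]:
    """(scale sigma, shape gamma) -> (lambda, gamma) rate form."""
    return sigma ** (-gamma), gamma


@dataclass
class SurvivalFit:
    """A fitted parametric survival family with information criteria.

    ``params`` is family-specific:

    * exponential: ``rate``
    * weibull: ``rate`` (lambda), ``shape`` (gamma)
    * logistic: ``loc``, ``scale``
    * log-logistic: ``scale`` (alpha), ``shape`` (beta)
    * log-normal: ``mu``, ``sigma`` (log-time moments)
    """

    family: str
    params: dict[str, float]
    loglik: float
    n: int
    n_events: int
    converged: bool = True
    grad_norm: float = 0.0
    endpoint: str | None = None
    arm: str | None = None

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2.0 * self.loglik

    def survival(self, t) -> np.ndarray | float:
        return survival_at(self, t)

    def median(self) -> float:
        return median_survival(self)

    def summary(self) -> str:
        lines = [
            f"{self.family} survival fit (n={self.n}, events={self.n_events})",
            "  " + ", ".join(f"{k}={v:.6g}" for k, v in self.params.items()),
            f"  loglik={self.loglik:.4f}  AIC={self.aic:.4f}  BIC={self.bic:.4f}"
            f"  converged={self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalFit":
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            loglik=float(d["loglik"]),
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            converged=bool(d.get("converged", True)),
        )


# ---------------------------------------------------------------------------
# family-specific log-density / log-survival on the natural parameter scale
# ---------------------------------------------------------------------------

def _logpdf_logsf(family: str, t: np.ndarray, p: np.ndarray):
    if family == "exponential":
        (rate,) = p
        return np.log(rate) - rate * t, -rate * t
    if family == "weibull":
        lam, gam = p
        logt = np.log(np.maximum(t, 1e-300))
        logsf = -lam * np.power(t, gam)
        logpdf = np.log(lam) + np.log(gam) + (gam - 1.0) * logt + logsf
        return logpdf, logsf
    if family == "logistic":
        loc, scale = p
        z = (t - loc) / scale
        logpdf = -z - 2.0 * np.logaddexp(0.0, -z) - np.log(scale)
        logsf = -np.logaddexp(0.0, z)
        return logpdf, logsf
    if family == "log-logistic":
        alpha, beta = p
        logt = np.log(np.maximum(t, 1e-300))
        z = beta * (logt - np.log(alpha))
        logsf = -np.logaddexp(0.0, z)
        logpdf = np.log(beta) + (beta - 1.0) * (logt - np.log(alpha)) - np.log(alpha) + 2.0 * logsf
        return logpdf, logsf
    if family == "log-normal":
        mu, sigma = p
        logt = np.log(np.maximum(t, 1e-300))
        z = (logt - mu) / sigma
        logpdf = stats.norm.logpdf(z) - np.log(sigma) - logt
        logsf = stats.norm.logsf(z)
        return logpdf, logsf
    raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")


# transforms between the optimiser's unconstrained vector and natural params
def _to_natural(family: str, x: np.ndarray) -> np.ndarray:
    if family == "logistic":
        return np.array([x[0], math.exp(x[1])])
    return np.exp(x)


def _to_unconstrained(family: str, p: np.ndarray) -> np.ndarray:
    if family == "logistic":
        return np.array([p[0], math.log(p[1])])
    return np.log(p)


def _neg_loglik(family: str, x: np.ndarray, t_ev, t_cs) -> float:
    p = _to_natural(family, x)
    if not np.all(np.isfinite(p)):
        return 1e12
    lp_ev, _ = _logpdf_logsf(family, t_ev, p)
    _, ls_cs = _logpdf_logsf(family, t_cs, p)
    val = lp_ev.sum() + ls_cs.sum()
    if not np.isfinite(val):
        return 1e12
    return -float(val)


def _initial_starts(family: str, t: np.ndarray, events: np.ndarray) -> list[np.ndarray]:
    t_ev = t[events == 1]
    d = max(len(t_ev), 1)
    rate0 = d / max(t.sum(), 1e-12)
    m = float(np.median(t_ev)) if len(t_ev) else float(np.median(t))
    m = max(m, 1e-6)
    if family == "exponential":
        return [np.array([rate0])]
    if family == "weibull":
        return [
            np.array([math.log(2.0) / m**g, g]) for g in (1.0, 0.7, 1.5)
        ]
    if family == "logistic":
        loc0 = float(np.mean(t))
        s0 = max(float(np.std(t)) * math.sqrt(3.0) / math.pi, 1e-3)
        return [np.array([loc0, s0 * f]) for f in (1.0, 0.5, 2.0)]
    logt = np.log(np.maximum(t_ev if len(t_ev) else t, 1e-6))
    mu0 = float(np.mean(logt))
    s0 = max(float(np.std(logt)), 1e-3)
    if family == "log-logistic":
        beta0 = math.pi / (s0 * math.sqrt(3.0))
        return [np.array([math.exp(mu0), beta0 * f]) for f in (1.0, 0.5, 2.0)]
    if family == "log-normal":
        return [np.array([math.exp(mu0), s0 * f]) for f in (1.0, 0.5, 2.0)]
    raise ValueError(f"unknown family {family!r}")


_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("rate", "shape"),
    "logistic": ("loc", "scale"),
    "log-logistic": ("scale", "shape"),
    "log-normal": ("mu", "sigma"),
}


def fit_distribution(ipd: pd.DataFrame, family: str, *, endpoint: str | None = None,
                     arm: str | None = None) -> SurvivalFit:
    """Maximum-likelihood fit of one family to right-censored records.

    Parameters
    ----------
    ipd : DataFrame with columns ``time_months`` and ``event`` (1 event,
        0 censored).  Other columns are ignored, so arm/endpoint subsets
        should be selected by the caller.
    family : one of :data:`FAMILIES`.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")
    t = np.asarray(ipd["time_months"], dtype=float)
    events = np.asarray(ipd["event"], dtype=int)
    if len(t) == 0:
        raise ValueError("empty IPD")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("all records censored; parametric fit is not identified")

    t = np.maximum(t, 1e-9)  # zero times break log-time families
    t_ev = t[events == 1]
    t_cs = t[events == 0]

    if family == "exponential":  # closed form: rate = events / total time
        rate = n_events / t.sum()
        ll = -_neg_loglik(family, np.log([rate]), t_ev, t_cs)
        return SurvivalFit(family, {"rate": rate}, ll, len(t), n_events,
                           converged=True, grad_norm=0.0, endpoint=endpoint, arm=arm)

    best = None
    for p0 in _initial_starts(family, t, events):
        x0 = _to_unconstrained(family, p0)
        res = optimize.minimize(
            lambda x: _neg_loglik(family, x, t_ev, t_cs),
            x0,
            method="L-BFGS-B",
            options={"gtol": _GRAD_TOL, "ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    grad = float(np.max(np.abs(best.jac))) if best.jac is not None else math.inf
    converged = bool(best.success) or grad < 1e-4 * (1.0 + abs(best.fun))
    if not converged:
        raise FitConvergenceError(
            f"{family} fit did not converge (final |grad| = {grad:.3e})"
        )
    p = _to_natural(family, best.x)
    params = dict(zip(_PARAM_NAMES[family], map(float, p)))
    return SurvivalFit(family, params, -float(best.fun), len(t), n_events,
                       converged=converged, grad_norm=grad, endpoint=endpoint, arm=arm)


def fit_all(ipd: pd.DataFrame, **kw) -> list[SurvivalFit]:
    """Fit every family in :data:`FAMILIES` to the same records."""
    return [fit_distribution(ipd, fam, **kw) for fam in FAMILIES]


def criterion_table(fits: list[SurvivalFit]) -> pd.DataFrame:
    """AIC/BIC comparison table across candidate fits."""
    return pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def select_model(fits: list[SurvivalFit]) -> SurvivalFit:
    """Pick the minimum-AIC fit; ties resolved by BIC, then family order."""
    if not fits:
        raise ValueError("no candidate fits")
    ns = {(f.n, f.n_events) for f in fits}
    if len(ns) > 1:
        raise ValueError(f"candidate fits cover different data: n/(events) = {sorted(ns)}")

    def key(f: SurvivalFit):
        order = FAMILIES.index(f.family) if f.family in FAMILIES else len(FAMILIES)
        return (round(f.aic, 9), round(f.bic, 9), order)

    return min(fits, key=key)


def survival_at(fit: SurvivalFit, t) -> np.ndarray | float:
    """S(t) for a fitted family; values clamped into [0, 1]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_at requires t >= 0")
    p = np.array([fit.params[k] for k in _PARAM_NAMES[fit.family]])
    _, logsf = _logpdf_logsf(fit.family, np.maximum(t_arr, 0.0), p)
    s = np.exp(logsf)
    if fit.family != "logistic":
        # nonnegative-support families: S(0) = 1 exactly
        s = np.where(t_arr == 0.0, 1.0, s)
    s = np.clip(s, 0.0, 1.0)
    return float(s) if np.isscalar(t) or t_arr.ndim == 0 else s


def _median_bisect(fit: SurvivalFit) -> float:
    hi = 1.0
    while survival_at(fit, hi) > 0.5:
        hi *= 2.0
        if hi > 1e9:
            raise MedianUndefinedError(
                f"{fit.family} fit never reaches S(t) = 0.5 on (0, 1e9] months"
            )
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if survival_at(fit, mid) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def median_survival(fit: SurvivalFit) -> float:
    """Time m with S(m) = 0.5 (closed form where available, else bisection)."""
    if fit.family == "weibull":
        lam, gam = fit.params["rate"], fit.params["shape"]
        return (math.log(2.0) / lam) ** (1.0 / gam)
    if fit.family == "exponential":
        return math.log(2.0) / fit.params["rate"]
    return _median_bisect(fit)
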