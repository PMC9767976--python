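"""Parametric survival curves, censored maximum likelihood and pseudo-IPD reconstruction.

Six candidate families are supported (exponential, Weibull, Gompertz, lognormal,
log-logistic, generalized gamma), all on a time axis measured in months.  The
lognormal and log-logistic families use the log-location-scale parameterization
(location mu = log median, scale sigma); the generalized gamma uses the
(mu, sigma, Q) form that contains the lognormal as the Q -> 0 limit.

Fitted models are ranked by AIC/BIC, and published Kaplan-Meier curves (digitized
to (time, survival) coordinates, optionally with a numbers-at-risk table) can be
converted back to pseudo individual-patient data so the same likelihood machinery
applies to them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "PseudoIPD",
    "ModelFit",
    "DigitizedCurve",
    "survival_prob",
    "log_likelihood",
    "fit_mle",
    "select_best",
    "reconstruct_ipd",
]

#: canonical family order, also used as the final tie-break in model selection
FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic", "gengamma")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gengamma": 3,
}

# below this |Q| the generalized gamma is evaluated as its lognormal limit
_GG_LOGNORMAL_EPS = 1e-6
#: bound on the generalized-gamma shape Q to avoid numerical overflow
GG_Q_BOUND = 5.0


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival distribution S(t) with t in months.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    location:
        Family-dependent first parameter: rate ``lambda`` (exponential), shape
        ``a`` (Weibull, Gompertz), or log-time location ``mu`` (lognormal,
        log-logistic, generalized gamma).
    scale:
        Family-dependent positive second parameter: scale ``b`` in months
        (Weibull), rate ``b`` (Gompertz), or log-time scale ``sigma``
        (lognormal, log-logistic, generalized gamma).  Unused for the
        exponential family.
    extra:
        Shape ``Q`` of the generalized gamma; ``None`` otherwise.
    """

    family: str
    location: float
    scale: float = 1.0
    extra: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not np.isfinite(self.location):
            raise ValueError("location must be finite")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scale must be a positive finite number")
        if self.family == "exponential" and self.location <= 0:
            raise ValueError("exponential rate must be positive")
        if self.family == "weibull" and self.location <= 0:
            raise ValueError("Weibull shape must be positive")
        if self.family == "gengamma":
            if self.extra is None or not np.isfinite(self.extra):
                raise ValueError("generalized gamma requires the extra shape Q")
            if abs(self.extra) > GG_Q_BOUND:
                raise ValueError(f"generalized-gamma Q must lie in [-{GG_Q_BOUND}, {GG_Q_BOUND}]")

    # -- frozen scipy distribution where one exists ---------------------------
    def _frozen(self):
        f = self.family
        if f == "exponential":
            return stats.expon(scale=1.0 / self.location)
        if f == "weibull":
            return stats.weibull_min(self.location, scale=self.scale)
        if f == "lognormal":
            return stats.lognorm(self.scale, scale=np.exp(self.location))
        if f == "loglogistic":
            return stats.fisk(1.0 / self.scale, scale=np.exp(self.location))
        if f == "gengamma" and abs(self.extra) < _GG_LOGNORMAL_EPS:
            return stats.lognorm(self.scale, scale=np.exp(self.location))
        return None  # gompertz and generalized gamma handled explicitly

    def _gg_w(self, t: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return (np.log(t) - self.location) / self.scale

    def logsf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        if self.family == "gompertz":
            a, b = self.location, self.scale
            if abs(a) < 1e-12:
                return -b * t
            with np.errstate(over="ignore"):
                return -(b / a) * np.expm1(a * t)
        frozen = self._frozen()
        if frozen is not None:
            with np.errstate(divide="ignore"):
                out = frozen.logsf(t)
            return np.where(t == 0.0, 0.0, out)
        # generalized gamma in the (mu, sigma, Q) form, via the regularized
        # incomplete gamma of u = Q^-2 exp(Q w), w = (ln t - mu) / sigma
        q = self.extra
        gam = q ** -2.0
        with np.errstate(over="ignore"):
            u = gam * np.exp(q * self._gg_w(t))
        surv = special.gammaincc(gam, u) if q > 0 else special.gammainc(gam, u)
        with np.errstate(divide="ignore"):
            out = np.log(surv)
        return np.where(t == 0.0, 0.0, out)

    def logpdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        if self.family == "gompertz":
            a, b = self.location, self.scale
            return np.log(b) + a * t + self.logsf(t)
        frozen = self._frozen()
        if frozen is not None:
            with np.errstate(divide="ignore"):
                return frozen.logpdf(t)
        q, sigma = self.extra, self.scale
        gam = q ** -2.0
        w = self._gg_w(t)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            return (np.log(abs(q)) + gam * np.log(gam) - special.gammaln(gam)
                    - np.log(sigma) - np.log(t) + gam * (q * w - np.exp(q * w)))

    def survival(self, t) -> np.ndarray:
        return np.exp(self.logsf(t))

    def density(self, t) -> np.ndarray:
        return np.exp(self.logpdf(t))

    def hazard(self, t) -> np.ndarray:
        return np.exp(self.logpdf(t) - self.logsf(t))

    def quantile_surv(self, p: float) -> float:
        """Time t at which S(t) = p (p in (0, 1))."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")
        if self.family == "gompertz":
            a, b = self.location, self.scale
            if abs(a) < 1e-12:
                return -np.log(p) / b
            arg = 1.0 - (a / b) * np.log(p)
            if arg <= 0:  # defective tail (a < 0): plateau above p
                return np.inf
            return np.log(arg) / a
        frozen = self._frozen()
        if frozen is not None:
            return float(frozen.isf(p))
        q, mu, sigma = self.extra, self.location, self.scale
        gam = q ** -2.0
        u = special.gammainccinv(gam, p) if q > 0 else special.gammaincinv(gam, p)
        return float(np.exp(mu + sigma * np.log(u / gam) / q))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw event times by inverse-CDF sampling (reproducible via rng)."""
        u = rng.uniform(size=n)
        frozen = self._frozen()
        if frozen is not None:
            return frozen.isf(u)
        return np.array([self.quantile_surv(ui) for ui in u])


def survival_prob(model: ParametricSurvival, t) -> np.ndarray | float:
    """S(t) for a valid model; S(0) = 1 by construction."""
    out = model.survival(t)
    return float(out) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class PseudoIPD:
    """Event-and-censoring times (months) with parallel event indicators."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be parallel 1-d arrays")
        if t.size == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


def log_likelihood(model: ParametricSurvival, data: PseudoIPD) -> float:
    """Right-censored log likelihood: sum of log f over events, log S over censored."""
    ev = data.events.astype(bool)
    terms = np.empty(data.n)
    terms[ev] = model.logpdf(data.times[ev])
    terms[~ev] = model.logsf(data.times[~ev])
    ll = float(np.sum(terms))
    if not np.isfinite(ll):
        warnings.warn("log-likelihood is -inf: a density or survival term underflowed to 0")
        return -np.inf
    return ll


@dataclass(frozen=True)
class ModelFit:
    """A fitted family with its information criteria."""

    model: ParametricSurvival
    loglik: float
    n_params: int
    n_obs: int
    converged: bool = True
    message: str = ""
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "aic", 2.0 * self.n_params - 2.0 * self.loglik)
        object.__setattr__(self, "bic", self.n_params * np.log(self.n_obs) - 2.0 * self.loglik)


class FitError(RuntimeError):
    """MLE non-convergence; carries the last iterate for diagnosis."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def _pack(family: str, theta: np.ndarray) -> ParametricSurvival:
    if family == "exponential":
        return ParametricSurvival(family, float(np.exp(theta[0])))
    if family in ("weibull",):
        return ParametricSurvival(family, float(np.exp(theta[0])), float(np.exp(theta[1])))
    if family == "gompertz":
        return ParametricSurvival(family, float(theta[0]), float(np.exp(theta[1])))
    if family in ("lognormal", "loglogistic"):
        return ParametricSurvival(family, float(theta[0]), float(np.exp(theta[1])))
    q = float(np.clip(theta[2], -GG_Q_BOUND, GG_Q_BOUND))
    return ParametricSurvival(family, float(theta[0]), float(np.exp(theta[1])), q)


def _starts(family: str, data: PseudoIPD, rng: np.random.Generator) -> list[np.ndarray]:
    """Method-of-moments style start plus jittered restarts (fixed rng)."""
    t = np.clip(data.times, 1e-8, None)
    logt = np.log(t)
    mu0 = float(np.mean(logt))
    sd0 = float(np.std(logt)) or 0.5
    rate0 = max(data.n_events / max(np.sum(data.times), 1e-8), 1e-8)
    base = {
        "exponential": [np.log(rate0)],
        "weibull": [np.log(max(1.2825 / sd0, 1e-3)), mu0 + 0.5772 * sd0],
        "gompertz": [0.05, np.log(rate0)],
        "lognormal": [mu0, np.log(sd0)],
        "loglogistic": [mu0, np.log(sd0 * 0.5513)],  # sigma = sd * sqrt(3)/pi
        "gengamma": [mu0, np.log(sd0), 0.5],
    }[family]
    theta0 = np.asarray(base, dtype=float)
    starts = [theta0]
    for _ in range(4):
        starts.append(theta0 + rng.normal(scale=0.3, size=theta0.size))
    return starts


def fit_mle(
    family: str,
    data: PseudoIPD,
    init: np.ndarray | None = None,
    seed: int = 20210921,
) -> ModelFit:
    """Censored maximum-likelihood fit of one family.

    Multi-start quasi-Newton optimization on log-transformed positive
    parameters; the exponential rate has the closed form events / time-at-risk.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if data.n_events == 0:
        raise ValueError("all observations are censored: the likelihood has no maximum")
    if data.n < 10:
        warnings.warn(f"only {data.n} observations; fit may be unstable")

    if family == "exponential":
        lam = data.n_events / float(np.sum(data.times))
        model = ParametricSurvival("exponential", lam)
        return ModelFit(model, log_likelihood(model, data), 1, data.n)

    def negll(theta: np.ndarray) -> float:
        try:
            m = _pack(family, theta)
        except ValueError:
            return np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll = log_likelihood(m, data)
        return np.inf if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = [np.asarray(init, dtype=float)] if init is not None else _starts(family, data, rng)
    best = None
    for theta0 in starts:
        res = optimize.minimize(negll, theta0, method="L-BFGS-B")
        if not res.success or not np.isfinite(res.fun):
            res_nm = optimize.minimize(negll, theta0, method="Nelder-Mead",
                                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
            if np.isfinite(res_nm.fun) and (not np.isfinite(res.fun) or res_nm.fun < res.fun):
                res = res_nm
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"{family} fit did not converge",
                       last_iterate=None if best is None else best.x)
    model = _pack(family, best.x)
    return ModelFit(model, -float(best.fun), _N_PARAMS[family], data.n,
                    converged=bool(best.success), message=str(best.message))


def select_best(fits: list[ModelFit], criterion: str = "aic") -> ModelFit:
    """Pick the fit with the smallest information criterion.

    ``criterion``: ``"aic"``, ``"bic"`` or ``"both"`` (sum of the two).  Ties
    are broken by fewer parameters, then by the canonical family order.
    """
    if criterion not in ("aic", "bic", "both"):
        raise ValueError("criterion must be 'aic', 'bic' or 'both'")
    if not fits:
        raise ValueError("no fits to select from")
    if len(fits) == 1:
        warnings.warn("only one candidate fit; returning it unranked")
        return fits[0]
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits were computed on datasets of differing size")

    def key(f: ModelFit):
        val = {"aic": f.aic, "bic": f.bic, "both": f.aic + f.bic}[criterion]
        return (val, f.n_params, FAMILIES.index(f.model.family))

    return min(fits, key=key)


def fit_all(data: PseudoIPD, families=FAMILIES, seed: int = 20210921) -> list[ModelFit]:
    """Fit every candidate family to the same data."""
    return [fit_mle(f, data, seed=seed) for f in families]


def fit_report(fits: list[ModelFit]) -> pd.DataFrame:
    """Tabulate fits as family x {loglik, aic, bic, parameters}."""
    rows = []
    for f in fits:
        rows.append({
            "family": f.model.family,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "aic": f.aic,
            "bic": f.bic,
            "location": f.model.location,
            "scale": f.model.scale,
            "extra": f.model.extra,
            "converged": f.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Digitized curves and pseudo-IPD reconstruction
# ---------------------------------------------------------------------------

@dataclass
class DigitizedCurve:
    """(time, survival) coordinates read off a published Kaplan-Meier plot."""

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and survival must be parallel non-empty 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        self.times = t
        self.survival = s
        if self.n_risk is not None:
            r = np.asarray(self.n_risk, dtype=float)
            if r.shape != t.shape:
                raise ValueError("n_risk must parallel times")
            self.n_risk = r

    def repaired(self, tolerance: float = 0.02) -> "DigitizedCurve":
        """Project survival onto a non-increasing sequence (pool adjacent violators).

        Raises if any digitization artifact increases survival by more than
        ``tolerance`` (such curves are treated as corrupt rather than noisy).
        """
        s = self.survival
        rises = np.diff(s)
        if rises.size and rises.max() > tolerance:
            raise ValueError(
                f"survival increases by {rises.max():.3f} > {tolerance}; curve beyond repair")
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
        fixed = iso.fit_transform(self.times, s)
        return DigitizedCurve(self.times, fixed, self.n_risk)

    @classmethod
    def from_csv(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        required = {"time_months", "survival"}
        if not required.issubset(df.columns):
            raise ValueError(f"digitized-curve CSV must have columns {sorted(required)}")
        n_risk = df["n_risk"].to_numpy() if "n_risk" in df.columns else None
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy(), n_risk)

    def to_csv(self, path) -> None:
        d = {"time_months": self.times, "survival": self.survival}
        if self.n_risk is not None:
            d["n_risk"] = self.n_risk
        pd.DataFrame(d).to_csv(path, index=False)


def reconstruct_ipd(curve: DigitizedCurve, n_start: int) -> PseudoIPD:
    """Rebuild pseudo individual-patient data from a digitized survival curve.

    A step-allocation scheme: walking through the digitized coordinates, each
    drop in survival is converted into the integer number of deaths that best
    reproduces the Kaplan-Meier step given the current at-risk count.  With a
    numbers-at-risk table, the surplus between at-risk counts and deaths is
    allocated to interval censoring (spread uniformly across the interval);
    without one, no censoring is assumed before the last follow-up time and
    survivors are censored there.
    """
    if n_start < 1:
        raise ValueError("n_start must be at least 1")
    curve = curve.repaired()
    times, surv = curve.times, curve.survival
    if times[0] > 0 or surv[0] < 1.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
        risk = None if curve.n_risk is None else np.concatenate([[n_start], curve.n_risk])
    else:
        risk = curve.n_risk

    out_t: list[float] = []
    out_e: list[int] = []
    n_at_risk = n_start
    s_km = 1.0
    for j in range(1, len(times)):
        if n_at_risk <= 0 or s_km <= 0:
            break
        target = surv[j]
        d = int(round(n_at_risk * (1.0 - target / s_km)))
        d = int(np.clip(d, 0, n_at_risk))
        if d > 0:
            out_t.extend([times[j]] * d)
            out_e.extend([1] * d)
            s_km *= (n_at_risk - d) / n_at_risk
            n_at_risk -= d
        if risk is not None and j < len(times) - 1:
            c = int(round(n_at_risk - risk[j + 1]))
            c = int(np.clip(c, 0, n_at_risk))
            if c > 0:
                # censor uniformly inside (t_j, t_{j+1})
                cens = times[j] + (np.arange(1, c + 1) / (c + 1)) * (times[j + 1] - times[j])
                out_t.extend(cens.tolist())
                out_e.extend([0] * c)
                n_at_risk -= c
    if n_at_risk > 0:
        out_t.extend([float(times[-1])] * n_at_risk)
        out_e.extend([0] * n_at_risk)
    order = np.argsort(out_t, kind="stable")
    return PseudoIPD(np.asarray(out_t)[order], np.asarray(out_e)[order])


def fit_curve_coordinates(family: str, curve: DigitizedCurve) -> ParametricSurvival:
    """Least-squares fit of S(t) directly to digitized coordinates.

    Secondary fitting path for when pseudo-IPD reconstruction is not wanted;
    minimizes the sum of squared survival residuals.
    """
    curve = curve.repaired()

    def sse(theta):
        try:
            m = _pack(family, theta)
        except ValueError:
            return np.inf
        with np.errstate(all="ignore"):
            r = m.survival(curve.times) - curve.survival
        return float(np.sum(r * r))

    rng = np.random.default_rng(0)
    # seed the search from a crude pseudo-IPD fit
    ipd = reconstruct_ipd(curve, n_start=max(100, 10 * curve.times.size))
    start_model = fit_mle(family, ipd).model
    if family == "exponential":
        theta0 = np.array([np.log(start_model.location)])
    elif family == "gompertz":
        theta0 = np.array([start_model.location, np.log(start_model.scale)])
    elif family == "weibull":
        theta0 = np.array([np.log(start_model.location), np.log(start_model.scale)])
    elif family in ("lognormal", "loglogistic"):
        theta0 = np.array([start_model.location, np.log(start_model.scale)])
    else:
        theta0 = np.array([start_model.location, np.log(start_model.scale), start_model.extra])
    best = None
    for t0 in [theta0] + [theta0 + rng.normal(scale=0.2, size=theta0.size) for _ in range(3)]:
        res = optimize.minimize(sse, t0, method="Nelder-Mead", options={"maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return _pack(family, best.x)
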