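"""Benchmark concentration (BMC) modeling for continuous endpoints.

Fits a suite of continuous dose-response models — exponential (forms
2-5), Hill, linear, polynomial (degree <= 3) and power — by maximum
likelihood under a normal or log-normal error distribution with constant
or non-constant (power-of-mean, sigma^2 = alpha * mu^rho) variance. The
BMC is the smallest positive concentration at which the fitted mean
departs from the control mean by one control standard deviation (the
benchmark response), found by root solving; its 95% confidence interval
comes from the profile likelihood, with a parametric bootstrap fallback.
Models are screened by documented recommendation rules (convergence,
goodness-of-fit p-value, scaled residuals, BMC/BMCL ratio) and the BMCs
of all recommended models are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "BMCModelSpec",
    "BMCFit",
    "BMCResult",
    "DEFAULT_MODEL_SPECS",
    "fit_bmc_model",
    "compute_bmc",
    "bmc_confidence_interval",
    "recommend_and_average",
    "fit_bmc_suite",
]


# ---------------------------------------------------------------------------
# mean functions

def _mean_linear(x, p):
    return p[0] + p[1] * x


def _mean_poly2(x, p):
    return p[0] + p[1] * x + p[2] * x ** 2


def _mean_poly3(x, p):
    return p[0] + p[1] * x + p[2] * x ** 2 + p[3] * x ** 3


def _mean_power(x, p):
    # gamma + beta * x^delta, delta >= 1 so the mean is defined at 0
    return p[0] + p[1] * np.power(np.maximum(x, 0.0), p[2])


def _mean_hill(x, p):
    # gamma + v x^n / (k^n + x^n)
    g, v, k, n = p
    xn = np.power(np.maximum(x, 0.0), n)
    return g + v * xn / (k ** n + xn)


def _mean_exp2(x, p):
    # a * exp(s b x); the sign s is folded into b (b free)
    return p[0] * np.exp(p[1] * x)


def _mean_exp3(x, p):
    # a * exp(s (b x)^d); sign carried by p[1]'s sign
    a, b, d = p
    return a * np.exp(np.sign(b) * np.power(np.abs(b) * x, d))


def _mean_exp4(x, p):
    # a * (c - (c - 1) exp(-b x))
    a, b, c = p
    return a * (c - (c - 1.0) * np.exp(-np.abs(b) * x))


def _mean_exp5(x, p):
    a, b, c, d = p
    return a * (c - (c - 1.0) * np.exp(-np.power(np.abs(b) * x, d)))


_FAMILIES = {
    "linear": (_mean_linear, 2),
    "polynomial2": (_mean_poly2, 3),
    "polynomial3": (_mean_poly3, 4),
    "power": (_mean_power, 3),
    "hill": (_mean_hill, 4),
    "exponential2": (_mean_exp2, 2),
    "exponential3": (_mean_exp3, 3),
    "exponential4": (_mean_exp4, 3),
    "exponential5": (_mean_exp5, 4),
}


@dataclass(frozen=True)
class BMCModelSpec:
    """One member of the continuous model suite.

    family
        'exponential2'..'exponential5', 'hill', 'linear', 'polynomial2',
        'polynomial3', or 'power'.
    distribution
        'normal' or 'lognormal' (log-normal models the response median).
    variance
        'constant' (sigma^2 = alpha) or 'nonconstant'
        (sigma^2 = alpha * mu^rho).
    """

    family: str
    distribution: str = "normal"
    variance: str = "constant"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be normal|lognormal")
        if self.variance not in ("constant", "nonconstant"):
            raise ValueError("variance must be constant|nonconstant")

    @property
    def n_mean_params(self) -> int:
        return _FAMILIES[self.family][1]

    @property
    def n_params(self) -> int:
        return self.n_mean_params + (1 if self.variance == "constant" else 2)


#: the default suite fitted by :func:`fit_bmc_suite`
DEFAULT_MODEL_SPECS = tuple(
    BMCModelSpec(fam, dist, var)
    for fam in ("exponential2", "exponential3", "exponential4",
                "exponential5", "hill", "linear", "polynomial2",
                "polynomial3", "power")
    for dist in ("normal", "lognormal")
    for var in ("constant", "nonconstant")
)


@dataclass
class BMCFit:
    """A fitted suite member with its diagnostics."""

    spec: BMCModelSpec
    theta: np.ndarray            # mean-function parameters
    var_params: np.ndarray       # [alpha] or [alpha, rho]
    nll: float
    aic: float
    converged: bool
    gof_pvalue: float
    scaled_residuals: pd.DataFrame  # per dose group
    x: np.ndarray
    y: np.ndarray
    usable: bool = True
    message: str = ""

    def mean(self, x):
        f = _FAMILIES[self.spec.family][0]
        return f(np.asarray(x, dtype=float), self.theta)

    def modeled_control_sd(self) -> float:
        """Model-estimated response SD at the control (the default BMR unit).

        For non-constant variance this is sqrt(alpha * mu(0)^rho); for a
        log-normal fit it is the SD on the log-response scale, matching
        the scale on which the benchmark response is then defined.
        """
        alpha = float(self.var_params[0])
        if self.spec.variance == "nonconstant":
            mu0 = float(self.mean(0.0))
            return float(np.sqrt(alpha * max(mu0, 1e-12) ** self.var_params[1]))
        return float(np.sqrt(alpha))

    def _bmr_mean(self, x):
        """Mean on the scale the BMR is defined on (log for lognormal)."""
        m = self.mean(x)
        if self.spec.distribution == "lognormal":
            return np.log(np.maximum(m, 1e-300))
        return m


@dataclass
class BMCResult:
    """Recommended/averaged benchmark concentration for one series."""

    bmc: float | None
    bmcl: float | None
    bmcu: float | None
    bmr_definition: str
    contributing: list
    recommended: bool
    extrapolated: bool = False
    advisory: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# likelihood machinery


def _nll(spec: BMCModelSpec, theta, var_params, x, y) -> float:
    f = _FAMILIES[spec.family][0]
    mu = f(x, theta)
    if np.any(~np.isfinite(mu)):
        return np.inf
    if spec.distribution == "lognormal":
        if np.any(mu <= 0) or np.any(y <= 0):
            return np.inf
        resp = np.log(y)
        center = np.log(mu)
    else:
        resp = y
        center = mu
    alpha = var_params[0]
    if alpha <= 0:
        return np.inf
    if spec.variance == "nonconstant":
        rho = var_params[1]
        if np.any(mu <= 0):
            return np.inf
        var = alpha * np.power(mu, rho)
    else:
        var = np.full_like(resp, alpha)
    if np.any(var <= 0) or np.any(~np.isfinite(var)):
        return np.inf
    ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (resp - center) ** 2 / var)
    if spec.distribution == "lognormal":
        ll -= np.sum(np.log(y))  # Jacobian of the log transform
    return float(-ll)


def _initial_theta(spec: BMCModelSpec, x, y) -> list[np.ndarray]:
    """Moment-based starting points for the mean parameters."""
    groups = pd.DataFrame({"x": x, "y": y}).groupby("x")["y"].mean()
    x0 = groups.index.to_numpy()
    m = groups.to_numpy()
    m0, m1 = m[0], m[-1]
    span = m1 - m0
    xmax = max(x0.max(), 1e-6)
    fam = spec.family
    starts = []
    if fam == "linear":
        slope = span / xmax
        starts = [np.array([m0, slope])]
    elif fam == "polynomial2":
        starts = [np.array([m0, span / xmax, 0.0])]
    elif fam == "polynomial3":
        starts = [np.array([m0, span / xmax, 0.0, 0.0])]
    elif fam == "power":
        starts = [np.array([m0, span / xmax, 1.0]),
                  np.array([m0, span / xmax ** 2, 2.0])]
    elif fam == "hill":
        k = np.median(x0[x0 > 0]) if np.any(x0 > 0) else 1.0
        starts = [np.array([m0, span, k, 1.0]),
                  np.array([m0, span, k, 2.0])]
    elif fam == "exponential2":
        b = np.log(max(m1, 1e-6) / max(m0, 1e-6)) / xmax
        starts = [np.array([max(m0, 1e-6), b])]
    elif fam == "exponential3":
        b = abs(np.log(max(m1, 1e-6) / max(m0, 1e-6))) / xmax
        s = 1.0 if span >= 0 else -1.0
        starts = [np.array([max(m0, 1e-6), s * max(b, 1e-6), 1.0])]
    elif fam == "exponential4":
        c = max(m1, 1e-6) / max(m0, 1e-6)
        starts = [np.array([max(m0, 1e-6), 1.0 / xmax, c])]
    elif fam == "exponential5":
        c = max(m1, 1e-6) / max(m0, 1e-6)
        starts = [np.array([max(m0, 1e-6), 1.0 / xmax, c, 1.0]),
                  np.array([max(m0, 1e-6), 2.0 / xmax, c, 2.0])]
    return starts


def _theta_bounds(spec: BMCModelSpec, x, y):
    """Box bounds keeping mean parameters in sane, identifiable ranges."""
    xmax = max(np.max(x), 1e-6)
    yspan = max(np.max(y) - np.min(y), 1e-6)
    ylo, yhi = np.min(y) - 2 * yspan, np.max(y) + 2 * yspan
    big = 1e6
    fam = spec.family
    if fam == "linear":
        return [(ylo, yhi), (-big, big)]
    if fam == "polynomial2":
        return [(ylo, yhi)] + [(-big, big)] * 2
    if fam == "polynomial3":
        return [(ylo, yhi)] + [(-big, big)] * 3
    if fam == "power":
        return [(ylo, yhi), (-big, big), (1.0, 18.0)]
    if fam == "hill":
        return [(ylo, yhi), (-4 * yspan, 4 * yspan),
                (xmax / 1e4, xmax * 100), (0.5, 18.0)]
    if fam == "exponential2":
        return [(1e-9, yhi), (-100 / xmax, 100 / xmax)]
    if fam == "exponential3":
        return [(1e-9, yhi), (-100 / xmax, 100 / xmax), (1.0, 18.0)]
    if fam == "exponential4":
        return [(1e-9, yhi), (1e-9, 100 / xmax), (1e-6, 100.0)]
    if fam == "exponential5":
        return [(1e-9, yhi), (1e-9, 100 / xmax), (1e-6, 100.0), (1.0, 18.0)]
    raise AssertionError(fam)


def _fit_ml(spec: BMCModelSpec, x, y):
    """Maximize the likelihood over mean + variance parameters."""
    resp = np.log(y) if spec.distribution == "lognormal" else y
    var0 = max(np.var(resp), 1e-8)
    best = None
    bounds = _theta_bounds(spec, x, y)
    nm = spec.n_mean_params
    if spec.variance == "constant":
        vb = [(1e-12, None)]
        v0s = [np.array([var0])]
    else:
        vb = [(1e-12, None), (-10.0, 10.0)]
        v0s = [np.array([var0, 0.0]), np.array([var0, 1.0])]
    for t0 in _initial_theta(spec, x, y):
        for v0 in v0s:
            p0 = np.concatenate([t0, v0])
            p0 = np.clip(p0, [b[0] if b[0] is not None else -np.inf
                              for b in bounds + vb],
                         [b[1] if b[1] is not None else np.inf
                          for b in bounds + vb])

            def obj(p):
                with np.errstate(over="ignore", invalid="ignore",
                                 divide="ignore"):
                    return _nll(spec, p[:nm], p[nm:], x, y)

            try:
                res = optimize.minimize(obj, p0, method="Nelder-Mead",
                                        options={"maxiter": 4000,
                                                 "xatol": 1e-8,
                                                 "fatol": 1e-10})
                res = optimize.minimize(obj, res.x, method="L-BFGS-B",
                                        bounds=bounds + vb)
            except Exception:
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
    return best


def _saturated_nll(spec: BMCModelSpec, x, y) -> tuple[float, int]:
    """NLL of the saturated (per-group means) model with matched variance."""
    df = pd.DataFrame({"x": x, "y": y})
    groups = list(df.groupby("x"))
    resp = np.log(y) if spec.distribution == "lognormal" else y
    if spec.variance == "constant":
        # per-group means, one pooled variance: analytic
        resid2 = 0.0
        for _, g in groups:
            r = np.log(g["y"]) if spec.distribution == "lognormal" else g["y"]
            resid2 += float(np.sum((r - r.mean()) ** 2))
        n = len(y)
        sig2 = max(resid2 / n, 1e-12)
        nll = 0.5 * n * np.log(2 * np.pi * sig2) + 0.5 * n
        if spec.distribution == "lognormal":
            nll += float(np.sum(np.log(y)))
        return float(nll), len(groups) + 1
    # non-constant: per-group means and variances (fully saturated)
    nll = 0.0
    for _, g in groups:
        r = np.log(g["y"].to_numpy()) if spec.distribution == "lognormal" \
            else g["y"].to_numpy()
        s2 = max(float(np.var(r)), 1e-12)
        nll += 0.5 * r.size * np.log(2 * np.pi * s2) + 0.5 * r.size
        if spec.distribution == "lognormal":
            nll += float(np.sum(np.log(g["y"])))
    return float(nll), 2 * len(groups)


def fit_bmc_model(series: pd.DataFrame, spec: BMCModelSpec) -> BMCFit:
    """Fit one suite member to individual-level concentration-response data.

    ``series`` needs columns ``concentration`` and ``response`` with at
    least 4 dose groups including control. Returns a :class:`BMCFit`
    whose diagnostics include AIC, a likelihood-ratio goodness-of-fit
    p-value against the saturated per-group-means model, and scaled
    residuals (group mean deviation / SE) per dose group. Non-convergence
    or degenerate data mark the fit unusable rather than raising.
    """
    x = series["concentration"].to_numpy(dtype=float)
    y = series["response"].to_numpy(dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 dose groups including control")
    empty = pd.DataFrame(columns=["concentration", "scaled_residual"])
    if np.allclose(np.var(y), 0):
        return BMCFit(spec, np.array([]), np.array([]), np.inf, np.inf,
                      False, np.nan, empty, x, y, usable=False,
                      message="zero-variance data")
    if spec.distribution == "lognormal" and np.any(y <= 0):
        return BMCFit(spec, np.array([]), np.array([]), np.inf, np.inf,
                      False, np.nan, empty, x, y, usable=False,
                      message="nonpositive responses under lognormal")
    res = _fit_ml(spec, x, y)
    if res is None or not np.isfinite(res.fun):
        return BMCFit(spec, np.array([]), np.array([]), np.inf, np.inf,
                      False, np.nan, empty, x, y, usable=False,
                      message="optimizer failed")
    nm = spec.n_mean_params
    theta, var_params = res.x[:nm], res.x[nm:]
    nll = float(res.fun)
    aic = 2 * spec.n_params + 2 * nll

    sat_nll, sat_k = _saturated_nll(spec, x, y)
    lr = max(2.0 * (nll - sat_nll), 0.0)
    dof = max(sat_k - spec.n_params, 1)
    gof_p = float(stats.chi2.sf(lr, dof))

    f = _FAMILIES[spec.family][0]
    mu = f(x, theta)
    if spec.variance == "nonconstant":
        var = var_params[0] * np.power(np.maximum(mu, 1e-12), var_params[1])
    else:
        var = np.full_like(y, var_params[0])
    if spec.distribution == "lognormal":
        resp = np.log(y)
        center = np.log(np.maximum(mu, 1e-300))
    else:
        resp, center = y, mu
    rows = []
    for xv in np.unique(x):
        sel = x == xv
        ng = int(sel.sum())
        se = np.sqrt(float(np.mean(var[sel])) / ng)
        rows.append({"concentration": float(xv),
                     "scaled_residual":
                         float((resp[sel].mean() - center[sel].mean()) / se)})
    scaled = pd.DataFrame(rows)
    return BMCFit(spec, theta, var_params, nll, float(aic), True, gof_p,
                  scaled, x, y)


# ---------------------------------------------------------------------------
# benchmark concentration


def compute_bmc(fit: BMCFit, control_sd: float | None = None,
                search_factor: float = 10.0) -> float | None:
    """Smallest concentration where |mean(x) - mean(0)| = 1 control SD.

    ``control_sd`` defaults to the fit's modeled control SD (the
    benchmark response of one standard deviation estimated by the model
    itself); passing an explicit value uses that instead, e.g. the
    sample control SD. For a log-normal fit the comparison is made on
    the log-response scale. Scans a dense log grid from well below the
    lowest positive tested dose up to ``search_factor`` times the
    highest, brackets the first crossing and refines it with Brent root
    solving. Returns None when the benchmark response is never reached
    in that range.
    """
    if not fit.usable or not fit.converged:
        raise ValueError("cannot compute BMC from an unusable fit")
    if control_sd is None:
        control_sd = fit.modeled_control_sd()
    if control_sd <= 0:
        raise ValueError("control SD must be > 0")
    mu0 = float(fit._bmr_mean(0.0))

    def g(xv):
        return np.abs(fit._bmr_mean(xv) - mu0) - control_sd

    xpos = fit.x[fit.x > 0]
    lo = float(xpos.min()) / 1000.0 if xpos.size else 1e-6
    hi = float(fit.x.max()) * search_factor
    grid = np.geomspace(lo, hi, 4096)
    vals = g(grid)
    cross = np.flatnonzero(vals >= 0)
    if cross.size == 0:
        return None
    i = int(cross[0])
    if i == 0:
        return float(grid[0])
    a, b = float(grid[i - 1]), float(grid[i])
    try:
        return float(optimize.brentq(g, a, b, xtol=1e-12, rtol=1e-12))
    except ValueError:
        return b


def _constrained_nll(fit: BMCFit, bmd: float, control_sd: float | None,
                     direction: float, x0=None) -> float:
    """Profile NLL with the mean constrained to hit the BMR at ``bmd``.

    With ``control_sd`` None the benchmark response is one *modeled*
    control SD, which then varies with the variance parameters and is
    profiled jointly — the uncertainty of the control SD propagates into
    the interval, as in likelihood-based benchmark-dose software.
    """
    spec = fit.spec
    nm = spec.n_mean_params
    f = _FAMILIES[spec.family][0]
    bounds = _theta_bounds(spec, fit.x, fit.y)
    vb = [(1e-12, None)] if spec.variance == "constant" \
        else [(1e-12, None), (-10.0, 10.0)]
    use_log = spec.distribution == "lognormal"

    def obj(p):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _nll(spec, p[:nm], p[nm:], fit.x, fit.y)

    def bmr_sd(p):
        if control_sd is not None:
            return control_sd
        alpha = p[nm]
        if spec.variance == "nonconstant":
            mu0 = float(f(np.array([0.0]), p[:nm])[0])
            return float(np.sqrt(max(alpha, 1e-300)
                                 * max(mu0, 1e-12) ** p[nm + 1]))
        return float(np.sqrt(max(alpha, 1e-300)))

    def cons(p):
        th = p[:nm]
        m_b = float(f(np.array([bmd]), th)[0])
        m_0 = float(f(np.array([0.0]), th)[0])
        if use_log:
            if m_b <= 0 or m_0 <= 0:
                return 1e6
            m_b, m_0 = np.log(m_b), np.log(m_0)
        return m_b - m_0 - direction * bmr_sd(p)

    p0 = np.concatenate([fit.theta, fit.var_params]) if x0 is None else x0
    scale = bmr_sd(p0) or 1.0
    try:
        res = optimize.minimize(
            obj, p0, method="SLSQP", bounds=bounds + vb,
            constraints=[{"type": "eq", "fun": cons}],
            options={"maxiter": 400, "ftol": 1e-10})
    except Exception:
        return np.inf
    if not np.isfinite(res.fun) or abs(cons(res.x)) > abs(scale) * 1e-3:
        return np.inf
    return float(res.fun)


def bmc_confidence_interval(
    fit: BMCFit,
    control_sd: float | None = None,
    bmc: float | None = None,
    level: float = 0.95,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> tuple[float | None, float | None, dict]:
    """95% profile-likelihood interval on the BMC.

    The profile fixes candidate BMC values, re-maximizes the likelihood
    subject to the benchmark-response constraint, and finds where twice
    the log-likelihood drop crosses the chi-square(1) critical value.
    With ``control_sd`` None the BMR of one modeled control SD is
    profiled jointly with the mean, so the interval reflects both slope
    and variance uncertainty. If profiling fails on a side, a parametric
    bootstrap (refit + BMC on ``n_bootstrap`` resampled datasets)
    supplies that bound; a side that never crosses within the search
    range is reported one-sided with a flag in the info dict.
    """
    if bmc is None:
        bmc = compute_bmc(fit, control_sd)
    if bmc is None:
        return None, None, {"method": "none", "message": "BMC not computable"}
    crit = stats.chi2.ppf(level, 1) / 2.0
    mu0 = float(fit._bmr_mean(0.0))
    direction = 1.0 if float(fit._bmr_mean(bmc)) >= mu0 else -1.0

    def profile_excess(b):
        return _constrained_nll(fit, b, control_sd, direction) - fit.nll - crit

    info: dict = {"method": "profile", "flags": []}

    def search(side: int) -> float | None:
        # side -1: lower bound, +1: upper bound; expand geometrically
        prev = bmc
        for step in range(1, 25):
            cand = bmc * (1.25 ** (side * step))
            val = profile_excess(cand)
            if not np.isfinite(val):
                return None
            if val > 0:
                a, b = (cand, prev) if side < 0 else (prev, cand)
                try:
                    return float(optimize.brentq(profile_excess, a, b,
                                                 xtol=bmc * 1e-6))
                except ValueError:
                    return None
            prev = cand
        info["flags"].append("unbounded-%s" % ("lower" if side < 0 else "upper"))
        return None

    bmcl = search(-1)
    bmcu = search(+1)

    if bmcl is None or bmcu is None:
        boot_l, boot_u = _bootstrap_interval(fit, control_sd, level,
                                             n_bootstrap, seed)
        if bmcl is None and boot_l is not None:
            bmcl, info["method"] = boot_l, "profile+bootstrap"
        if bmcu is None and boot_u is not None:
            bmcu, info["method"] = boot_u, "profile+bootstrap"
    if bmcl is not None:
        bmcl = min(bmcl, bmc)
    if bmcu is not None:
        bmcu = max(bmcu, bmc)
    return bmcl, bmcu, info


def _bootstrap_interval(fit: BMCFit, control_sd: float, level: float,
                        n_bootstrap: int, seed: int):
    rng = np.random.default_rng(seed)
    spec = fit.spec
    f = _FAMILIES[spec.family][0]
    mu = f(fit.x, fit.theta)
    if spec.variance == "nonconstant":
        var = fit.var_params[0] * np.power(np.maximum(mu, 1e-12),
                                           fit.var_params[1])
    else:
        var = np.full_like(fit.y, fit.var_params[0])
    sd = np.sqrt(var)
    draws = []
    for _ in range(n_bootstrap):
        if spec.distribution == "lognormal":
            yb = np.exp(rng.normal(np.log(np.maximum(mu, 1e-300)), sd))
        else:
            yb = rng.normal(mu, sd)
        try:
            fb = fit_bmc_model(
                pd.DataFrame({"concentration": fit.x, "response": yb}), spec)
            if fb.usable:
                b = compute_bmc(fb, control_sd)
                if b is not None:
                    draws.append(b)
        except Exception:
            continue
    if len(draws) < max(20, n_bootstrap // 4):
        return None, None
    alpha = (1 - level) / 2
    return (float(np.quantile(draws, alpha)),
            float(np.quantile(draws, 1 - alpha)))


# ---------------------------------------------------------------------------
# recommendation & averaging


@dataclass
class _Candidate:
    fit: BMCFit
    bmc: float | None
    bmcl: float | None
    bmcu: float | None
    recommended: bool
    reasons: list


def recommend_and_average(
    fits: list[BMCFit],
    control_sd: float | None = None,
    gof_threshold: float = 0.1,
    residual_threshold: float = 2.0,
    bmc_bmcl_ratio_max: float = 20.0,
    compute_ci: bool = True,
    seed: int = 0,
) -> BMCResult:
    """Screen the fitted suite and average the recommended BMCs.

    Recommendation rules (a documented subset of the usual
    benchmark-dose screening logic): the fit converged and its BMC is
    computable; goodness-of-fit p >= ``gof_threshold``; the absolute
    scaled residual at the control group and at the dose group nearest
    the BMC are below ``residual_threshold``; and BMC/BMCL <
    ``bmc_bmcl_ratio_max``. The result is the unweighted arithmetic mean
    of the recommended models' BMCs (and of their interval bounds). With
    no recommended model, the lowest-AIC usable BMC is reported advisory.
    """
    if not fits:
        raise ValueError("need >= 1 fitted model")
    cands: list[_Candidate] = []
    for fit in fits:
        reasons = []
        bmc = bmcl = bmcu = None
        if not (fit.usable and fit.converged):
            reasons.append("did not converge")
        else:
            bmc = compute_bmc(fit, control_sd)
            if bmc is None:
                reasons.append("BMR not reached in range")
            else:
                if not np.isnan(fit.gof_pvalue) and \
                        fit.gof_pvalue < gof_threshold:
                    reasons.append(f"goodness-of-fit p {fit.gof_pvalue:.3g} "
                                   f"< {gof_threshold}")
                sr = fit.scaled_residuals
                if not sr.empty:
                    ctrl = sr.loc[sr["concentration"].idxmin(),
                                  "scaled_residual"]
                    near = sr.iloc[(sr["concentration"] - bmc).abs().argmin()
                                   ]["scaled_residual"]
                    if abs(ctrl) >= residual_threshold:
                        reasons.append("control scaled residual too large")
                    if abs(near) >= residual_threshold:
                        reasons.append("near-BMC scaled residual too large")
                if not reasons and compute_ci:
                    bmcl, bmcu, _ = bmc_confidence_interval(
                        fit, control_sd, bmc, seed=seed)
                    if bmcl is not None and bmcl > 0 \
                            and bmc / bmcl >= bmc_bmcl_ratio_max:
                        reasons.append("BMC/BMCL ratio too large")
        cands.append(_Candidate(fit, bmc, bmcl, bmcu, not reasons, reasons))

    rec = [c for c in cands if c.recommended]
    max_tested = max(float(np.max(f.x)) for f in fits)
    if rec:
        bmcs = np.array([c.bmc for c in rec])
        bmc = float(bmcs.mean())
        ls = [c.bmcl for c in rec if c.bmcl is not None]
        us = [c.bmcu for c in rec if c.bmcu is not None]
        bmcl = float(np.mean(ls)) if len(ls) == len(rec) else None
        bmcu = float(np.mean(us)) if len(us) == len(rec) else None
        return BMCResult(
            bmc=bmc, bmcl=bmcl, bmcu=bmcu,
            bmr_definition="1 control SD",
            contributing=[c.fit.spec for c in rec],
            recommended=True, extrapolated=bmc > max_tested,
            message=f"averaged over {len(rec)} recommended model(s)")
    usable = [c for c in cands if c.bmc is not None]
    if not usable:
        return BMCResult(None, None, None, "1 control SD", [], False,
                         message="no usable model reached the BMR")
    best = min(usable, key=lambda c: c.fit.aic)
    return BMCResult(
        bmc=best.bmc, bmcl=best.bmcl, bmcu=best.bmcu,
        bmr_definition="1 control SD", contributing=[best.fit.spec],
        recommended=False, advisory=True,
        extrapolated=best.bmc > max_tested,
        message="no recommendation; lowest-AIC BMC reported advisory "
                f"({'; '.join(best.reasons) or 'n/a'})")


def fit_bmc_suite(
    series: pd.DataFrame,
    specs: tuple = DEFAULT_MODEL_SPECS,
    control_sd: float | None = None,
    seed: int = 0,
    compute_ci: bool = True,
) -> tuple[BMCResult, list[BMCFit]]:
    """Fit the full model suite and return the screened/averaged result.

    The benchmark response is a change of one control standard
    deviation; by default each model's own (modeled) control SD is used,
    as in likelihood-based benchmark-dose software, but an explicit
    sample control SD may be passed instead.
    """
    fits = [fit_bmc_model(series, s) for s in specs]
    result = recommend_and_average(fits, control_sd, seed=seed,
                                   compute_ci=compute_ci)
    return result, fits
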