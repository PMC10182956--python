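"""Dose-response endpoints: normalization, log-logistic fitting, hit calling.

Turns per-well image quantifications into four endpoint fold-change
series (lipid droplets per cell, net Mitotracker intensity per cell, net
CellROX intensity per cell, apoptotic fraction), normalized per plate to
the vehicle-control mean so unexposed wells sit at a fold change of 1.
Each chemical x endpoint series is fitted with 3- and 4-parameter
log-logistic models selected by AIC, and a directional hit is called when
the fitted curve exceeds +/- 2 pooled standard deviations of the response
at the two lowest tested concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "ENDPOINTS",
    "log_logistic",
    "LogLogisticFit",
    "HitCall",
    "EC50Result",
    "compute_endpoint_table",
    "compute_hit_threshold",
    "fit_dose_response",
    "call_hit",
    "fit_ec50",
    "evaluate_calls",
]

#: canonical endpoint names, in assay order
ENDPOINTS = (
    "lipid_accumulation",
    "mitochondrial_membrane_potential",
    "oxidative_stress",
    "nuclear_morphology",
)


def log_logistic(x, b: float, c: float, d: float, e: float):
    """Four-parameter log-logistic curve c + (d-c)/(1 + exp(b*(ln x - ln e))).

    ``c`` and ``d`` are the two asymptotes, ``e`` the inflection
    concentration, ``b`` the slope. With b < 0 the curve runs from c at
    zero concentration to d at infinity; x = 0 is handled as that limit.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        t = np.exp(np.clip(b * (np.log(x[pos]) - np.log(e)), -700, 700))
    out[pos] = c + (d - c) / (1.0 + t)
    out[~pos] = c if b < 0 else d
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LogLogisticFit:
    """A fitted log-logistic dose-response model.

    ``n_params`` is 3 (baseline asymptote c fixed at 1) or 4 (both
    asymptotes free). AIC is computed from the Gaussian log-likelihood
    with the residual variance estimated from the fit.
    """

    n_params: int
    b: float
    c: float
    d: float
    e: float
    aic: float
    residual_sd: float
    converged: bool
    n_obs: int

    def predict(self, x):
        return log_logistic(x, self.b, self.c, self.d, self.e)

    @property
    def baseline(self) -> float:
        """Fitted response in the zero-concentration limit."""
        return self.c if self.b < 0 else self.d

    @property
    def plateau(self) -> float:
        """Fitted response in the high-concentration limit."""
        return self.d if self.b < 0 else self.c


@dataclass(frozen=True)
class HitCall:
    hit: bool
    direction: str  # 'increase' | 'decrease' | 'none'
    lowest_exceeding_concentration: float | None
    threshold: tuple[float, float]


@dataclass(frozen=True)
class EC50Result:
    ec50: float | None
    censored: bool  # True when no half-maximal decline within tested range
    fit: LogLogisticFit | None
    top_tested: float


# ---------------------------------------------------------------------------
# endpoint table


def compute_endpoint_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-well endpoint values and per-plate vehicle-normalized fold changes.

    Parameters
    ----------
    quant
        One row per well with columns ``plate_id, chemical, concentration,
        is_vehicle, n_cells, n_droplets, mean_mito, background_mito,
        mean_oxstress, background_oxstress, n_apoptotic`` (an optional
        ``experiment`` column is carried through).

    Returns
    -------
    DataFrame
        Tidy long format: one row per well x endpoint with ``raw_value``
        (droplets/cell, net intensity/cell, apoptotic fraction) and
        ``fold_change`` (raw value divided by the same plate's vehicle
        mean for that endpoint). Wells with zero cells are excluded with
        a log entry; a plate without vehicle wells raises ValueError.
    """
    df = quant.copy()
    zero = df["n_cells"] <= 0
    if zero.any():
        logger.warning("excluding %d wells with zero cells", int(zero.sum()))
        df = df[~zero]
    if df.empty:
        raise ValueError("no wells with cells remain")

    raw = pd.DataFrame({
        "lipid_accumulation": df["n_droplets"] / df["n_cells"],
        "mitochondrial_membrane_potential":
            (df["mean_mito"] - df["background_mito"]) / df["n_cells"],
        "oxidative_stress":
            (df["mean_oxstress"] - df["background_oxstress"]) / df["n_cells"],
        "nuclear_morphology": df["n_apoptotic"] / df["n_cells"],
    })
    meta_cols = [c for c in ("plate_id", "experiment", "chemical",
                             "concentration", "is_vehicle") if c in df.columns]
    long = pd.concat([df[meta_cols].reset_index(drop=True),
                      raw.reset_index(drop=True)], axis=1)
    long = long.melt(id_vars=meta_cols, var_name="endpoint",
                     value_name="raw_value")

    out = []
    for (plate, endpoint), grp in long.groupby(["plate_id", "endpoint"]):
        veh = grp[grp["is_vehicle"]]
        if veh.empty:
            raise ValueError(f"plate {plate!r} has no vehicle wells")
        vmean = veh["raw_value"].mean()
        g = grp.copy()
        if vmean != 0:
            g["fold_change"] = g["raw_value"] / vmean
        else:
            # degenerate vehicle (e.g. zero apoptotic cells in controls):
            # fall back to an additive shift so controls still center at 1
            g["fold_change"] = g["raw_value"] - veh["raw_value"].mean() + 1.0
            logger.warning("plate %r endpoint %s: vehicle mean is 0; "
                           "using additive normalization", plate, endpoint)
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# hit threshold


def compute_hit_threshold(series: pd.DataFrame) -> tuple[float, float]:
    """+/- 2 SD band from the responses at the two lowest concentrations.

    ``series`` needs columns ``concentration`` and ``fold_change``. The
    anchors are the two lowest distinct nonzero tested concentrations
    (vehicle wells are handled by the fold-change definition, not here);
    the band is m +/- 2s with m the mean and s the pooled (overall,
    ddof=1) SD of all replicate wells at those two doses. Each anchor
    must have >= 2 wells.
    """
    s = series[series["concentration"] > 0]
    concs = np.sort(s["concentration"].unique())
    if concs.size < 2:
        raise ValueError("need >= 2 distinct nonzero concentrations")
    anchors = s[s["concentration"].isin(concs[:2])]
    counts = anchors.groupby("concentration").size()
    if (counts < 2).any():
        raise ValueError("each anchor concentration needs >= 2 wells")
    vals = anchors["fold_change"].to_numpy(dtype=float)
    m = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return (m - 2.0 * sd, m + 2.0 * sd)


# ---------------------------------------------------------------------------
# log-logistic fitting


def _fit_variant(x, y, n_params: int) -> LogLogisticFit:
    """Least-squares fit of one log-logistic variant (c free or fixed at 1)."""
    e_lo = max(x[x > 0].min() / 10.0, 1e-12)
    e_hi = x.max() * 10.0
    y_lo, y_hi = float(y.min()), float(y.max())
    span = max(y_hi - y_lo, 1e-6)
    e0 = float(np.exp(np.mean(np.log(x[x > 0]))))

    def _unpack(p):
        if n_params == 4:
            b, c, d, loge = p
        else:
            b, d, loge = p
            c = 1.0
        return b, c, d, loge

    def residuals(p):
        b, c, d, loge = _unpack(p)
        return log_logistic(x, b, c, d, np.exp(loge)) - y

    def jacobian(p):
        # analytic derivatives of c + (d-c)/(1+t), t = exp(b (ln x - ln e))
        b, c, d, loge = _unpack(p)
        J = np.zeros((x.size, n_params))
        pos = x > 0
        u = np.log(x[pos]) - loge
        with np.errstate(over="ignore"):
            t = np.exp(np.clip(b * u, -700, 700))
        inv = 1.0 / (1.0 + t)
        w = t * inv * inv  # t/(1+t)^2, -> 0 in both saturation limits
        d_b = -(d - c) * w * u
        d_c = t * inv
        d_d = inv
        d_loge = (d - c) * w * b
        # zero-concentration rows sit at the curve's limit: only the
        # relevant asymptote derivative is nonzero
        if n_params == 4:
            J[pos, 0], J[pos, 1], J[pos, 2], J[pos, 3] = d_b, d_c, d_d, d_loge
            J[~pos, 1] = 1.0 if b < 0 else 0.0
            J[~pos, 2] = 0.0 if b < 0 else 1.0
        else:
            J[pos, 0], J[pos, 1], J[pos, 2] = d_b, d_d, d_loge
            J[~pos, 1] = 0.0 if b < 0 else 1.0
        return J

    if n_params == 4:
        lb = [-50.0, y_lo - span, y_lo - span, np.log(e_lo)]
        ub = [50.0, y_hi + span, y_hi + span, np.log(e_hi)]
        starts = [[-1.0, y_lo, y_hi, np.log(e0)], [1.0, y_hi, y_lo, np.log(e0)]]
    else:
        lb = [-50.0, y_lo - span, np.log(e_lo)]
        ub = [50.0, y_hi + span, np.log(e_hi)]
        starts = [[-1.0, y_hi, np.log(e0)], [-1.0, y_lo, np.log(e0)],
                  [1.0, y_lo, np.log(e0)]]

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(residuals, p0, jac=jacobian,
                                bounds=(lb, ub), method="trf", max_nfev=200)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    n = y.size
    if best is None or not np.all(np.isfinite(best.x)):
        return LogLogisticFit(n_params, np.nan, np.nan, np.nan, np.nan,
                              np.inf, np.nan, False, n)
    if n_params == 4:
        b, c, d, loge = best.x
    else:
        b, d, loge = best.x
        c = 1.0
    rss = float(2 * best.cost)
    sigma2 = max(rss / n, 1e-300)
    k = n_params + 1  # + residual variance
    aic = n * np.log(2 * np.pi * sigma2) + n + 2 * k
    # a finite bounded least-squares solution is usable even when the
    # evaluation cap was reached (common for near-flat series where the
    # slope runs along its bound)
    converged = bool(best.success or np.isfinite(rss))
    return LogLogisticFit(n_params, float(b), float(c), float(d),
                          float(np.exp(loge)), float(aic),
                          float(np.sqrt(sigma2)), converged, n)


def fit_dose_response(series: pd.DataFrame,
                      aic_tie_margin: float = 2.0) -> LogLogisticFit:
    """Fit 3- and 4-parameter log-logistic models; return the lower-AIC one.

    Both variants are fitted by least squares on the fold changes
    (vehicle wells included at concentration 0, handled as the curve's
    zero limit). Ties within ``aic_tie_margin`` AIC units are broken
    toward the 3-parameter model for parsimony. If neither variant
    converges a RuntimeError is raised so the series is reported unfit
    rather than silently flat.
    """
    x = series["concentration"].to_numpy(dtype=float)
    y = series["fold_change"].to_numpy(dtype=float)
    if np.unique(x[x > 0]).size < 4:
        raise ValueError("need >= 4 nonzero concentrations to fit")
    fit3 = _fit_variant(x, y, 3)
    fit4 = _fit_variant(x, y, 4)
    if not fit3.converged and not fit4.converged:
        raise RuntimeError("log-logistic fit failed to converge for both "
                           "the 3- and 4-parameter variants")
    if not fit4.converged:
        return fit3
    if not fit3.converged:
        return fit4
    if fit4.aic < fit3.aic - aic_tie_margin:
        return fit4
    return fit3


# ---------------------------------------------------------------------------
# hit calling


def call_hit(fit: LogLogisticFit, threshold: tuple[float, float],
             tested_range: tuple[float, float], n_grid: int = 1024) -> HitCall:
    """Directional hit: fitted curve crosses the +/- 2 SD band in-range.

    The curve is evaluated on a log-spaced grid over the tested nonzero
    concentration range; the call reports the lowest concentration at
    which the band is exceeded and the direction of the excursion.
    """
    lo, hi = threshold
    cmin, cmax = tested_range
    if cmin <= 0 or cmax < cmin:
        raise ValueError("tested range must be positive and ordered")
    grid = np.geomspace(cmin, cmax, n_grid)
    pred = fit.predict(grid)
    above = pred > hi
    below = pred < lo
    idx_a = int(np.argmax(above)) if above.any() else None
    idx_b = int(np.argmax(below)) if below.any() else None
    if idx_a is None and idx_b is None:
        return HitCall(False, "none", None, threshold)
    if idx_b is None or (idx_a is not None and idx_a <= idx_b):
        return HitCall(True, "increase", float(grid[idx_a]), threshold)
    return HitCall(True, "decrease", float(grid[idx_b]), threshold)


# ---------------------------------------------------------------------------
# viability EC50


def fit_ec50(series: pd.DataFrame) -> EC50Result:
    """EC50 from a viability (% of control) series via the log-logistic fit.

    Used to cap the concentrations tested in the imaging assay. If the
    fitted curve never falls below half of its baseline within the tested
    range, the EC50 is right-censored (reported as > top tested).
    """
    x = series["concentration"].to_numpy(dtype=float)
    top = float(x[x > 0].max())
    s = series.rename(columns={"viability": "fold_change"}) \
        if "viability" in series.columns else series
    fit = fit_dose_response(s)
    half = (fit.baseline + fit.plateau) / 2.0
    # half-maximal response must actually be reached within the range
    pred_top = float(fit.predict(np.array([top]))[0])
    declines = fit.plateau < fit.baseline
    if not declines or pred_top > half or fit.e > top:
        return EC50Result(None, True, fit, top)
    return EC50Result(float(fit.e), False, fit, top)


# ---------------------------------------------------------------------------
# validation metrics


def evaluate_calls(expected: pd.DataFrame, observed: pd.DataFrame) -> dict:
    """Sensitivity/specificity of observed vs expected hit calls.

    Both tables need columns ``chemical, endpoint, hit`` (boolean).
    Pairs present in only one table are excluded with a log entry.
    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), per endpoint and
    pooled across endpoints.
    """
    exp = expected.set_index(["chemical", "endpoint"])["hit"]
    obs = observed.set_index(["chemical", "endpoint"])["hit"]
    common = exp.index.intersection(obs.index)
    missing = len(exp.index.symmetric_difference(obs.index))
    if missing:
        logger.warning("excluding %d unmatched chemical x endpoint calls",
                       missing)
    if common.empty:
        raise ValueError("no aligned calls to evaluate")
    e = exp.loc[common].astype(bool)
    o = obs.loc[common].astype(bool)

    def confusion(ei, oi):
        tp = int((ei & oi).sum())
        fn = int((ei & ~oi).sum())
        tn = int((~ei & ~oi).sum())
        fp = int((~ei & oi).sum())
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        return {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
                "sensitivity_pct": sens, "specificity_pct": spec}

    per_endpoint = {
        ep: confusion(e.xs(ep, level="endpoint"), o.xs(ep, level="endpoint"))
        for ep in e.index.get_level_values("endpoint").unique()
    }
    overall = confusion(e, o)
    return {"per_endpoint": per_endpoint, "overall": overall}
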