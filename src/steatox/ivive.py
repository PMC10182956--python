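"""In vitro to in vivo extrapolation (IVIVE) and reverse dosimetry.

Implements a three-compartment steady-state pharmacokinetic model for oral
exposure: steady-state blood concentration (Css) under constant daily
dosing, oral equivalent doses (OED) by reverse dosimetry against an in
vitro benchmark concentration, scaling between in vitro intrinsic hepatic
clearance and whole-body metabolic clearance, and Monte Carlo simulation
of population variability in glomerular filtration, hepatic/gut blood
flow, and metabolic clearance.

Model assumptions (documented, hard-coded):

* oral route of exposure, daily dosing with a constant dose rate;
* 100% bioavailability;
* renal excretion limited to glomerular filtration of unbound chemical
  (GFR * fup);
* hepatic elimination by the well-stirred model, flow-limited through the
  combined liver + gut blood flow;
* first-order kinetics, so Css is linear in dose rate — the property that
  licenses the reverse-dosimetry OED calculation.

Units are part of every public signature: flows are allometrically scaled
(ml/min/kg^3/4) and converted to whole-body L/day at a reference body
weight; intrinsic clearance is ul/min per 10^6 hepatocytes; Css is mg/L
(or uM via the molecular weight); OED is mg/kg BW/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChemicalPK",
    "PhysiologyParams",
    "ClearanceScalingConstants",
    "InVivoPKRecord",
    "CssDistribution",
    "OEDDistribution",
    "DEFAULT_SCALING",
    "REFERENCE_BODY_WEIGHT_KG",
    "mg_per_l_to_um",
    "um_to_mg_per_l",
    "clint_to_cl_metabolism",
    "clint_from_in_vivo",
    "calc_css",
    "sample_population",
    "simulate_css_distribution",
    "calc_oed",
    "css_from_pk",
    "evaluate_forward",
    "hazard_compare",
]

# Reference body weights used to convert allometric (kg^3/4) flows to
# whole-body values, by species.
REFERENCE_BODY_WEIGHT_KG = {"human": 70.0, "rat": 0.25, "rabbit": 2.5}

_ML_MIN_TO_L_DAY = 60.0 * 24.0 / 1000.0  # ml/min -> L/day


@dataclass(frozen=True)
class ClearanceScalingConstants:
    """Physiological constants linking intrinsic and whole-body clearance.

    ``liver_density_g_per_ml`` (1.05 g/ml) and ``hepatocytes_per_g_liver``
    (1.1e8 cells/g) together with the per-species liver volume (L/kg BW)
    give the number of hepatocytes per kg body weight; the unit-conversion
    chain (million cells <-> cells, ml <-> L, min <-> h, L <-> ul) is
    applied explicitly in :func:`clint_to_cl_metabolism`.
    """

    liver_density_g_per_ml: float = 1.05
    hepatocytes_per_g_liver: float = 1.1e8
    liver_volume_l_per_kg: dict = field(
        default_factory=lambda: {"human": 0.0245, "rat": 0.0349, "rabbit": 0.04}
    )
    f_ub_corr: float = 1.0  # assay binding correction; 1 = no correction

    def hepatocytes_per_kg_bw(self, species: str) -> float:
        if species not in self.liver_volume_l_per_kg:
            raise KeyError(f"unknown species {species!r}; expected one of "
                           f"{sorted(self.liver_volume_l_per_kg)}")
        # g liver per kg BW = density [g/ml] * 1000 [ml/L] * V_liver [L/kg]
        g_liver_per_kg = (self.liver_density_g_per_ml * 1000.0
                          * self.liver_volume_l_per_kg[species])
        return g_liver_per_kg * self.hepatocytes_per_g_liver


DEFAULT_SCALING = ClearanceScalingConstants()


@dataclass(frozen=True)
class ChemicalPK:
    """Chemical-specific toxicokinetic parameters.

    fup
        fraction of chemical unbound in plasma, in (0, 1].
    clint
        in vitro intrinsic hepatic clearance, ul/min per 10^6 hepatocytes.
    r_blood2plasma
        blood:plasma concentration ratio (unitless).
    mw
        molecular weight, g/mol.
    """

    name: str
    fup: float
    clint: float
    r_blood2plasma: float = 1.0
    mw: float = 250.0
    species: str = "human"

    def __post_init__(self) -> None:
        if not 0.0 < self.fup <= 1.0:
            raise ValueError(f"fup must be in (0, 1], got {self.fup}")
        if self.clint < 0:
            raise ValueError(f"clint must be >= 0, got {self.clint}")
        if self.mw <= 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        if self.r_blood2plasma <= 0:
            raise ValueError("r_blood2plasma must be > 0")


@dataclass(frozen=True)
class PhysiologyParams:
    """Population-mean physiology with allometrically scaled flows.

    Flows are in ml/min/kg^3/4 (means: GFR 5.17, liver blood flow 59.9,
    gut blood flow 47.5). ``cv_*`` are the coefficients of variation used
    by the Monte Carlo population sampler; metabolic clearance variability
    is expressed as a multiplicative factor with CV ``cv_cl_metabolism``.
    """

    gfr: float = 5.17
    q_liver: float = 59.9
    q_gut: float = 47.5
    body_weight: float = 70.0
    cv_gfr: float = 0.3
    cv_q_liver: float = 0.3
    cv_q_gut: float = 0.3
    cv_cl_metabolism: float = 0.5

    def __post_init__(self) -> None:
        for name in ("gfr", "q_liver", "q_gut", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cv_gfr", "cv_q_liver", "cv_q_gut", "cv_cl_metabolism"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class InVivoPKRecord:
    """Published in vivo pharmacokinetic record for a Css back-calculation.

    ``cl`` is total (or hepatic, if available) clearance; ``cl_per_kg``
    flags whether it is L/h/kg (True) or absolute L/h (False). ``dose``
    must be on the matching basis (mg/kg or mg).
    """

    dose: float
    f_bioavailable: float
    cl: float
    dosing_interval_h: float = 24.0
    cl_per_kg: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.f_bioavailable <= 1.0:
            raise ValueError("bioavailability F must be in (0, 1]")
        if self.cl <= 0:
            raise ValueError("clearance must be > 0")
        if self.dosing_interval_h <= 0:
            raise ValueError("dosing interval must be > 0")


@dataclass(frozen=True)
class CssDistribution:
    """Monte Carlo draws of steady-state concentration for one chemical."""

    chemical: str
    draws_mg_per_l: np.ndarray
    mw: float
    ko_mg_per_kg_day: float
    seed: int | None = None

    @property
    def draws_um(self) -> np.ndarray:
        return mg_per_l_to_um(self.draws_mg_per_l, self.mw)

    @property
    def median_mg_per_l(self) -> float:
        return float(np.median(self.draws_mg_per_l))

    @property
    def median_um(self) -> float:
        return float(np.median(self.draws_um))

    def summary(self) -> dict:
        d = self.draws_mg_per_l
        return {
            "chemical": self.chemical,
            "n_individuals": int(d.size),
            "median_mg_per_l": float(np.median(d)),
            "p2.5_mg_per_l": float(np.percentile(d, 2.5)),
            "p97.5_mg_per_l": float(np.percentile(d, 97.5)),
            "median_um": self.median_um,
        }


@dataclass(frozen=True)
class OEDDistribution:
    """Monte Carlo draws of the oral equivalent dose (mg/kg BW/day)."""

    chemical: str
    endpoint: str
    bmc_um: float
    draws_mg_per_kg_day: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.draws_mg_per_kg_day))

    def summary(self) -> dict:
        d = self.draws_mg_per_kg_day
        return {
            "chemical": self.chemical,
            "endpoint": self.endpoint,
            "bmc_um": self.bmc_um,
            "median_oed": float(np.median(d)),
            "p2.5_oed": float(np.percentile(d, 2.5)),
            "p97.5_oed": float(np.percentile(d, 97.5)),
            "n_individuals": int(d.size),
        }


# ---------------------------------------------------------------------------
# unit conversions


def mg_per_l_to_um(value_mg_per_l, mw: float):
    """Convert mg/L to micromolar using the molecular weight (g/mol)."""
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return np.asarray(value_mg_per_l, dtype=float) * 1000.0 / mw


def um_to_mg_per_l(value_um, mw: float):
    """Convert micromolar to mg/L using the molecular weight (g/mol)."""
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return np.asarray(value_um, dtype=float) * mw / 1000.0


# ---------------------------------------------------------------------------
# clearance scaling


def clint_to_cl_metabolism(
    clint: float,
    species: str = "human",
    constants: ClearanceScalingConstants = DEFAULT_SCALING,
    f_ub_corr: float | None = None,
) -> float:
    """Scale intrinsic clearance (ul/min/10^6 cells) to L/h/kg BW.

    Inverse of :func:`clint_from_in_vivo`: multiplies by hepatocytes per
    kg body weight (liver density x liver volume x cells per gram) and
    converts ul/min to L/h.
    """
    if clint < 0:
        raise ValueError("clint must be >= 0")
    fub = constants.f_ub_corr if f_ub_corr is None else f_ub_corr
    cells_per_kg_millions = constants.hepatocytes_per_kg_bw(species) / 1e6
    ul_min_per_kg = clint * cells_per_kg_millions
    return ul_min_per_kg * 60.0 / 1e6 / fub  # -> L/h/kg


def clint_from_in_vivo(
    cl_metabolism_l_h_kg: float,
    species: str = "human",
    constants: ClearanceScalingConstants = DEFAULT_SCALING,
    f_ub_corr: float | None = None,
) -> float:
    """Back-calculate in vitro intrinsic clearance from in vivo clearance.

    Parameters
    ----------
    cl_metabolism_l_h_kg
        In vivo (hepatic if available, else total) clearance in L/h/kg.
    species
        'human', 'rat' or 'rabbit' — selects the liver volume per kg.

    Returns
    -------
    float
        Intrinsic clearance in ul/min per 10^6 hepatocytes.
    """
    if cl_metabolism_l_h_kg < 0:
        raise ValueError("clearance must be >= 0")
    fub = constants.f_ub_corr if f_ub_corr is None else f_ub_corr
    cells_per_kg_millions = constants.hepatocytes_per_kg_bw(species) / 1e6
    ul_min_per_kg = cl_metabolism_l_h_kg * fub * 1e6 / 60.0
    return ul_min_per_kg / cells_per_kg_millions


# ---------------------------------------------------------------------------
# steady-state model


def calc_css(
    chem: ChemicalPK,
    phys: PhysiologyParams | None = None,
    ko: float = 1.0,
    *,
    gfr: float | None = None,
    q_liver: float | None = None,
    q_gut: float | None = None,
    cl_multiplier: float = 1.0,
    constants: ClearanceScalingConstants = DEFAULT_SCALING,
):
    """Steady-state blood concentration (mg/L) at dose rate ``ko``.

    Css = ko / (GFR*fup + Q*fup*Cl / (Q + fup*Cl/Rb2p)) with Q the summed
    liver + gut blood flow and Cl the whole-body metabolic clearance
    scaled from ``chem.clint``. Allometric flows (ml/min/kg^3/4) are
    converted to whole-body L/day at ``phys.body_weight``; ``ko`` is
    mg/kg BW/day, so the numerator is ko * BW (mg/day).

    The ``gfr``/``q_liver``/``q_gut``/``cl_multiplier`` overrides accept
    scalars or arrays of individual Monte Carlo draws (still on the
    ml/min/kg^3/4 scale); the return value is then an array.
    """
    if phys is None:
        phys = PhysiologyParams()
    if ko <= 0:
        raise ValueError("dose rate ko must be > 0")
    bw = phys.body_weight
    scale = bw ** 0.75 * _ML_MIN_TO_L_DAY  # ml/min/kg^3/4 -> L/day

    gfr_v = np.asarray(phys.gfr if gfr is None else gfr, dtype=float) * scale
    ql = np.asarray(phys.q_liver if q_liver is None else q_liver, dtype=float) * scale
    qg = np.asarray(phys.q_gut if q_gut is None else q_gut, dtype=float) * scale
    q_total = ql + qg

    cl_l_day = (clint_to_cl_metabolism(chem.clint, chem.species, constants)
                * bw * 24.0 * np.asarray(cl_multiplier, dtype=float))

    fup = chem.fup
    with np.errstate(invalid="ignore", divide="ignore"):
        hepatic = np.where(
            cl_l_day > 0,
            q_total * fup * cl_l_day
            / (q_total + fup * cl_l_day / chem.r_blood2plasma),
            0.0,
        )
    css = ko * bw / (gfr_v * fup + hepatic)
    return float(css) if np.ndim(css) == 0 else css


def sample_population(
    phys: PhysiologyParams,
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
    truncate_z: float = 1.96,
) -> pd.DataFrame:
    """Draw ``n`` individuals' physiology for Monte Carlo simulation.

    Each varied parameter (GFR, liver flow, gut flow, and a multiplicative
    metabolic-clearance factor centred on 1) is drawn from an
    independent normal at its stated CV, truncated below at
    mean - ``truncate_z``*SD (the 2.5th percentile by default) so draws
    stay positive and physiologically plausible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def draw(mean: float, cv: float) -> np.ndarray:
        if cv == 0:
            return np.full(n, mean)
        sd = mean * cv
        return stats.truncnorm.rvs(-truncate_z, np.inf, loc=mean, scale=sd,
                                   size=n, random_state=rng)

    return pd.DataFrame({
        "gfr": draw(phys.gfr, phys.cv_gfr),
        "q_liver": draw(phys.q_liver, phys.cv_q_liver),
        "q_gut": draw(phys.q_gut, phys.cv_q_gut),
        "cl_multiplier": draw(1.0, phys.cv_cl_metabolism),
    })


def simulate_css_distribution(
    chem: ChemicalPK,
    phys: PhysiologyParams | None = None,
    ko: float = 1.0,
    n: int = 1000,
    seed: int | None = None,
) -> CssDistribution:
    """Monte Carlo Css across a simulated population of ``n`` individuals."""
    if phys is None:
        phys = PhysiologyParams()
    pop = sample_population(phys, n=n, seed=seed)
    draws = calc_css(
        chem, phys, ko,
        gfr=pop["gfr"].to_numpy(),
        q_liver=pop["q_liver"].to_numpy(),
        q_gut=pop["q_gut"].to_numpy(),
        cl_multiplier=pop["cl_multiplier"].to_numpy(),
    )
    return CssDistribution(chemical=chem.name, draws_mg_per_l=np.asarray(draws),
                           mw=chem.mw, ko_mg_per_kg_day=ko, seed=seed)


# ---------------------------------------------------------------------------
# reverse dosimetry


def calc_oed(
    bmc_um: float,
    css: CssDistribution,
    endpoint: str = "",
) -> OEDDistribution:
    """Oral equivalent dose by reverse dosimetry: OED = BMC / Css(1 mg/kg/day).

    Valid only under first-order kinetics (Css linear in dose rate); the
    Css draws must have been simulated at a dose rate of 1 mg/kg BW/day.
    Draw-wise division propagates the population variability of Css into
    an OED distribution (mg/kg BW/day).
    """
    if bmc_um <= 0:
        raise ValueError("bmc must be > 0")
    if css.ko_mg_per_kg_day != 1.0:
        raise ValueError("OED requires Css simulated at ko = 1 mg/kg/day")
    draws = bmc_um / css.draws_um
    return OEDDistribution(chemical=css.chemical, endpoint=endpoint,
                           bmc_um=bmc_um, draws_mg_per_kg_day=draws)


def pool_oed_draws(distributions: list[OEDDistribution]) -> np.ndarray:
    """Concatenate OED draws across chemicals/endpoints for pooled display."""
    if not distributions:
        return np.empty(0)
    return np.concatenate([d.draws_mg_per_kg_day for d in distributions])


def css_from_pk(rec: InVivoPKRecord, body_weight: float | None = None) -> float:
    """Css (mg/L) from published PK parameters: Dose*F / (Cl * interval).

    If the record's clearance is per kg (``cl_per_kg``), the dose must be
    mg/kg and the units cancel without a body weight; mixing a per-kg
    clearance with an absolute request (or vice versa) raises.
    """
    if rec.cl_per_kg and body_weight is not None:
        raise ValueError("per-kg clearance record: dose must already be mg/kg; "
                         "do not pass body_weight")
    return rec.dose * rec.f_bioavailable / (rec.cl * rec.dosing_interval_h)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_forward(predicted, observed) -> dict:
    """Compare predicted vs observed Css on the log10 scale.

    Returns the coefficient of determination R^2 and root-mean-squared
    error of log10(predicted) against log10(observed), plus per-chemical
    fold errors 10^|delta log10|.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size != obs.size or pred.size < 3:
        raise ValueError("need >= 3 paired predicted/observed values")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("all concentrations must be > 0 for log10 comparison")
    lp, lo = np.log10(pred), np.log10(obs)
    resid = lp - lo
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((lo - lo.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else (
        1.0 if np.allclose(resid, 0) else float("-inf"))
    fold = 10.0 ** np.abs(resid)
    return {
        "r2_log10": r2,
        "rmse_log10": rmse,
        "mean_fold_error": float(np.mean(fold)),
        "fold_errors": fold,
    }


def hazard_compare(
    bmc_um: float,
    css: CssDistribution,
    hazard_ratio: float = 1.0,
    margin_ratio: float = 10.0,
) -> dict:
    """Compare an in vitro BMC against the predicted in vivo Css median.

    ratio = BMC / median Css (both uM). A ratio below ``hazard_ratio``
    (bioactivity at or below the predicted internal exposure) flags a
    potential in vivo hazard; ratios in [hazard_ratio, margin_ratio) are
    near-margin (a ratio of exactly 1 falls here); larger ratios are low
    priority. Thresholds are configurable.
    """
    if bmc_um <= 0:
        raise ValueError("bmc must be > 0")
    med = css.median_um
    if med <= 0:
        raise ValueError("median Css must be > 0")
    ratio = bmc_um / med
    if ratio < hazard_ratio:
        category = "hazard"
    elif ratio < margin_ratio:
        category = "near-margin"
    else:
        category = "low-priority"
    return {"chemical": css.chemical, "ratio": ratio, "category": category,
            "bmc_um": bmc_um, "median_css_um": med}
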