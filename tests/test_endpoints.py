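"""Endpoint normalization, log-logistic fitting, hit calling, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steatox.endpoints import (call_hit, compute_endpoint_table,
                               compute_hit_threshold, evaluate_calls,
                               fit_dose_response, fit_ec50, log_logistic)
from steatox.synth import (ChemicalProfile, CurveParams,
                           generate_plate_dataset, normalize_plate_wells)


def _quant_df(rows):
    defaults = dict(plate_id="p1", chemical="c", concentration=10.0,
                    is_vehicle=False, n_cells=100, n_droplets=0,
                    mean_mito=0.0, background_mito=0.0, mean_oxstress=0.0,
                    background_oxstress=0.0, n_apoptotic=0)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestEndpointTable:
    def test_droplets_per_cell_fold_change(self):
        # vehicle wells at 2 droplets/cell; treated well at 4 -> fold 2.0
        df = _quant_df([
            {"is_vehicle": True, "concentration": 0.0, "n_cells": 100,
             "n_droplets": 200},
            {"is_vehicle": True, "concentration": 0.0, "n_cells": 50,
             "n_droplets": 100},
            {"n_cells": 200, "n_droplets": 800},
        ])
        out = compute_endpoint_table(df)
        la = out[out["endpoint"] == "lipid_accumulation"]
        assert la.loc[~la["is_vehicle"], "fold_change"].iloc[0] == \
            pytest.approx(2.0)
        assert la.loc[la["is_vehicle"], "fold_change"].mean() == \
            pytest.approx(1.0)

    def test_apoptotic_fraction_fold_change(self):
        df = _quant_df([
            {"is_vehicle": True, "concentration": 0.0, "n_cells": 400,
             "n_apoptotic": 10},   # fraction 0.025
            {"is_vehicle": True, "concentration": 0.0, "n_cells": 400,
             "n_apoptotic": 10},
            {"n_cells": 400, "n_apoptotic": 20},
        ])
        out = compute_endpoint_table(df)
        nm = out[out["endpoint"] == "nuclear_morphology"]
        assert nm.loc[~nm["is_vehicle"], "fold_change"].iloc[0] == \
            pytest.approx(2.0)

    def test_plate_scaling_invariance(self):
        # multiplying every raw intensity/count ratio on a plate by a
        # constant must leave fold changes unchanged
        base = _quant_df([
            {"is_vehicle": True, "concentration": 0.0, "n_droplets": 150,
             "mean_mito": 500.0, "background_mito": 100.0, "n_apoptotic": 4},
            {"is_vehicle": True, "concentration": 0.0, "n_droplets": 170,
             "mean_mito": 520.0, "background_mito": 100.0, "n_apoptotic": 6},
            {"n_droplets": 420, "mean_mito": 900.0, "background_mito": 100.0,
             "n_apoptotic": 14},
        ])
        scaled = base.copy()
        for col in ("n_droplets", "n_apoptotic"):
            scaled[col] = scaled[col] * 3
        scaled["mean_mito"] = (scaled["mean_mito"]
                               - scaled["background_mito"]) * 3 \
            + scaled["background_mito"]
        a = compute_endpoint_table(base)
        b = compute_endpoint_table(scaled)
        for ep in ("lipid_accumulation", "mitochondrial_membrane_potential",
                   "nuclear_morphology"):
            pd.testing.assert_series_equal(
                a.loc[a["endpoint"] == ep, "fold_change"],
                b.loc[b["endpoint"] == ep, "fold_change"])

    def test_zero_cell_wells_excluded(self):
        df = _quant_df([
            {"is_vehicle": True, "concentration": 0.0, "n_droplets": 100},
            {"is_vehicle": True, "concentration": 0.0, "n_droplets": 100},
            {"n_cells": 0, "n_droplets": 500},
        ])
        out = compute_endpoint_table(df)
        assert (~out["is_vehicle"]).sum() == 0

    def test_plate_without_vehicle_raises(self):
        with pytest.raises(ValueError, match="vehicle"):
            compute_endpoint_table(_quant_df([{"n_droplets": 10}]))


class TestHitThreshold:
    def _series(self, values_by_conc):
        rows = [{"concentration": c, "fold_change": v}
                for c, vals in values_by_conc.items() for v in vals]
        return pd.DataFrame(rows)

    def test_degenerate_anchors_give_zero_width(self):
        s = self._series({1.0: [1.0, 1.0], 2.0: [1.0, 1.0], 10.0: [5.0]})
        assert compute_hit_threshold(s) == (1.0, 1.0)

    def test_band_arithmetic(self):
        # anchor wells engineered to mean 1.0, SD exactly 0.05
        s = self._series({1.0: [0.95, 1.05], 2.0: [0.95, 1.05],
                          100.0: [2.0, 2.0]})
        sd = np.std([0.95, 1.05, 0.95, 1.05], ddof=1)
        lo, hi = compute_hit_threshold(s)
        assert lo == pytest.approx(1 - 2 * sd)
        assert hi == pytest.approx(1 + 2 * sd)

    def test_insufficient_anchor_wells_raise(self):
        with pytest.raises(ValueError):
            compute_hit_threshold(self._series({1.0: [1.0], 2.0: [1.0, 1.1]}))

    def test_null_false_hit_rate(self, oa_pa_profile):
        """Flat truth + Gaussian noise: curve-crossing false hits are rare."""
        flat = ChemicalProfile(
            "null", {"lipid_accumulation": CurveParams(-1.0, 1.0, 1.0, 100.0)},
            oa_pa_profile.tested_concentrations)
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            wells, _ = generate_plate_dataset(
                [flat], experiments=1, seed=rng)
            norm = normalize_plate_wells(wells)
            s = norm.rename(columns={"lipid_accumulation": "fold_change"})
            thr = compute_hit_threshold(s)
            fit = fit_dose_response(s)
            concs = s.loc[s["concentration"] > 0, "concentration"]
            if call_hit(fit, thr, (concs.min(), concs.max())).hit:
                hits += 1
        assert hits / n_sim <= 0.10


class TestLogLogisticFit:
    def test_noiseless_parameter_identity(self):
        x = np.concatenate([[0.0] * 4, np.repeat(np.geomspace(1, 1000, 8), 3)])
        y = log_logistic(x, -1.2, 1.0, 2.0, 50.0)
        fit = fit_dose_response(
            pd.DataFrame({"concentration": x, "fold_change": y}))
        assert fit.b == pytest.approx(-1.2, abs=1e-3)
        assert fit.d == pytest.approx(2.0, abs=1e-3)
        assert fit.e == pytest.approx(50.0, rel=1e-3)

    def test_grid_search_oracle_agreement(self):
        # independent coarse grid + local polish over (b, d, log e), c = 1
        rng = np.random.default_rng(8)
        x = np.repeat(np.geomspace(1, 1000, 8), 6)
        y = log_logistic(x, -1.0, 1.0, 1.8, 80.0) + rng.normal(0, 0.03, x.size)
        df = pd.DataFrame({"concentration": x, "fold_change": y})
        fit = fit_dose_response(df)

        bs = np.linspace(-4, -0.2, 25)
        ds = np.linspace(1.2, 2.4, 25)
        es = np.geomspace(5, 2000, 40)
        best = (np.inf, None)
        for b in bs:
            for d in ds:
                for e in es:
                    sse = float(np.sum(
                        (log_logistic(x, b, 1.0, d, e) - y) ** 2))
                    if sse < best[0]:
                        best = (sse, (b, d, e))
        _, (b, d, e) = best
        assert fit.d == pytest.approx(d, abs=0.1)
        assert fit.e == pytest.approx(e, rel=0.3)
        # our optimizer should do at least as well as the grid
        ours = float(np.sum((fit.predict(x) - y) ** 2))
        assert ours <= best[0] * (1 + 1e-6)

    def test_flat_truth_prefers_three_parameters(self):
        rng = np.random.default_rng(3)
        x = np.repeat(np.geomspace(1, 1000, 8), 6)
        prefer3 = 0
        n_sim = 100
        for _ in range(n_sim):
            y = 1.0 + rng.normal(0, 0.05, x.size)
            fit = fit_dose_response(
                pd.DataFrame({"concentration": x, "fold_change": y}))
            prefer3 += fit.n_params == 3
        assert prefer3 / n_sim >= 0.90

    def test_too_few_concentrations_raise(self):
        df = pd.DataFrame({"concentration": [1, 10, 100] * 3,
                           "fold_change": [1.0] * 9})
        with pytest.raises(ValueError):
            fit_dose_response(df)


class TestCallHit:
    def _fit(self, b, c, d, e):
        from steatox.endpoints import LogLogisticFit
        return LogLogisticFit(4, b, c, d, e, 0.0, 0.05, True, 10)

    def test_flat_curve_no_hit(self):
        call = call_hit(self._fit(-1, 1.0, 1.0, 100), (0.9, 1.1), (1, 1000))
        assert not call.hit and call.direction == "none"

    def test_strong_increase(self):
        call = call_hit(self._fit(-1, 1.0, 2.3, 100), (0.9, 1.1), (1, 1000))
        assert call.hit and call.direction == "increase"
        assert 1 <= call.lowest_exceeding_concentration <= 1000

    def test_decrease_only_at_top_dose(self):
        # shallow decline crossing the band just below the top dose
        fit = self._fit(3.0, 0.7, 1.0, 4000.0)
        call = call_hit(fit, (0.9, 1.1), (5.0, 5000.0))
        assert call.hit and call.direction == "decrease"
        assert call.lowest_exceeding_concentration > 1000.0

    def test_monotone_in_effect_size(self, oa_pa_profile):
        """Raising the top asymptote never flips a hit back to non-hit."""
        hits = []
        for d in (1.05, 1.2, 1.5, 2.0, 2.5):
            prof = ChemicalProfile(
                "c", {"lipid_accumulation": CurveParams(-1.0, 1.0, d, 100.0)},
                oa_pa_profile.tested_concentrations)
            wells, _ = generate_plate_dataset([prof], seed=12)
            s = normalize_plate_wells(wells).rename(
                columns={"lipid_accumulation": "fold_change"})
            thr = compute_hit_threshold(s)
            fit = fit_dose_response(s)
            hits.append(call_hit(fit, thr, (1.0, 1000.0)).hit)
        # once hitting starts it must persist for larger effects
        assert hits == sorted(hits)
        assert hits[-1]


class TestEC50:
    def _viability(self, ec50, noise, rng, top=10000.0):
        x = np.repeat(np.geomspace(1, top, 8), 6)
        y = log_logistic(x, 2.0, 0.0, 100.0, ec50)
        y = y + rng.normal(0, noise * 100.0, x.size)
        return pd.DataFrame({"concentration": x, "fold_change": y})

    def test_recovery_within_fifteen_percent(self):
        rng = np.random.default_rng(5)
        res = fit_ec50(self._viability(100.0, 0.05, rng))
        assert not res.censored
        assert res.ec50 == pytest.approx(100.0, rel=0.15)

    def test_no_decline_is_right_censored(self):
        rng = np.random.default_rng(6)
        x = np.repeat(np.geomspace(1, 1000, 8), 3)
        y = 100.0 + rng.normal(0, 2.0, x.size)
        res = fit_ec50(pd.DataFrame({"concentration": x, "fold_change": y}))
        assert res.censored and res.ec50 is None

    def test_full_kill_lower_asymptote(self):
        rng = np.random.default_rng(7)
        res = fit_ec50(self._viability(50.0, 0.02, rng))
        assert res.fit.plateau == pytest.approx(0.0, abs=5.0)


class TestEvaluateCalls:
    def _calls(self, counts):
        rows = []
        for ep, (expected, observed) in counts.items():
            for i, (e, o) in enumerate(zip(expected, observed)):
                rows.append({"chemical": f"{ep}_{i}", "endpoint": ep,
                             "expected": e, "observed": o})
        df = pd.DataFrame(rows)
        exp = df.rename(columns={"expected": "hit"})[
            ["chemical", "endpoint", "hit"]]
        obs = df.rename(columns={"observed": "hit"})[
            ["chemical", "endpoint", "hit"]]
        return exp, obs

    def test_perfect_agreement(self):
        exp, obs = self._calls({"a": ([1, 0, 1], [1, 0, 1])})
        m = evaluate_calls(exp, obs)
        assert m["overall"]["sensitivity_pct"] == 100.0
        assert m["overall"]["specificity_pct"] == 100.0

    def test_all_negative_observed(self):
        exp, obs = self._calls({"a": ([1, 1, 0], [0, 0, 0])})
        assert evaluate_calls(exp, obs)["overall"]["sensitivity_pct"] == 0.0
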