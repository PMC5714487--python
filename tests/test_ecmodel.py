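"""Environmental covariates, QTL-EC model, prediction and evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beanqtl import ecmodel, simdata


def constant_weather(site="C", lat=10.0, sowing=1, tmin=16.0, tmax=28.0, srad=18.0, n=160):
    p = simdata.SiteProfile(
        site, latitude=lat, sowing_doy=sowing, n_days=n, tmin_mean=tmin,
        tmax_mean=tmax, temp_amplitude=0.0, temp_noise_sd=0.0,
        srad_mean=srad, srad_sd=0.0,
    )
    return simdata.simulate_site_weather(p, 0)


class TestDayLength:
    def test_equator_always_near_12(self):
        for doy in (1, 80, 172, 265, 355):
            assert ecmodel.day_length(0.0, doy) == pytest.approx(12.0, abs=0.1)

    def test_high_latitude_solstice(self):
        assert ecmodel.day_length(47.0, 172) == pytest.approx(15.7, abs=0.4)

    @given(st.floats(-60, 60))
    @settings(derandomize=True, max_examples=40)
    def test_equinox_near_12_everywhere(self, lat):
        assert ecmodel.day_length(lat, 80) == pytest.approx(12.0, abs=0.2)

    def test_latitude_validation(self):
        with pytest.raises(ValueError):
            ecmodel.day_length(91.0, 100)


class TestEcComputation:
    def test_constant_weather_gives_constants(self):
        w = constant_weather()
        ecs = ecmodel.compute_line_ecs(w, 50)
        assert ecs["Tmin"].iloc[0] == pytest.approx(16.0)
        assert ecs["Tmax"].iloc[0] == pytest.approx(28.0)
        assert ecs["Srad"].iloc[0] == pytest.approx(18.0)
        assert ecs["DAY"].iloc[0] + ecs["NIGHT"].iloc[0] == pytest.approx(24.0)
        assert ecs["Tmin"].iloc[0] <= ecs["Tavg"].iloc[0] <= ecs["Tmax"].iloc[0]

    def test_linear_ramp_averages_to_midpoint(self):
        w = constant_weather()
        w.tmax = np.linspace(20, 30, w.n_days)
        w.tmin = w.tmax - 10
        ecs = ecmodel.compute_line_ecs(w, w.n_days)
        assert ecs["Tmax"].iloc[0] == pytest.approx(25.0, abs=0.05)

    def test_window_beyond_coverage_rejected(self):
        w = constant_weather(n=120)
        with pytest.raises(ValueError, match="coverage"):
            ecmodel.compute_line_ecs(w, 121)

    def test_determinism(self):
        w = constant_weather()
        a = ecmodel.compute_line_ecs(w, 45)
        b = ecmodel.compute_line_ecs(w, 45)
        pd.testing.assert_frame_equal(a, b)


class TestSpearmanScreen:
    def _table(self, n=300, seed=0):
        """Paper-like correlation structure: four quasi-independent drivers
        plus the derived temperature covariates."""
        rng = np.random.default_rng(seed)
        day = rng.normal(12.5, 1.2, n)
        srad = rng.normal(18, 2.5, n)
        tmin = rng.normal(16, 2.5, n)
        tmax = tmin * 0.3 + rng.normal(20, 2.2, n)  # mild coupling, rho < 0.5
        return pd.DataFrame(
            {
                "DAY": day, "NIGHT": 24 - day, "Srad": srad, "Tmin": tmin,
                "Tavg": (tmin + tmax) / 2, "Tmax": tmax,
                "DTavg": 0.75 * tmax + 0.25 * tmin,
                "NTavg": 0.25 * tmax + 0.75 * tmin,
            }
        )

    def test_paper_like_structure_selects_the_four(self):
        sel, rho = ecmodel.spearman_screen(self._table())
        assert sel == ["DAY", "Srad", "Tmin", "Tmax"]

    def test_day_night_complement_admits_one(self):
        sel, _ = ecmodel.spearman_screen(self._table())
        assert "NIGHT" not in sel

    def test_independent_ecs_all_admitted(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(size=(200, 4)), columns=["DAY", "Srad", "Tmin", "Tmax"])
        sel, _ = ecmodel.spearman_screen(t)
        assert sel == ["DAY", "Srad", "Tmin", "Tmax"]

    def test_constant_column_excluded(self):
        t = self._table()
        t["Srad"] = 18.0
        with pytest.warns(UserWarning, match="constant"):
            sel, _ = ecmodel.spearman_screen(t)
        assert "Srad" not in sel


def _toy_model():
    return ecmodel.QtlEcModel(
        intercept=44.18,
        centering={"DAY": 12.37, "Tmin": 16.128},
        ec_main={"DAY": 4.03, "Tmin": -0.61},
        qtl_main={"m1": -2.28, "m2": 1.0},
        qtl_ec={("m1", "Tmin"): -0.25},
        epistasis={("m1", "m2"): -0.4},
    )


class TestPrediction:
    def test_zero_ec_model_converges_immediately(self):
        model = _toy_model()
        model.ec_main = {}
        model.qtl_ec = {}
        w = constant_weather()
        tf, it = ecmodel.predict_tf(model, {"m1": 1.0, "m2": -1.0}, w)
        assert it <= 2
        assert tf == pytest.approx(44.18 - 2.28 - 1.0 + 0.4, abs=1e-6)

    def test_constant_weather_fixed_point_is_closed_form(self):
        model = _toy_model()
        w = constant_weather(lat=0.0, tmin=18.0)
        tf, _ = ecmodel.predict_tf(model, {"m1": -1.0, "m2": -1.0}, w)
        ecs = ecmodel.compute_line_ecs(w, 45)
        dos = pd.DataFrame({"m1": [-1.0], "m2": [-1.0]})
        assert tf == pytest.approx(float(model.linear_predictor(ecs, dos)[0]), abs=0.2)

    def test_linear_in_each_dosage_at_fixed_window(self):
        model = _toy_model()
        w = constant_weather(lat=0.0)
        ecs = ecmodel.compute_line_ecs(w, 45)
        f = lambda x: float(
            model.linear_predictor(ecs, pd.DataFrame({"m1": [x], "m2": [0.0]}))[0]
        )
        slope1 = f(1.0) - f(0.0)
        slope2 = f(0.0) - f(-1.0)
        assert slope1 == pytest.approx(slope2, abs=1e-10)

    def test_day_coefficient_propagates_exactly_under_constant_weather(self):
        model = _toy_model()
        model.qtl_main = {}; model.qtl_ec = {}; model.epistasis = {}
        model.ec_main = {"DAY": 4.03}
        model.centering = {"DAY": 12.37}
        wa = constant_weather(lat=0.0)  # 12.0 h all year
        tfa, _ = ecmodel.predict_tf(model, {}, wa)
        assert tfa == pytest.approx(44.18 + 4.03 * (12.0 - 12.37), abs=0.05)

    def test_monotone_weather_converges(self):
        model = _toy_model()
        w = constant_weather(lat=29.65, sowing=90)  # day length drifts upward
        tf, it = ecmodel.predict_tf(model, {"m1": 1.0, "m2": 1.0}, w)
        assert 1 <= it <= 25
        assert 20 < tf < 120

    def test_serialization_round_trip(self, tmp_path):
        model = _toy_model()
        path = tmp_path / "model.json"
        model.save(path)
        back = ecmodel.QtlEcModel.load(path)
        w = constant_weather(lat=5.0)
        for code in (-1.0, 1.0):
            a, _ = ecmodel.predict_tf(model, {"m1": code, "m2": -code}, w)
            b, _ = ecmodel.predict_tf(back, {"m1": code, "m2": -code}, w)
            assert a == pytest.approx(b, abs=1e-10)


class TestEvaluation:
    def test_perfect_predictions(self):
        r = ecmodel.evaluate_predictions([1, 2, 3, 4], [1, 2, 3, 4], 1)
        assert r.rmse == 0.0 and r.adj_r2 == 1.0

    def test_constant_offset_preserves_r2(self):
        obs = np.array([1.0, 2.0, 3.0])
        r = ecmodel.evaluate_predictions(obs, obs + 1.0, 1)
        assert r.rmse == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            ecmodel.evaluate_predictions([1.0, 2.0], [1.0, 2.0], 1)


class TestQtlEcFit:
    def test_fit_recovers_generative_coefficients(self, paper_records, paper_truth):
        truth, qtab = paper_truth
        records, _ = paper_records
        model = ecmodel.fit_qtl_ec_model(
            records,
            qtab["marker"].tolist(),
            qtab.loc[qtab["interacts"], "marker"].tolist(),
            epistatic_pairs=list(truth.epistasis),
            selected_ecs=["DAY", "Srad", "Tmin", "Tmax"],
            centering=truth.centering,
        )
        for e, b in truth.ec_main.items():
            est, se = model.ec_main[e], model.se[f"c_{e}"]
            assert abs(est - b) < 3 * se, (e, est, b, se)

    def test_single_site_rejected(self, paper_records, paper_truth):
        records, _ = paper_records
        _, qtab = paper_truth
        one = records[records["site"] == records["site"].iloc[0]]
        with pytest.raises(ValueError):
            ecmodel.fit_qtl_ec_model(one, qtab["marker"].tolist(), [])

    def test_null_interactions_rejected_near_alpha(self):
        # QTL with no EC dependence: its interaction terms retained at ~alpha
        rng = np.random.default_rng(11)
        nl = 150
        kept = 0
        total = 0
        for rep in range(8):
            x = rng.choice([-1.0, 1.0], nl)
            rows = []
            for s in range(3):
                day = 12 + s + rng.normal(0, 0.1, nl)
                rows.append(
                    pd.DataFrame(
                        {
                            "line": [f"l{i}" for i in range(nl)], "site": f"S{s}",
                            "tf": 40 + 2 * x + rng.normal(0, 1, nl),
                            "DAY": day, "Srad": rng.normal(18, 1, nl),
                            "Tmin": rng.normal(16, 1, nl), "Tmax": rng.normal(28, 1, nl),
                            "m1": x,
                        }
                    )
                )
            records = pd.concat(rows, ignore_index=True)
            model = ecmodel.fit_qtl_ec_model(
                records, ["m1"], ["m1"], selected_ecs=["DAY", "Srad", "Tmin", "Tmax"]
            )
            kept += len(model.qtl_ec)
            total += 4
        assert kept / total < 0.20  # ~ alpha=0.05 with MC slack


class TestLoso:
    def test_self_consistent_data_predicts_held_out_site(self, paper_map):
        """Noise-free data generated by the model itself: held-out RMSE ~ 0."""
        geno = simdata.simulate_ril_genotypes(paper_map, 120, 55)
        truth, qtab = simdata.default_truth_model(paper_map, residual_sd=1e-6, line_sd=1e-6)
        weather = {
            p.site: simdata.simulate_site_weather(p, 600 + i)
            for i, p in enumerate(simdata.default_site_profiles()[:3])
        }
        records, _ = simdata.simulate_line_site_tf(truth, geno, weather, 56)
        records = records[records["converged"]].reset_index(drop=True)
        reports = ecmodel.loso_cv(
            records, weather, qtab["marker"].tolist(),
            qtab.loc[qtab["interacts"], "marker"].tolist(),
            epistatic_pairs=list(truth.epistasis),
            selected_ecs=["DAY", "Srad", "Tmin", "Tmax"],
        )
        best = min(r.rmse for r in reports.values())
        assert best < 1.0

    def test_extrapolation_flagged(self, paper_records, paper_truth, paper_weather):
        records, _ = paper_records
        truth, qtab = paper_truth
        with pytest.warns(UserWarning, match="extrapolation"):
            reports = ecmodel.loso_cv(
                records, paper_weather, qtab["marker"].tolist(),
                qtab.loc[qtab["interacts"], "marker"].tolist(),
                epistatic_pairs=list(truth.epistasis),
                selected_ecs=["DAY", "Srad", "Tmin", "Tmax"],
            )
        # the long-day site is the canonical extrapolative hold-out
        assert reports["ND"].extrapolated_ecs
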