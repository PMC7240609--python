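"""VIF screening, stepwise regression, F-test p-values, report consistency."""

import numpy as np
import pandas as pd
import pytest

from steppescan.models import (
    build_candidate_design,
    f_test_p,
    per_scale_models,
    significance_stars,
    stepwise_lm,
    vif,
    vif_filter,
)


def brute_force_vif(design: pd.DataFrame) -> dict:
    """Oracle: per-predictor R^2 via numpy least squares."""
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = (resid**2).sum()
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1 - 1e-12 else 1 / (1 - r2)
    return out


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 16
        t = np.arange(n)
        design = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        v = vif(design)
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_duplicated_predictor_reported_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        design = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=20)})
        v = vif(design)
        assert np.isinf(v["a"]) and np.isinf(v["b"])
        assert np.isfinite(v["c"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=30)
        design = pd.DataFrame(
            {
                "a": z + rng.normal(scale=0.5, size=30),
                "b": z + rng.normal(scale=0.5, size=30),
                "c": rng.normal(size=30),
            }
        )
        got = vif(design)
        expected = brute_force_vif(design)
        for name in design.columns:
            assert got[name] == pytest.approx(expected[name], abs=1e-10)


class TestVifFilter:
    def test_identity_when_all_below_threshold(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        kept, report = vif_filter(design)
        assert report.exclusion_order == []
        assert list(kept.columns) == list("abcd")

    def test_redundant_predictor_dropped(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        design = pd.DataFrame({"a": a, "b": b, "dup": a + rng.normal(scale=0.01, size=40)})
        kept, report = vif_filter(design)
        assert "dup" in report.exclusion_order or "a" in report.exclusion_order
        assert (vif(kept) < 10).all()

    def test_exclusion_order_replayable(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=50)
        design = pd.DataFrame(
            {
                "p1": z + rng.normal(scale=0.05, size=50),
                "p2": z + rng.normal(scale=0.05, size=50),
                "p3": z + rng.normal(scale=0.05, size=50),
                "q": rng.normal(size=50),
            }
        )
        _, report = vif_filter(design)
        # replay: dropping in the recorded order reproduces the retained set
        cols = list(design.columns)
        for name in report.exclusion_order:
            cols.remove(name)
        assert cols == report.retained
        assert (report.final_vif < report.threshold).all()


class TestFTest:
    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [(8.406, 1, 13, 0.012), (11.59, 1, 13, 0.005)],
    )
    def test_reference_values(self, F, df1, df2, expected):
        assert f_test_p(F, df1, df2) == pytest.approx(expected, abs=5e-4)

    def test_large_f_below_reporting_floor(self):
        assert f_test_p(20.92, 2, 12) < 0.001

    def test_zero_statistic_gives_p_one(self):
        assert f_test_p(0.0, 3, 10) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            f_test_p(-1.0, 1, 10)


class TestStepwise:
    def make_problem(self, seed, n=45, snr=4.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=["true", "d1", "d2", "d3", "d4", "d5"]
        )
        y = 3.0 * X["true"].to_numpy() * snr / 4.0 + rng.normal(size=n)
        return X, y

    def test_recovers_single_active_predictor(self):
        # the active predictor must always survive; AIC is liberal enough to
        # admit an occasional decoy, so only bound their average count
        true_hits, decoys = 0, []
        for seed in range(10):
            X, y = self.make_problem(seed)
            report = stepwise_lm(y, X)
            names = [t["name"] for t in report.terms]
            true_hits += "true" in names
            decoys.append(len([n for n in names if n != "true"]))
        assert true_hits == 10
        assert np.mean(decoys) <= 1.5

    def test_pure_noise_rarely_builds_big_models(self):
        rng = np.random.default_rng(99)
        sizes = []
        for seed in range(10):
            X = pd.DataFrame(
                np.random.default_rng(seed).normal(size=(40, 5)), columns=list("abcde")
            )
            y = rng.normal(size=40)
            report = stepwise_lm(y, X)
            sizes.append(len(report.terms))
        assert np.mean(sizes) < 2

    def test_single_predictor_f_equals_r2_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        design = pd.DataFrame({"x": x})
        report = stepwise_lm(y, design)
        assert report.df1 == 1
        expected_f = report.r2 / (1 - report.r2) * report.df2
        assert report.f_statistic == pytest.approx(expected_f, rel=1e-10)

    def test_report_p_consistent_with_f(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        report = stepwise_lm(y, pd.DataFrame({"x": x}))
        assert report.p == pytest.approx(f_test_p(report.f_statistic, report.df1, report.df2))
        assert report.df2 == report.n - report.df1 - 1
        assert 0 <= report.r2 <= 1

    def test_intercept_only_flagged(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=8)})
        y = np.full(8, 5.0) + rng.normal(scale=0.01, size=8)
        report = stepwise_lm(y, X)
        if not report.terms:
            assert report.intercept_only
            assert report.r2 == 0.0

    def test_term_formatting_carries_sign_and_scale(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = -5 * x + rng.normal(size=40)
        report = stepwise_lm(y, pd.DataFrame({"MNDWI": x}), scales={"MNDWI": 1500.0})
        assert report.terms[0]["sign"] == "-"
        assert report.formatted_terms()[0].startswith("MNDWI(-) @1500m")


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, "."), (0.5, "")],
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars


class TestPerScaleModels:
    def planted_setup(self, seed=0):
        from steppescan.buffers import extract_cube, make_scale_grid
        from steppescan.indices import DEFAULT_INDICES, compute_index
        from steppescan.synthetic import (
            PlantSpec,
            SceneSpec,
            generate_reflectance_scene,
            generate_sites,
            plant_abundance,
        )

        scene = generate_reflectance_scene(
            SceneSpec(n_rows=160, n_cols=160, origin_y=4800.0, corr_length=300, seed=seed, date="d1")
        )
        sites = generate_sites(
            45, (700, 700, 4100, 4100), min_sep=150, seed=seed + 1, stratum="s"
        )
        scales = make_scale_grid(25, 600, 25)
        plant = PlantSpec("NDVI", 300.0, beta0=60.0, beta1=400.0, sigma=8.0, seed=seed + 2)
        sites = plant_abundance(scene, sites, plant, scales=scales)
        grids = {"d1": {n: compute_index(scene, n) for n in DEFAULT_INDICES}}
        cube = extract_cube(grids, sites, scales)
        return cube, sites

    def test_planted_index_family_recovered_near_planted_scale(self):
        # all six indices share latent fields, so a collinear proxy may stand
        # in for the planted index; the recovered *scale* must be close
        cube, sites = self.planted_setup(seed=21)
        reports = per_scale_models(cube, sites, "s")
        assert len(reports) == 1
        report = reports[0]
        assert report.terms, "model should not be intercept-only"
        scales = [t["scale"] for t in report.terms if t["scale"] is not None]
        assert any(abs(s - 300.0) <= 150.0 for s in scales)

    def test_all_noise_cube_yields_intercept_only(self):
        rng = np.random.default_rng(30)
        rows = []
        for name in ["A", "B"]:
            for r in (100.0, 200.0):
                vals = rng.normal(size=20)
                for i, v in enumerate(vals):
                    rows.append((f"s{i}", name, r, "d1", float(v), 1))
        cube = pd.DataFrame(
            rows, columns=["site_id", "index", "radius_m", "date", "value", "n_pixels"]
        )
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(20)],
                "x": np.arange(20.0),
                "y": np.arange(20.0),
                "stratum": "s",
                "abundance": rng.integers(0, 5, size=20),
            }
        )
        reports = per_scale_models(cube, sites, "s")
        assert len(reports[0].terms) <= 1  # nothing real to find

    def test_explicit_candidate_scales_respected(self):
        cube, sites = self.planted_setup(seed=22)
        from steppescan.scan import correlation_scan

        scan = correlation_scan(cube, sites, "s")
        design, chosen = build_candidate_design(
            cube, scan, sites, "d1", explicit={"NDVI": 150.0}
        )
        assert chosen["NDVI"] == 150.0
        cell = cube[
            (cube["index"] == "NDVI") & (cube["radius_m"] == 150.0) & (cube["date"] == "d1")
        ].set_index("site_id")["value"]
        np.testing.assert_allclose(
            design["NDVI"].to_numpy(), cell.reindex(sites["site_id"]).to_numpy()
        )
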