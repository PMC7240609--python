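"""Correlation scan, pre-screen, variance profiles, Tukey groups, best scale."""

import numpy as np
import pandas as pd
import pytest

from steppescan.scan import (
    best_scale,
    correlation_scan,
    pearson_with_p,
    prescreen_indices,
    tukey_scale_groups,
    variance_profile,
)


def make_cube(values: dict, radii=(100.0,), dates=("d1",)):
    """Tiny long-format cube: values maps index name -> per-site array."""
    n = len(next(iter(values.values())))
    rows = []
    for date in dates:
        for name, arr in values.items():
            for r in radii:
                for i, v in enumerate(np.asarray(arr)):
                    rows.append((f"s{i}", name, r, date, float(v), 1))
    return pd.DataFrame(
        rows, columns=["site_id", "index", "radius_m", "date", "value", "n_pixels"]
    )


def make_sites(abundance, stratum="all"):
    n = len(abundance)
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "x": np.arange(n, dtype=float),
            "y": np.arange(n, dtype=float),
            "stratum": stratum,
            "abundance": abundance,
        }
    )


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(5, dtype=float)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_orthogonal_vectors_give_r_zero_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_t_transform_value(self):
        # r = 0.5 at n = 15 -> t = 0.5*sqrt(13/0.75), p ~ 0.0577
        rng = np.random.default_rng(0)
        # construct x, y with exact sample correlation 0.5
        x = rng.normal(size=15)
        e = rng.normal(size=15)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # residualize
        xs = (x - x.mean()) / x.std()
        es = (e - e.mean()) / e.std()
        y = 0.5 * xs + np.sqrt(1 - 0.25) * es
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        assert p == pytest.approx(0.0577, abs=2e-4)

    def test_matches_permutation_null(self):
        # two-sided t-based p vs permutation distribution of |r|
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r, p = pearson_with_p(x, y)
        n_perm = 20_000
        perm_r = np.empty(n_perm)
        xs = (x - x.mean()) / (x.std() * np.sqrt(len(x)))
        for i in range(n_perm):
            yp = rng.permutation(y)
            perm_r[i] = xs @ ((yp - yp.mean()) / (yp.std() * np.sqrt(len(y))))
        p_perm = (np.abs(perm_r) >= abs(r) - 1e-12).mean()
        assert p == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3)

    @pytest.mark.parametrize("bad", [np.ones(5), np.arange(2)])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            pearson_with_p(bad, np.arange(len(bad), dtype=float))


class TestPrescreen:
    def test_duplicate_of_reference_dropped(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=20)
        cube = make_cube({"NDVI": base, "COPY": base * 2 + 1, "OTHER": rng.normal(size=20)})
        rep = prescreen_indices(cube)
        assert rep.dropped == ["COPY"]
        assert "NDVI" in rep.retained and "OTHER" in rep.retained

    def test_keep_list_overrides_drop(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        near = base + rng.normal(scale=0.05, size=20)  # r > 0.9
        cube = make_cube({"NDVI": base, "TWIN": near})
        rep = prescreen_indices(cube, keep=("TWIN",))
        assert rep.dropped == []
        assert rep.kept_flagged == ["TWIN"]

    def test_reference_never_dropped_and_matrix_matches_oracle(self):
        rng = np.random.default_rng(4)
        data = {name: rng.normal(size=25) for name in ["NDVI", "A", "B", "C"]}
        cube = make_cube(data)
        rep = prescreen_indices(cube)
        assert "NDVI" in rep.retained
        cmat = rep.corr["d1"]
        for a in data:
            for b in data:
                expected = np.corrcoef(data[a], data[b])[0, 1]
                assert cmat.loc[a, b] == pytest.approx(expected, abs=1e-12)


class TestCorrelationScan:
    def test_equals_cell_by_cell_recomputation(self):
        rng = np.random.default_rng(5)
        data = {"NDVI": rng.normal(size=20), "SATVI": rng.normal(size=20)}
        cube = make_cube(data, radii=(100.0, 200.0), dates=("d1", "d2"))
        abundance = rng.integers(0, 100, size=20)
        sites = make_sites(abundance)
        scan = correlation_scan(cube, sites)
        for _, row in scan.iterrows():
            vals = cube[
                (cube["index"] == row["index"])
                & (cube["radius_m"] == row["radius_m"])
                & (cube["date"] == row["date"])
            ].set_index("site_id")["value"]
            x = vals.reindex(sites["site_id"]).to_numpy()
            r, p = pearson_with_p(x, abundance.astype(float))
            assert row["r"] == pytest.approx(r, abs=1e-12)
            assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_invariant_to_affine_abundance_rescaling(self):
        rng = np.random.default_rng(6)
        cube = make_cube({"NDVI": rng.normal(size=15)})
        ab = rng.integers(1, 50, size=15)
        s1 = correlation_scan(cube, make_sites(ab))
        s2 = correlation_scan(cube, make_sites(ab * 7 + 3))
        np.testing.assert_allclose(s1["r"], s2["r"], atol=1e-12)

    def test_single_site_stratum_flagged_undefined(self):
        cube = make_cube({"NDVI": [0.5]})
        scan = correlation_scan(cube, make_sites([10]))
        assert scan["r"].isna().all()
        assert not scan["significant"].any()

    def test_shuffled_abundance_false_positive_rate(self):
        # null calibration, scaled down (full version in the acceptance suite):
        # independent index values per cell, shuffled abundance
        rng = np.random.default_rng(7)
        radii = tuple(np.arange(25.0, 525.0, 25.0))
        rows = []
        for k in range(3):
            for r in radii:
                vals = rng.normal(size=30)
                for i, v in enumerate(vals):
                    rows.append((f"s{i}", f"I{k}", r, "d1", float(v), 1))
        cube = pd.DataFrame(
            rows, columns=["site_id", "index", "radius_m", "date", "value", "n_pixels"]
        )
        sites = make_sites(rng.permutation(np.arange(30)))
        scan = correlation_scan(cube, sites)
        rate = scan["significant"].mean()
        assert 0.01 <= rate <= 0.10  # 60 cells: wide Monte-Carlo band


class TestVarianceProfile:
    def test_constant_field_zero_variance(self):
        cube = make_cube({"NDVI": np.full(10, 0.4)}, radii=(25.0, 50.0))
        prof = variance_profile(cube, make_sites(np.arange(10)))
        assert (prof["variance"] == 0).all()

    def test_per_date_structure(self):
        rng = np.random.default_rng(8)
        cube = make_cube({"NDVI": rng.normal(size=10)}, dates=("d1", "d2"))
        prof = variance_profile(cube, make_sites(np.arange(10)))
        assert set(prof["date"]) == {"d1", "d2"}
        assert len(prof) == 2

    def test_buffer_averaging_shrinks_variance_with_radius(self, small_scene):
        # white-noise-dominated field: across-site variance of the buffer
        # mean decreases with radius
        from steppescan.buffers import extract_cube, make_scale_grid
        from steppescan.indices import compute_index
        from steppescan.synthetic import SceneSpec, generate_reflectance_scene, generate_sites

        scene = generate_reflectance_scene(
            SceneSpec(n_rows=128, n_cols=128, origin_y=3840.0, corr_length=0, seed=12)
        )
        sites = generate_sites(25, (700, 700, 3100, 3100), min_sep=200, seed=13)
        sites["abundance"] = 1
        grid = compute_index(scene, "NDVI")
        cube = extract_cube({"d": {"NDVI": grid}}, sites, make_scale_grid(50, 650, 150))
        prof = variance_profile(cube, sites).sort_values("radius_m")
        v = prof["variance"].to_numpy()
        assert v[-1] < v[0]
        assert (np.diff(v) < 0).mean() >= 0.75  # monotone trend


class TestTukeyGroups:
    def test_single_population_single_group(self):
        rng = np.random.default_rng(9)
        radii = np.repeat([25.0, 50.0, 75.0], 20)
        values = rng.normal(size=60)
        groups = tukey_scale_groups(values, radii)
        assert set(groups.values()) == {"a"}

    def test_widely_separated_means_get_distinct_letters(self):
        rng = np.random.default_rng(10)
        radii = np.repeat([25.0, 50.0], 20)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        groups = tukey_scale_groups(values, radii)
        assert groups[25.0] != groups[50.0]

    def test_labels_invariant_to_input_ordering(self):
        rng = np.random.default_rng(11)
        radii = np.repeat([25.0, 50.0, 75.0], 15)
        values = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0.5, 1, 15), rng.normal(8, 1, 15)]
        )
        g1 = tukey_scale_groups(values, radii)
        perm = rng.permutation(len(values))
        g2 = tukey_scale_groups(values[perm], radii[perm])
        assert g1 == g2


class TestBestScale:
    def scan_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["stratum", "index", "radius_m", "date", "n", "r", "p", "significant"]
        )

    def test_tie_breaks_toward_smaller_radius(self):
        scan = self.scan_frame(
            [
                ("all", "NDVI", 900.0, "d1", 20, 0.8, 0.01, True),
                ("all", "NDVI", 300.0, "d1", 20, -0.8, 0.01, True),
                ("all", "NDVI", 600.0, "d1", 20, 0.5, 0.03, True),
            ]
        )
        bs = best_scale(scan, "NDVI")
        assert bs.radius_m == 300.0

    def test_none_when_nothing_significant(self):
        scan = self.scan_frame([("all", "NDVI", 300.0, "d1", 20, 0.4, 0.2, False)])
        assert best_scale(scan, "NDVI") is None

    def test_picks_max_abs_r_among_significant(self):
        scan = self.scan_frame(
            [
                ("all", "NDVI", 100.0, "d1", 20, 0.6, 0.01, True),
                ("all", "NDVI", 200.0, "d1", 20, -0.9, 0.001, True),
                ("all", "NDVI", 300.0, "d1", 20, 0.95, 0.2, False),
            ]
        )
        bs = best_scale(scan, "NDVI")
        assert bs.radius_m == 200.0 and bs.r == -0.9
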