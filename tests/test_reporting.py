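"""Descriptive rates, Wilson intervals, AOR tables, SRR surfaces, maps."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrrmap import mcmc, reporting
from hrrmap.reporting import crude_rate, wilson_ci


class TestCrudeRate:
    @pytest.mark.parametrize(
        "deaths,n,expected",
        [(285, 6704, 4.25), (0, 100, 0.00), (67, 660, 10.15), (219, 3766, 5.82)],
    )
    def test_examples(self, deaths, n, expected):
        assert crude_rate(deaths, n) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            crude_rate(0, 0)

    def test_deaths_above_n_rejected(self):
        with pytest.raises(ValueError):
            crude_rate(5, 4)


class TestWilson:
    def test_overall_rate_interval(self):
        assert wilson_ci(285, 6704, 0.95) == (3.79, 4.76)

    def test_zero_successes_lower_bound(self):
        lo, hi = wilson_ci(0, 10, 0.95)
        assert lo == 0.00
        assert hi > 0

    def test_matches_score_equation_root_finding(self):
        # oracle: the Wilson bounds are the roots of
        # (p_hat - p)^2 = z^2 p (1 - p) / n
        from scipy.optimize import brentq
        from scipy.stats import norm

        deaths, n = 50, 100
        z = norm.ppf(0.975)
        phat = deaths / n

        def score(p):
            return (phat - p) ** 2 - z**2 * p * (1 - p) / n

        lo = brentq(score, 0, phat)
        hi = brentq(score, phat, 1)
        assert wilson_ci(deaths, n, 0.95) == (round(100 * lo, 2), round(100 * hi, 2))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 200), st.integers(1, 30))
    def test_interval_contains_point_estimate(self, deaths, extra):
        n = deaths + extra
        lo, hi = wilson_ci(deaths, n, 0.95)
        assert lo - 1e-9 <= crude_rate(deaths, n) <= hi + 1e-9

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (50, 200, 800, 3200):
            lo, hi = wilson_ci(int(0.3 * n), n, 0.95)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestDescriptiveTable:
    def test_matches_published_stage_composition(self):
        # cohort rows reconstructed from the printed stage counts
        counts = {"I": 199, "II": 471, "III": 1401, "IV": 3766, "Not stated": 867}
        df = pd.DataFrame(
            {"stage": np.repeat(list(counts), list(counts.values()))}
        )
        out = reporting.descriptive_table(df, ["stage"])
        stage_iv = out[(out.variable == "stage") & (out.category == "IV")].iloc[0]
        assert stage_iv["count"] == 3766
        assert stage_iv["percent"] == 56.18

    def test_single_category_is_hundred_percent(self):
        df = pd.DataFrame({"grp": ["only"] * 7})
        out = reporting.descriptive_table(df, ["grp"])
        assert out.iloc[0]["percent"] == 100.00

    def test_matches_brute_force_tabulation(self, small_registry):
        recs = small_registry.records
        out = reporting.descriptive_table(recs, ["ecog"])
        for _, row in out.iterrows():
            assert row["count"] == (recs["ecog"] == row["category"]).sum()
        assert out["percent"].sum() == pytest.approx(100.0, abs=0.05)


def _manual_samples(fixed, u, v, names):
    """PosteriorSamples assembled by hand for reporting-only tests."""
    D = fixed.shape[0]
    return mcmc.PosteriorSamples(
        fixed=fixed[None],
        u=u[None],
        v=v[None],
        tau2=np.full((1, D, 2), 0.1),
        deviance=np.zeros((1, D)),
        fixed_names=tuple(names),
    )


class TestAorTable:
    def test_null_draws_give_unit_or(self):
        D = 300
        samples = _manual_samples(
            np.zeros((D, 2)), np.zeros((D, 1)), np.zeros((D, 1)), ["mu", "beta:x"]
        )
        row = reporting.aor_table(samples).loc["beta:x"]
        assert row["aor"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_constant_draws_collapse_interval(self):
        D = 200
        fixed = np.column_stack([np.zeros(D), np.full(D, np.log(3.19))])
        samples = _manual_samples(fixed, np.zeros((D, 1)), np.zeros((D, 1)), ["mu", "beta:x"])
        row = reporting.aor_table(samples).loc["beta:x"]
        assert row["aor"] == pytest.approx(3.19, abs=1e-9)
        assert row["lower"] == pytest.approx(3.19, abs=1e-9)
        assert row["significant"]

    def test_fitted_model_flags_strong_effects(self, small_fit):
        out = reporting.aor_table(small_fit)
        assert set(out.index) == set(n for n in small_fit.fixed_names if n != "mu")
        assert (out["lower"] <= out["upper"]).all()


class TestSRRSurface:
    def _cells(self, small_registry, small_cells):
        return small_cells

    def test_null_model_gives_unit_srr(self, small_cells):
        D = 150
        F = small_cells.n_fixed
        J = small_cells.n_areas
        fixed = np.zeros((D, F))
        fixed[:, 0] = -3.0
        samples = _manual_samples(
            fixed, np.zeros((D, J)), np.zeros((D, J)), list(small_cells.param_names)
        )
        surf = reporting.srr_surface(samples, small_cells)
        occupied = ~surf.empty
        assert np.allclose(surf.mean[occupied], 1.0, atol=1e-9)
        assert np.allclose(surf.lower[occupied], 1.0, atol=1e-9)

    def test_raising_one_area_raises_its_srr(self, small_cells):
        D = 150
        F = small_cells.n_fixed
        J = small_cells.n_areas
        fixed = np.zeros((D, F))
        fixed[:, 0] = -3.0
        u = np.zeros((D, J))
        base = reporting.srr_surface(
            _manual_samples(fixed, u, np.zeros((D, J)), list(small_cells.param_names)),
            small_cells,
        )
        u2 = u.copy()
        u2[:, 3] = 0.8
        bumped = reporting.srr_surface(
            _manual_samples(fixed, u2, np.zeros((D, J)), list(small_cells.param_names)),
            small_cells,
        )
        occ = ~base.empty[3]
        assert np.all(bumped.mean[3][occ] > base.mean[3][occ])
        # exceedance of the hot area tops every cold area
        assert bumped.exceedance[3][occ].min() >= bumped.exceedance[0][~bumped.empty[0]].max()

    def test_empty_cells_flagged(self):
        # two areas, two periods, one area-period left empty
        df = pd.DataFrame(
            {
                "patient_id": range(6),
                "area_id": [0, 0, 0, 1, 1, 0],
                "period": [1, 1, 2, 1, 1, 2],
                "age_group": ["le60"] * 6,
                "mdm": ["no"] * 6,
                "scs": ["no"] * 6,
                "stage": ["I"] * 6,
                "comorbidity": ["no"] * 6,
                "ecog": ["good"] * 6,
                "outcome": [0, 1, 0, 0, 0, 1],
            }
        )
        from hrrmap.model import build_cells

        cells = build_cells(df, None, n_areas=2, n_periods=2)
        D = 120
        fixed = np.zeros((D, cells.n_fixed))
        fixed[:, 0] = -1.0
        samples = _manual_samples(
            fixed, np.zeros((D, 2)), np.zeros((D, 2)), list(cells.param_names)
        )
        surf = reporting.srr_surface(samples, cells)
        assert surf.empty[1, 1]  # area 1 has no period-2 patients
        assert np.isnan(surf.mean[1, 1]) and np.isnan(surf.exceedance[1, 1])
        assert not surf.empty[0, 0]


class TestSpatialVarianceFraction:
    def test_pure_structured_is_hundred(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(100, 8))
        samples = _manual_samples(np.zeros((100, 1)), u, np.zeros((100, 8)), ["mu"])
        assert reporting.spatial_variance_fraction(samples) == pytest.approx(100.0)

    def test_pure_unstructured_is_zero(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(100, 8))
        samples = _manual_samples(np.zeros((100, 1)), np.zeros((100, 8)), v, ["mu"])
        assert reporting.spatial_variance_fraction(samples) == pytest.approx(0.0)

    def test_degenerate_fields_rejected(self):
        samples = _manual_samples(np.zeros((100, 1)), np.zeros((100, 4)), np.zeros((100, 4)), ["mu"])
        with pytest.raises(ValueError):
            reporting.spatial_variance_fraction(samples)


class TestChoropleth:
    def _surface(self, J, T):
        rng = np.random.default_rng(3)
        mean = rng.uniform(0.5, 2.0, size=(J, T))
        return reporting.SRRSurface(
            mean=mean,
            lower=mean * 0.8,
            upper=mean * 1.3,
            exceedance=rng.uniform(size=(J, T)),
            empty=np.zeros((J, T), dtype=bool),
        )

    def test_single_area_valid_file(self, tmp_path):
        from shapely.geometry import box

        surf = self._surface(1, 1)
        paths = reporting.choropleth_export(surf, [box(0, 0, 1, 1)], tmp_path)
        obj = json.loads(paths[0].read_text())
        assert obj["type"] == "FeatureCollection"
        assert len(obj["features"]) == 1

    def test_one_file_per_period_with_all_areas(self, tmp_path):
        from hrrmap.synthetic import toy_map

        _, polys = toy_map(79)
        surf = self._surface(79, 3)
        paths = reporting.choropleth_export(surf, polys, tmp_path)
        assert len(paths) == 3
        for p in paths:
            assert len(json.loads(p.read_text())["features"]) == 79

    def test_round_trip_preserves_properties(self, tmp_path):
        from shapely.geometry import box

        surf = self._surface(2, 2)
        paths = reporting.choropleth_export(surf, [box(0, 0, 1, 1), box(1, 0, 2, 1)], tmp_path)
        obj = json.loads(paths[1].read_text())
        props = obj["features"][1]["properties"]
        assert props["srr_mean"] == pytest.approx(surf.mean[1, 1])
        assert props["exceedance"] == pytest.approx(surf.exceedance[1, 1])

    def test_id_mismatch_listed(self, tmp_path):
        from shapely.geometry import box

        surf = self._surface(3, 1)
        with pytest.raises(ValueError, match="missing \\[2\\]"):
            reporting.choropleth_export(surf, [box(0, 0, 1, 1), box(1, 0, 2, 1)], tmp_path)
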