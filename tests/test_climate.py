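"""Species-level exposure/sensitivity/risk against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coastvuln import climate as cl
from coastvuln.config import SyntheticConfig
from coastvuln.grids import ClimateField, SpeciesRange


def _range(prob, habitat="pelagic", species="spX"):
    prob = np.asarray(prob, dtype=float)
    lat = np.arange(prob.shape[0], dtype=float)
    lon = np.arange(prob.shape[1], dtype=float)
    return SpeciesRange(species=species, habitat=habitat, probability=prob,
                        lon=lon, lat=lat)


def _field(values, variable="temperature", layer="surface",
           period="historical", model="M1", mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape[1:], dtype=bool)
    lat = np.arange(values.shape[1], dtype=float)
    lon = np.arange(values.shape[2], dtype=float)
    return ClimateField(variable=variable, layer=layer, period=period,
                        model=model, values=values, mask=mask, lon=lon, lat=lat)


class TestRangeMask:
    def test_inclusive_threshold_boundary(self):
        mask = cl.extract_range_mask(_range([[0.40, 0.39]]), 0.40)
        assert mask.tolist() == [[True, False]]

    def test_uniform_half_probability_covers_grid(self):
        mask = cl.extract_range_mask(_range(np.full((3, 4), 0.5)), 0.4)
        assert mask.all()

    def test_empty_core_range_warns(self):
        with pytest.warns(UserWarning, match="no core range|no cell"):
            mask = cl.extract_range_mask(_range([[0.1, 0.2]]), 0.4)
        assert not mask.any()


class TestSampleNiche:
    def _fields(self, hist_bottom=7.0, n_time=12, shape=(2, 2)):
        out = []
        for layer, base in [("surface", 0.0), ("bottom", hist_bottom)]:
            for period in ("historical", "future"):
                out.append(_field(np.full((n_time, *shape), base),
                                  layer=layer, period=period))
        return out

    def test_benthic_species_reads_bottom_layer(self):
        fields = self._fields(hist_bottom=7.0)
        sp = _range(np.full((2, 2), 0.9), habitat="benthic")
        sample = cl.sample_niche(sp, fields, "M1", "temperature",
                                 np.ones((2, 2), bool))
        assert (sample.historical_values == 7.0).all()

    def test_one_cell_twelve_steps_gives_twelve_values(self):
        fields = self._fields()
        sp = _range([[0.9, 0.1], [0.1, 0.1]])
        sample = cl.sample_niche(sp, fields, "M1", "temperature",
                                 np.ones((2, 2), bool))
        assert sample.historical_values.size == 12
        assert sample.future_values.size == 12

    def test_constant_field_pools_constant_values(self):
        fields = self._fields()
        sp = _range([[0.9, 0.9], [0.9, 0.1]], habitat="benthic")
        sample = cl.sample_niche(sp, fields, "M1", "temperature",
                                 np.ones((2, 2), bool))
        assert sample.historical_values.size == 36
        assert (sample.historical_values == 7.0).all()

    def test_missing_layer_is_named_in_error(self):
        fields = [f for f in self._fields() if f.layer == "surface"]
        sp = _range(np.full((2, 2), 0.9), habitat="benthic")
        with pytest.raises(ValueError, match="bottom"):
            cl.sample_niche(sp, fields, "M1", "temperature", np.ones((2, 2), bool))

    def test_annual_pooling_averages_each_year(self):
        values = np.arange(24, dtype=float).reshape(24, 1, 1)
        fields = [_field(values, period=p) for p in ("historical", "future")]
        sp = _range([[0.9]])
        sample = cl.sample_niche(sp, fields, "M1", "temperature",
                                 np.ones((1, 1), bool), pooling="annual")
        np.testing.assert_allclose(sample.historical_values, [5.5, 17.5])


def _sample(hist, fut):
    return cl.NicheSample("s", "m", "temperature",
                          np.asarray(hist, float), np.asarray(fut, float))


class TestExposure:
    def test_self_overlap_is_ten_percent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        assert cl.compute_exposure(_sample(x, x)) == pytest.approx(10.0, abs=0.2)

    def test_fully_escaped_future_is_hundred(self):
        hist = np.linspace(0, 1, 100)
        fut = np.linspace(2, 3, 50)
        assert cl.compute_exposure(_sample(hist, fut)) == 100.0

    def test_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(123)
        hist = rng.standard_normal(10000)
        fut = hist + 1.0
        got = cl.compute_exposure(_sample(hist, fut))
        # oracle: percentiles by explicit linear interpolation of order
        # statistics, membership by loop count
        s = np.sort(hist)

        def pct(q):
            h = (len(s) - 1) * q / 100.0
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        p5, p95 = pct(5.0), pct(95.0)
        inside = sum(1 for v in fut if p5 <= v <= p95)
        expected = 100.0 - 100.0 * inside / len(fut)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_low_sample_flagged(self):
        with pytest.warns(UserWarning, match="low historical sample"):
            cl.compute_exposure(_sample(np.arange(5.0), np.arange(5.0)))

    def test_empty_future_rejected(self):
        with pytest.raises(ValueError):
            cl.compute_exposure(_sample(np.arange(30.0), []))


class TestSensitivity:
    def test_uniform_breadth_matches_percentile_oracle(self):
        rng = np.random.default_rng(7)
        hist = rng.uniform(0, 10, size=100000)
        got = cl.compute_sensitivity(_sample(hist, hist))
        s = np.sort(hist)

        def pct(q):
            h = (len(s) - 1) * q / 100.0
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[lo + 1] - s[lo])

        expected = 1.0 / (pct(95.0) - pct(5.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1 / 9, rel=0.01)

    def test_doubling_values_halves_sensitivity(self):
        hist = np.random.default_rng(1).normal(size=500)
        s1 = cl.compute_sensitivity(_sample(hist, hist))
        s2 = cl.compute_sensitivity(_sample(2 * hist, hist))
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)

    def test_zero_breadth_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="zero climatic breadth"):
            assert np.isinf(cl.compute_sensitivity(_sample(np.ones(50), np.ones(5))))


class TestTransformAndScale:
    def _frame(self, exposures, sensitivities=None):
        n = len(exposures)
        return pd.DataFrame({
            "species": [f"s{i}" for i in range(n)],
            "model": "M1", "variable": "temperature",
            "raw_exposure": exposures,
            "raw_sensitivity": sensitivities if sensitivities is not None
            else np.ones(n),
        })

    def test_decade_spaced_values_scale_to_halves(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cl.transform_and_scale(self._frame([1.0, 10.0, 100.0]))
        np.testing.assert_allclose(out["scaled_exposure"], [0.0, 0.5, 1.0])

    def test_constant_slice_scales_to_zero(self):
        with pytest.warns(UserWarning, match="degenerate scaling"):
            out = cl.transform_and_scale(self._frame([5.0, 5.0, 5.0]))
        assert (out["scaled_exposure"] == 0).all()

    def test_scaled_ordering_equals_raw_ordering(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0.1, 90, size=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cl.transform_and_scale(self._frame(raw, rng.uniform(0.1, 5, 15)))
        assert (np.argsort(out["scaled_exposure"]) == np.argsort(raw)).all()

    def test_zero_exposure_floored_not_infinite(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant sensitivity column
            out = cl.transform_and_scale(self._frame([0.0, 10.0, 100.0]))
        assert np.isfinite(out["scaled_exposure"]).all()
        assert out["scaled_exposure"].iloc[0] == 0.0

    def test_degenerate_sensitivity_gets_slice_max(self):
        df = self._frame([1.0, 10.0, 100.0], [0.5, np.inf, 2.0])
        out = cl.transform_and_scale(df)
        # inf replaced by the slice's max finite raw sensitivity (2.0 -> scaled 1)
        assert out["scaled_sensitivity"].iloc[1] == out["scaled_sensitivity"].iloc[2]


class TestAverageVariables:
    def _frame(self, values, variables):
        return pd.DataFrame({
            "species": "s1", "model": "M1", "variable": variables,
            "scaled_exposure": values, "scaled_sensitivity": values,
        })

    def test_four_variable_mean(self):
        out = cl.average_variables(self._frame(
            [0.2, 0.4, 0.6, 0.8], ["temperature", "ph", "oxygen", "chlorophyll"]))
        assert out["e_bar"].iloc[0] == pytest.approx(0.5)

    def test_identity_when_equal(self):
        out = cl.average_variables(self._frame(
            [0.3] * 4, ["temperature", "ph", "oxygen", "chlorophyll"]))
        assert out["e_bar"].iloc[0] == pytest.approx(0.3)

    def test_mean_of_available_variables_with_warning(self):
        with pytest.warns(UserWarning, match="missing climate variables"):
            out = cl.average_variables(self._frame(
                [0.1, 0.2, 0.3], ["temperature", "ph", "oxygen"]))
        assert out["e_bar"].iloc[0] == pytest.approx(0.2)


class TestEcologicalRisk:
    def test_species_at_minima_has_zero_risk(self):
        df = pd.DataFrame({"species": ["a", "b"], "model": "M1",
                           "e_bar": [0.0, 0.5], "s_bar": [0.0, 0.5]})
        per_model, _ = cl.ecological_risk(df)
        assert per_model["theta"].iloc[0] == 0.0

    def test_three_four_five_triangle(self):
        df = pd.DataFrame({"species": ["a", "b"], "model": "M1",
                           "e_bar": [0.0, 0.3], "s_bar": [0.0, 0.4]})
        per_model, _ = cl.ecological_risk(df)
        assert per_model["theta"].iloc[1] == pytest.approx(0.5)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "species": np.repeat([f"s{i}" for i in range(10)], 2),
            "model": ["M1", "M2"] * 10,
            "e_bar": rng.uniform(size=20), "s_bar": rng.uniform(size=20)})
        per_model, per_species = cl.ecological_risk(df)
        for model in ("M1", "M2"):
            sub = per_model[per_model["model"] == model]
            min_e, min_s = sub["e_bar"].min(), sub["s_bar"].min()
            for _, row in sub.iterrows():
                expected = ((row["e_bar"] - min_e) ** 2
                            + (row["s_bar"] - min_s) ** 2) ** 0.5
                assert row["theta"] == pytest.approx(expected, rel=1e-12)
        means = per_model.groupby("species")["theta"].mean()
        for _, row in per_species.iterrows():
            assert row["theta_bar"] == pytest.approx(means[row["species"]],
                                                     rel=1e-12)


class TestModelAgreement:
    def _frame(self, thetas):
        n, m = thetas.shape
        return pd.DataFrame({
            "species": np.repeat([f"s{i}" for i in range(n)], m),
            "model": [f"M{j}" for j in range(m)] * n,
            "theta": thetas.ravel()})

    def test_identical_rankings_give_one(self):
        t = np.arange(5, dtype=float)
        mat = cl.model_agreement(self._frame(np.column_stack([t, t])))
        assert mat.loc["M0", "M1"] == pytest.approx(1.0)

    def test_reversed_rankings_give_minus_one(self):
        t = np.arange(5, dtype=float)
        mat = cl.model_agreement(self._frame(np.column_stack([t, t[::-1]])))
        assert mat.loc["M0", "M1"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(17)
        thetas = rng.uniform(size=(8, 3))
        mat = cl.model_agreement(self._frame(thetas))
        for a in range(3):
            for b in range(a + 1, 3):
                ra = stats.rankdata(thetas[:, a])
                rb = stats.rankdata(thetas[:, b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert mat.iloc[a, b] == pytest.approx(expected, rel=1e-9)


def test_monotonicity_exposure_increases_with_shift():
    """Raw exposure of one species never decreases as its shift grows."""
    rng = np.random.default_rng(3)
    hist = rng.normal(size=2000)
    base_future = rng.normal(size=2000)
    exposures = [cl.compute_exposure(_sample(hist, base_future + d))
                 for d in np.linspace(0, 4, 9)]
    assert all(b >= a - 1e-12 for a, b in zip(exposures, exposures[1:]))


def test_build_eco_scores_bounds(small_bundle, small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eco = cl.build_eco_scores(small_bundle.ranges, small_bundle.climate,
                                  ["ESM-A", "ESM-B", "ESM-C"])
    pv = eco.per_variable
    assert pv["scaled_exposure"].between(0, 1).all()
    assert pv["scaled_sensitivity"].between(0, 1).all()
    assert (eco.per_model["theta"] >= 0).all()
    merged = eco.per_model.groupby("species")["theta"].mean()
    for _, row in eco.per_species.iterrows():
        assert row["theta_bar"] == pytest.approx(merged[row["species"]])
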