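"""Synthetic generators: mixture model, traces, evaporation, film scenes."""

import math

import numpy as np
import pytest

from albumag.dls_model import BOLTZMANN_CONSTANT, default_lag_grid
from albumag.errors import ParameterError
from albumag.synthetic import (
    AggregationModel,
    EvaporationParams,
    FilmGeometry,
    ScenarioConfig,
    aggregate_median_diameter_um,
    components_for_concentration,
    evaporation_rate,
    expected_aggregate_count,
    generate_film_image,
    generate_trace,
    mixture_for_concentration,
    spiral_count_model,
    truth_aggregate_mask,
)
from albumag.film import equivalent_diameters_from_mask


class TestMixtureModel:
    def test_zero_magnetite_gives_exactly_base_components(self):
        comps = components_for_concentration(AggregationModel(), 0.0)
        assert [c.label for c in comps] == [
            "albumin_monomer", "albumin_aggregate", "magnetite_particle",
        ]
        assert sum(c.intensity_fraction for c in comps) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "n_mf,expected_nm",
        [(2e-3, 800.0), (1e-1, 250.0), (1e-4, 500.0), (1.0, 1200.0)],
    )
    def test_complex_diameter_at_anchors(self, n_mf, expected_nm):
        comps = components_for_concentration(AggregationModel(), n_mf)
        complex_comp = [c for c in comps if c.label == "albumin_magnetite_complex"]
        assert len(complex_comp) == 1
        assert complex_comp[0].mode_diameter * 1e9 == pytest.approx(expected_nm)

    def test_complex_absent_below_onset(self):
        comps = components_for_concentration(AggregationModel(), 5e-5)
        assert all(c.label != "albumin_magnetite_complex" for c in comps)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ParameterError):
            components_for_concentration(AggregationModel(), -1e-3)
        with pytest.raises(ParameterError):
            mixture_for_concentration(AggregationModel(), -1.0)

    def test_complex_fraction_monotone_and_capped(self):
        model = AggregationModel()
        concs = np.logspace(-4, 0, 30)
        fracs = [model.complex_fraction(c) for c in concs]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert max(fracs) <= model.complex_fraction_cap + 1e-12

    def test_dmax_sign_pattern_over_regimes(self):
        """Dominant-mode diameter rises on 0.1-2 ug/L, falls on 2-100 ug/L,
        rises again above 100 ug/L (the non-monotonic aggregation
        signature)."""
        model = AggregationModel()

        def dominant_diameter(n_mf):
            comps = components_for_concentration(model, n_mf)
            return max(comps, key=lambda c: c.intensity_fraction).mode_diameter

        d = [dominant_diameter(c) for c in (1e-4, 2e-3, 1e-1, 1.0)]
        assert d[1] > d[0]   # rise into the complex-growth regime
        assert d[2] < d[1]   # descending (stabilized) segment
        assert d[3] > d[2]   # destabilized growth above 0.1 mg/L

    def test_rendered_mixture_is_valid_distribution(self):
        dist = mixture_for_concentration(AggregationModel(), 2e-3)
        assert dist.weights.sum() == pytest.approx(1.0)
        assert np.all(dist.weights >= 0)
        # the complex bump peaks near its 800 nm anchor
        peak_nm = dist.diameters_nm[np.argmax(dist.weights * (dist.diameters_nm > 300))]
        assert peak_nm == pytest.approx(800.0, rel=0.1)


class TestTraceGeneration:
    def test_zero_noise_equals_forward_model(self, instrument):
        from albumag.dls_model import forward_field_correlation
        from albumag.synthetic import render_components

        scenario = ScenarioConfig.from_concentration(2e-3, noise_sd=0.0, seed=1)
        lags = default_lag_grid()
        trace = generate_trace(scenario, instrument, lags)
        clean = forward_field_correlation(
            render_components(list(scenario.components)), instrument, lags
        )
        np.testing.assert_array_equal(trace.values, clean.values)

    def test_seed_reproducibility(self, instrument):
        scenario = ScenarioConfig.from_concentration(1e-3, noise_sd=0.02, seed=9)
        lags = default_lag_grid()
        t1 = generate_trace(scenario, instrument, lags)
        t2 = generate_trace(scenario, instrument, lags)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_noise_amplitude_matches_model(self, instrument):
        """Monte-Carlo: per-lag sample sd within 20% of noise_sd * g(tau)."""
        lags = default_lag_grid(30)
        base = ScenarioConfig.from_concentration(0.0, noise_sd=0.0, seed=0)
        from albumag.dls_model import forward_field_correlation
        from albumag.synthetic import render_components

        clean = forward_field_correlation(
            render_components(list(base.components)), instrument, lags
        ).values
        samples = []
        for seed in range(200):
            sc = ScenarioConfig.from_concentration(0.0, noise_sd=0.01, seed=seed)
            samples.append(generate_trace(sc, instrument, lags).values)
        sd = np.std(np.array(samples), axis=0)
        expected = 0.01 * clean
        big = clean > 0.05  # below that, 20% of a tiny sd is sub-float-noise
        np.testing.assert_allclose(sd[big], expected[big], rtol=0.2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            ScenarioConfig.from_concentration(0.0, noise_sd=-0.01)


class TestEvaporation:
    def test_zero_work_is_prefactor_times_sqrt_T(self):
        p = EvaporationParams(temperature=300.0, evaporation_work=0.0, thermal_constant=2.0)
        assert evaporation_rate(p) == pytest.approx(2.0 * math.sqrt(300.0))

    def test_doubling_T_at_zero_work_scales_sqrt2(self):
        p1 = EvaporationParams(temperature=300.0, evaporation_work=0.0)
        p2 = EvaporationParams(temperature=600.0, evaporation_work=0.0)
        assert evaporation_rate(p2) / evaporation_rate(p1) == pytest.approx(math.sqrt(2))

    def test_work_equal_to_kT_gives_factor_e_inverse(self):
        T = 310.0
        p0 = EvaporationParams(temperature=T, evaporation_work=0.0)
        p1 = EvaporationParams(temperature=T, evaporation_work=BOLTZMANN_CONSTANT * T)
        assert evaporation_rate(p1) / evaporation_rate(p0) == pytest.approx(math.exp(-1))

    def test_increasing_in_temperature(self):
        rates = [
            evaporation_rate(EvaporationParams(temperature=T)) for T in (290, 300, 310, 320)
        ]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_invalid_temperature(self):
        with pytest.raises(ParameterError):
            EvaporationParams(temperature=-10.0)


class TestSpiralCountModel:
    def test_reported_counts(self):
        assert spiral_count_model(1e-4) == pytest.approx(155.0)
        assert spiral_count_model(1.0) == pytest.approx(10.0)

    def test_unimodal_over_log_grid(self):
        counts = [spiral_count_model(c) for c in np.logspace(-5, 0, 60)]
        diffs = np.sign(np.diff(counts))
        # one contiguous non-negative run followed by a non-positive run
        switch = np.where(diffs < 0)[0]
        assert switch.size > 0
        first_down = switch[0]
        assert np.all(diffs[:first_down] >= 0)
        assert np.all(diffs[first_down:] <= 0)

    def test_decrease_starts_above_threshold(self):
        assert spiral_count_model(0.04) > spiral_count_model(0.2)
        assert spiral_count_model(1e-4) >= spiral_count_model(5e-2)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            spiral_count_model(-0.1)


class TestFilmScenes:
    def test_fixed_seed_reproducible(self):
        geo = FilmGeometry(256, 256, 0.5)
        img1, truth1 = generate_film_image(1e-4, geo, seed=3, count_scale=0.05)
        img2, truth2 = generate_film_image(1e-4, geo, seed=3, count_scale=0.05)
        np.testing.assert_array_equal(img1, img2)
        assert truth1.to_dict() == truth2.to_dict()

    def test_zero_magnetite_has_no_aggregates(self):
        _, truth = generate_film_image(0.0, FilmGeometry(256, 256, 0.5), seed=1,
                                       count_scale=0.05)
        assert truth.planted_aggregates == []

    def test_truth_bookkeeping(self):
        _, truth = generate_film_image(
            5e-2, FilmGeometry(512, 512, 0.5), seed=2, n_spirals=8, n_aggregates=2
        )
        assert len(truth.planted_spirals) == 8
        assert len(truth.planted_aggregates) == 2
        for s in truth.planted_spirals:
            assert s.turns >= 1.5
            assert 0 < s.growth_rate <= 0.35

    def test_ideal_mask_recovers_planted_blob_diameters(self):
        """Self-consistency: measuring the exact planted mask returns the
        planted equivalent diameters within one pixel-equivalent."""
        geo = FilmGeometry(512, 512, 1.0)
        _, truth = generate_film_image(1.0, geo, seed=4, n_spirals=0, n_aggregates=4)
        mask = truth_aggregate_mask(truth)
        measured = sorted(equivalent_diameters_from_mask(mask, geo.pixel_size_um))
        planted = sorted(a.equivalent_diameter for a in truth.planted_aggregates)
        assert len(measured) == len(planted)
        for m, p in zip(measured, planted):
            assert abs(m - p) <= 2.0 * geo.pixel_size_um  # rasterization slack

    def test_aggregate_scaling_with_concentration(self):
        assert expected_aggregate_count(0.0) == 0.0
        assert expected_aggregate_count(1.0) > expected_aggregate_count(0.01)
        assert aggregate_median_diameter_um(1.0) >= 10.0

    def test_geometry_validation(self):
        with pytest.raises(ParameterError):
            FilmGeometry(128, 512, 0.5)
        with pytest.raises(ParameterError):
            FilmGeometry(512, 512, 0.0)
        with pytest.raises(ParameterError):
            generate_film_image(-1.0, FilmGeometry(256, 256, 0.5), seed=0)
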