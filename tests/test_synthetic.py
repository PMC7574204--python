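"""Synthetic-data generators: determinism, invariants and parameter recovery."""

import math

import numpy as np
import pytest

from scofuel import reference as ref
from scofuel.bioprocess import analyze_timecourse, total_sugars
from scofuel.fame import normalize_profile, profile_from_items
from scofuel.fuelprops import cetane_number
from scofuel.synthetic import (
    FAMESimParams,
    GrowthSimParams,
    ParameterError,
    logistic_biomass,
    logistic_biomass_integral,
    simulate_fame_profile,
    simulate_hydrolysate,
    simulate_screening_table,
    simulate_timecourse,
    write_fixture_tree,
)

TIMES9 = np.linspace(0.0, 120.0, 9)


class TestGrowthSimulation:
    def test_logistic_limit_reaches_carrying_capacity(self):
        params = GrowthSimParams(X0=0.1, K=12.8, mu=0.08, alpha=0.53)
        tc = simulate_timecourse(params, [0.0, 500.0, 1000.0])
        assert tc.dcw[-1] == pytest.approx(12.8, abs=1e-6)

    def test_no_lipid_when_alpha_beta_zero(self):
        params = GrowthSimParams(X0=0.1, K=12.8, mu=0.08, alpha=0.0, beta=0.0)
        tc = simulate_timecourse(params, TIMES9)
        assert np.all(tc.lipid_titre == 0.0)

    def test_endpoint_content_matches_closed_form(self):
        """Noise-free endpoint lipid content equals the closed-form logistic
        evaluation 100·alpha·(X(120)−X0)/X(120), computed independently here."""
        X0, K, mu, alpha = 0.1, 12.8, 0.08, 0.53
        params = GrowthSimParams(X0=X0, K=K, mu=mu, alpha=alpha)
        tc = simulate_timecourse(params, TIMES9)
        x120 = K / (1.0 + ((K - X0) / X0) * math.exp(-mu * 120.0))
        expected = 100.0 * alpha * (x120 - X0) / x120
        kin = analyze_timecourse(tc)
        assert kin.lipid_content == pytest.approx(expected, abs=1e-9)

    def test_noiseless_productivity_recovery_exact(self):
        """Endpoint productivity from a noise-free trajectory matches the
        generator's closed form to 1e-9 for every preset medium."""
        for medium in ("as_psh", "ad_psh", "ynb"):
            params = GrowthSimParams.for_medium(medium)
            tc = simulate_timecourse(params, TIMES9)
            kin = analyze_timecourse(tc)
            assert kin.lipid_productivity == pytest.approx(
                params.expected_endpoint_productivity(120.0), abs=1e-9
            )

    def test_presets_hit_published_endpoints(self):
        for medium, (dcw_end, lipid_end) in ref.BATCH_ENDPOINTS.items():
            tc = simulate_timecourse(GrowthSimParams.for_medium(medium), TIMES9)
            assert tc.dcw[-1] == pytest.approx(dcw_end, abs=1e-9)
            assert tc.lipid_titre[-1] == pytest.approx(lipid_end, abs=1e-9)

    def test_ynb_glucose_rate(self):
        """The YNB preset consumes its 30 g/L glucose at 0.25 g/L/h."""
        tc = simulate_timecourse(GrowthSimParams.for_medium("ynb"), TIMES9)
        kin = analyze_timecourse(tc)
        assert kin.consumption_rates["glucose"] == pytest.approx(0.25, abs=1e-12)

    def test_sugars_sequential_and_exhausted(self):
        params = GrowthSimParams.for_medium("as_psh")
        tc = simulate_timecourse(params, TIMES9)
        # glucose depletes before xylose starts falling; all gone at harvest
        assert tc.sugars["xylose"][0] == pytest.approx(18.13)
        assert tc.sugars["xylose"][1] == pytest.approx(18.13)  # still untouched at 15 h
        for s in tc.sugars.values():
            assert s[-1] == pytest.approx(0.0, abs=1e-9)

    def test_lipid_never_exceeds_dcw(self):
        for seed in range(5):
            params = GrowthSimParams.for_medium("as_psh", noise_sd=0.5, seed=seed)
            tc = simulate_timecourse(params, TIMES9)
            assert np.all(tc.lipid_titre <= tc.dcw + 1e-12)
            assert np.all(tc.dcw >= 0.0)

    def test_seed_determinism(self):
        p = GrowthSimParams.for_medium("as_psh", noise_sd=0.3, seed=42)
        a = simulate_timecourse(p, TIMES9)
        b = simulate_timecourse(p, TIMES9)
        assert np.array_equal(a.dcw, b.dcw) and np.array_equal(a.lipid_titre, b.lipid_titre)

    def test_beta_term_uses_trapezoid_on_grid(self):
        """With beta > 0 the simulated lipid equals alpha-term plus a
        trapezoid integral of the biomass curve on the sampling grid."""
        params = GrowthSimParams(X0=0.1, K=10.0, mu=0.08, alpha=0.2, beta=0.002)
        t = TIMES9
        tc = simulate_timecourse(params, t)
        x = logistic_biomass(t, 0.1, 10.0, 0.08)
        expected = 0.2 * (x - 0.1) + 0.002 * np.concatenate(
            [[0.0], np.cumsum(np.diff(t) * (x[1:] + x[:-1]) / 2.0)]
        )
        np.testing.assert_allclose(tc.lipid_titre, expected, atol=1e-12)
        # and the trapezoid tracks the analytic integral closely on this grid
        analytic = 0.2 * (x[-1] - 0.1) + 0.002 * logistic_biomass_integral(120.0, 0.1, 10.0, 0.08)
        assert tc.lipid_titre[-1] == pytest.approx(float(analytic), rel=5e-3)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            GrowthSimParams(X0=5.0, K=2.0)
        with pytest.raises(ParameterError):
            GrowthSimParams(alpha=2.0, K=10.0, X0=0.1)  # lipid would exceed biomass
        with pytest.raises(ParameterError):
            simulate_timecourse(GrowthSimParams(), [10.0, 20.0])  # must start at 0


class TestFAMESimulation:
    def _mean(self):
        return normalize_profile(profile_from_items("as-psh", ref.AS_PSH_FAME.items()))

    def test_draw_sums_to_100(self):
        prof = simulate_fame_profile(FAMESimParams(self._mean(), seed=1))
        assert prof.total() == pytest.approx(100.0, abs=1e-9)
        assert prof.normalized

    def test_concentration_limit_recovers_mean(self):
        mean = self._mean()
        prof = simulate_fame_profile(FAMESimParams(mean, concentration=1e9, seed=2))
        for sp in mean.species:
            assert prof.get(sp) == pytest.approx(mean.get(sp), abs=0.05)

    def test_requires_normalized_mean(self):
        raw = profile_from_items("raw", ref.AS_PSH_FAME.items())
        with pytest.raises(ParameterError):
            FAMESimParams(raw)

    def test_seed_determinism(self):
        params = FAMESimParams(self._mean(), seed=9)
        a, b = simulate_fame_profile(params), simulate_fame_profile(params)
        assert a.fractions == b.fractions

    def test_mean_cetane_number_tracks_mean_profile(self):
        """Across many draws the mean DU-regression cetane number stays
        within Monte-Carlo error of the mean profile's value."""
        mean = self._mean()
        cn_mean_profile = cetane_number(mean, "du-regression")
        cns = [
            cetane_number(
                simulate_fame_profile(FAMESimParams(mean, concentration=500.0, seed=s)),
                "du-regression",
            )
            for s in range(300)
        ]
        mc_err = 3.0 * np.std(cns) / math.sqrt(len(cns))
        assert np.mean(cns) == pytest.approx(cn_mean_profile, abs=max(mc_err, 0.05))


class TestScreeningSimulation:
    def test_target_r_one_is_noise_free(self):
        from scofuel.screening import rfu_lipid_correlation

        table = simulate_screening_table(57, target_r=1.0, seed=0)
        assert rfu_lipid_correlation(table).r == pytest.approx(1.0, abs=1e-12)

    def test_minimum_strains(self):
        assert len(simulate_screening_table(3, seed=0)) == 3
        with pytest.raises(ParameterError):
            simulate_screening_table(2, seed=0)

    @pytest.mark.parametrize("r", [0.0, -0.5, 1.5])
    def test_unattainable_target_r(self, r):
        with pytest.raises(ParameterError):
            simulate_screening_table(10, target_r=r, seed=0)

    def test_seed_determinism(self):
        a = simulate_screening_table(20, seed=4)
        b = simulate_screening_table(20, seed=4)
        assert all(
            x.rfu_replicates == y.rfu_replicates and x.lipid_titre == y.lipid_titre
            for x, y in zip(a.records, b.records)
        )

    def test_all_values_non_negative(self):
        table = simulate_screening_table(57, target_r=0.7, seed=8)
        for rec in table.records:
            assert all(v >= 0 for v in rec.rfu_replicates)
            assert rec.lipid_titre >= 0


class TestHydrolysateSimulation:
    def test_zero_noise_reproduces_printed_table(self):
        comp, record = simulate_hydrolysate(seed=0, noise_scale=0.0)
        assert comp.analytes["glucose"].before == pytest.approx(28.05)
        assert comp.analytes["calcium"].after == pytest.approx(6.3)
        assert total_sugars(comp) == pytest.approx(46.47)
        assert record.sugars_before_detox == pytest.approx(37.38)
        assert record.detox_loss_percent() == pytest.approx(14.63, abs=0.005)

    def test_noiseless_utilization_matches_reported(self):
        comp, _ = simulate_hydrolysate(seed=0, noise_scale=0.0)
        util = comp.utilization_table()
        assert util["calcium"] == pytest.approx(94.11, abs=0.005)
        assert util["magnesium"] == pytest.approx(85.62, abs=0.005)
        assert util["potassium"] == pytest.approx(75.16, abs=0.005)
        assert util["manganese"] == pytest.approx(35.14, abs=0.005)
        assert util["sodium"] == pytest.approx(22.22, abs=0.005)

    def test_outputs_non_negative_for_any_seed(self):
        for seed in range(10):
            comp, record = simulate_hydrolysate(seed=seed)
            for rec in comp.analytes.values():
                assert rec.before is None or rec.before >= 0
                assert rec.after is None or rec.after >= 0
            assert record.sugars_after_detox <= record.sugars_before_detox

    def test_seed_determinism(self):
        a, _ = simulate_hydrolysate(seed=3)
        b, _ = simulate_hydrolysate(seed=3)
        assert all(
            a.analytes[k].before == b.analytes[k].before for k in a.analytes
        )


class TestFixtureTree:
    def test_tree_contents(self, fixture_tree):
        assert sorted(fixture_tree) == [
            "fame",
            "hydrolysate",
            "screening",
            "timecourse_ad_psh",
            "timecourse_as_psh",
            "timecourse_ynb",
        ]
        for path in fixture_tree.values():
            assert path.exists() and path.stat().st_size > 0
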