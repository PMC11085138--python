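"""Mechanistic simulator: closed forms, conservation laws, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

import phycobatch as pb
from phycobatch.simulate import CultureSpec, depth_averaged_rate


def photo_spec(**kw):
    base = dict(mode="photoautotrophic", I0=500.0, mu_max=0.2, K_I=150.0,
                sigma=100.0, L=0.03, X0=0.02, maintenance=0.0, seed=0)
    base.update(kw)
    return CultureSpec(**base)


class TestDepthAveragedRate:
    def test_matches_quadrature_oracle(self):
        spec = photo_spec()
        for X in np.linspace(0.01, 10.0, 25):
            closed = depth_averaged_rate(X, spec)
            integrand = lambda z: (
                spec.mu_max * spec.I0 * np.exp(-spec.sigma * X * z)
                / (spec.K_I + spec.I0 * np.exp(-spec.sigma * X * z))
            )
            expected = quad(integrand, 0.0, spec.L, epsabs=1e-13, limit=200)[0] / spec.L
            assert closed == pytest.approx(expected, abs=1e-8)

    def test_thin_culture_limit_is_surface_monod(self):
        spec = photo_spec(sigma=1e-6)
        surface = spec.mu_max * spec.I0 / (spec.K_I + spec.I0)
        assert depth_averaged_rate(1.0, spec) == pytest.approx(surface, rel=1e-6)

    def test_monotone_decreasing_in_density(self):
        spec = photo_spec()
        rates = depth_averaged_rate(np.linspace(0.01, 5.0, 50), spec)
        assert np.all(np.diff(rates) < 0)


class TestPhotoautotrophic:
    def test_no_shading_limit_is_pure_exponential(self):
        spec = photo_spec(sigma=1e-9, duration=72.0)
        batch = pb.simulate_photoautotrophic(spec)
        rate = spec.mu_max * spec.I0 / (spec.K_I + spec.I0) - spec.maintenance
        expected = spec.X0 * np.exp(rate * batch.times)
        assert np.max(np.abs(batch.biomass / expected - 1)) < 1e-6

    def test_dense_culture_productivity_plateaus(self):
        spec = pb.load_preset("vmax_reference", seed=0)
        batch = pb.simulate_photoautotrophic(spec)
        # over the last 24 h the volumetric accumulation rate is nearly flat
        rate = np.gradient(batch.biomass, batch.times)
        tail = rate[batch.times >= batch.times[-1] - 24.0]
        assert np.ptp(tail) / np.mean(tail) < 0.05

    def test_reports_initial_rate_and_onset(self, mu_batch):
        assert mu_batch.truth["initial_specific_rate"] == pytest.approx(0.15, abs=1e-9)
        onset = mu_batch.truth["light_limitation_onset"]
        spec = mu_batch.spec
        # at the onset the depth-averaged rate is exactly 95% of its initial value
        i = np.searchsorted(mu_batch.times, onset)
        X_at = np.interp(onset, mu_batch.times, mu_batch.biomass)
        assert depth_averaged_rate(X_at, spec) == pytest.approx(
            0.95 * depth_averaged_rate(spec.X0, spec), rel=1e-3)


class TestHeterotrophic:
    def test_mass_balance_conserved(self):
        spec = pb.load_preset("glucose_endpoint", seed=0)
        batch = pb.simulate_heterotrophic(spec)
        lhs = batch.biomass - spec.X0
        rhs = spec.Y_true * (spec.S0 - batch.substrate.concentration)
        assert np.max(np.abs(lhs - rhs)) < 1e-8

    def test_final_biomass_approaches_stoichiometric_limit(self):
        spec = pb.load_preset("glucose_endpoint", seed=0, X0=0.1)
        batch = pb.simulate_heterotrophic(spec)
        limit = spec.X0 + spec.Y_true * spec.S0
        assert limit == pytest.approx(8.35, rel=1e-9)  # 0.1 + 0.55 * 15
        assert batch.biomass[-1] == pytest.approx(limit, rel=0.01)

    def test_weak_light_and_dark_runs_diverge_after_onset(self):
        spec = pb.load_preset("weak_light_glucose", seed=0)
        dark = pb.simulate_heterotrophic(spec)
        wl = pb.simulate_heterotrophic(CultureSpec(**{**vars(spec), "weak_light": True}))
        before = dark.times < spec.dark_decay_onset
        assert np.allclose(dark.biomass[before], wl.biomass[before], rtol=1e-9)
        assert wl.biomass[-1] > 2.0 * dark.biomass[-1]  # weak light more than doubles OD


class TestSensorModel:
    def test_zero_noise_round_trip(self, fig8_model):
        spec = pb.load_preset("mu_reference", seed=0, noise_sd=0.0)
        batch = pb.simulate_batch(spec)
        for rep in batch.od_sensor:
            back = pb.correct_od(rep.values, spec.calibration)
            assert np.max(np.abs(back - batch.od_corrected.values)) < 1e-9

    def test_identity_calibration_passthrough(self):
        spec = pb.load_preset("mu_reference", seed=0, noise_sd=0.0,
                              calibration=pb.IDENTITY)
        batch = pb.simulate_batch(spec)
        assert np.allclose(batch.od_sensor[0].values, batch.od_corrected.values,
                           atol=1e-12)

    def test_fixed_seed_reproducibility(self):
        b1 = pb.simulate_batch(pb.load_preset("acetate_consumption", seed=9))
        b2 = pb.simulate_batch(pb.load_preset("acetate_consumption", seed=9))
        for r1, r2 in zip(b1.od_sensor, b2.od_sensor):
            assert np.array_equal(r1.values, r2.values)
        for s1, s2 in zip(b1.substrate_replicates, b2.substrate_replicates):
            assert np.array_equal(s1.concentration, s2.concentration)

    def test_replicates_differ_from_each_other(self):
        batch = pb.simulate_batch(pb.load_preset("mu_reference", seed=2))
        assert not np.array_equal(batch.od_sensor[0].values, batch.od_sensor[1].values)


class TestPigmentGenerator:
    def test_unit_multipliers_no_noise_give_base(self):
        eff = pb.PigmentEffects(phase_mult=1.0, substrate_mult=1.0, weaklight_mult=1.0,
                                suppression=1.0, c_min=1.0, c_max=1.0, noise_sd=0.0)
        table = pb.generate_pigment_tables(eff)
        photo = table[table["mode"] == "photoautotrophic"]
        for pigment, base in eff.base.items():
            vals = photo[photo["pigment"] == pigment]["percent_dw"]
            assert np.allclose(vals, base)

    def test_acclimation_decreasing_in_intensity(self):
        eff = pb.PigmentEffects()
        acc = [eff.acclim(I) for I in (0, 100, 300, 700)]
        assert all(b < a for a, b in zip(acc, acc[1:]))


class TestFullPipelineClosure:
    def test_calibration_fit_correction_and_mu_recovery_end_to_end(self):
        """Sensor logs -> fitted calibration -> correction -> segmentation -> mu."""
        spec = pb.load_preset("mu_reference", seed=21)
        batch = pb.simulate_batch(spec)
        pairs = pb.simulate.generate_dilution_pairs(spec)
        model = pb.fit_calibration(pairs, label="closure")
        corr = [pb.correct_od(s.values, model) for s in batch.od_sensor]
        mean = pb.ODTimeSeries(batch.times, np.mean(corr, axis=0), space="corrected")
        seg = pb.segment_phases(mean)
        mu, _ = pb.estimate_mu(mean, seg)
        assert mu == pytest.approx(batch.truth["initial_specific_rate"], rel=0.05)

    def test_yield_recovery_end_to_end(self):
        spec = pb.load_preset("acetate_endpoint", seed=21)
        batch = pb.simulate_batch(spec)
        corr = np.mean([pb.correct_od(s.values, spec.calibration)
                        for s in batch.od_sensor], axis=0)
        x_final = float(np.mean(corr[-9:])) * spec.conversion_k
        est = pb.yield_endpoint(x_final, spec.X0, spec.S0)
        assert est.y == pytest.approx(spec.Y_true, rel=0.10)
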