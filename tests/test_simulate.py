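import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rogredox as rx
from rogredox.errors import ConfigurationError
from rogredox.images import BACKGROUND, CYTOSOL, NUCLEUS, compartment_mask


class TestInvertRatio:
    def test_endpoints(self, calib):
        assert rx.invert_ratio(0.0, calib) == pytest.approx(calib.r_red)
        assert rx.invert_ratio(1.0, calib) == pytest.approx(calib.r_ox)

    def test_derived_example(self, calib):
        """R(OxD=0.6667) ~ 1.1; substituting back gives 0.9/(0.5*0.9+0.9)."""
        r = rx.invert_ratio(0.6667, calib)
        assert r == pytest.approx(1.1, abs=1e-3)
        assert rx.compute_oxd(r, calib) == pytest.approx(0.6667, abs=1e-12)

    @given(oxd=st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=60)
    def test_round_trip_property(self, oxd):
        calib = rx.CalibrationState.from_ratios(0.2, 2.0, 0.5)
        assert rx.compute_oxd(rx.invert_ratio(oxd, calib), calib) == pytest.approx(oxd, abs=1e-12)

    def test_invalid_calibration_rejected(self):
        from rogredox.errors import CalibrationInversionError
        with pytest.raises(CalibrationInversionError):
            rx.CalibrationState.from_ratios(2.0, 0.2, 0.5)
        with pytest.raises(ConfigurationError):
            rx.CalibrationState.from_ratios(0.2, 2.0, 0.0)


class TestImageSets:
    def test_geometry_and_pairing(self, small_config):
        img = rx.generate_image_set(small_config, 0, 0)
        assert img.channel_405.shape == img.channel_488.shape == img.label_mask.shape
        assert compartment_mask(img.label_mask, BACKGROUND).mean() >= 0.01
        ids = set(np.unique(img.label_mask)) - {0}
        for nid in img.cell_ids():
            assert nid % 2 == 1 and nid + 1 in ids  # nucleus pairs with its cytosol ring
        assert np.all(img.channel_405 >= 0) and np.all(img.channel_405 <= img.saturation_cap)

    def test_noiseless_pixels_carry_exact_ratio(self, quiet_config, calib):
        img = rx.generate_image_set(quiet_config, 6, 0)
        truth = quiet_config.oxd_truth("nucleus", 6)
        expected_r = rx.invert_ratio(truth, calib)
        nuc = compartment_mask(img.label_mask, NUCLEUS)
        ratios = img.channel_405[nuc] / img.channel_488[nuc]
        assert ratios == pytest.approx(expected_r, abs=1e-9)

    def test_same_seed_bit_identical(self, small_config):
        a = rx.generate_image_set(small_config, 4, 2)
        b = rx.generate_image_set(small_config, 4, 2)
        assert np.array_equal(a.channel_405, b.channel_405)
        assert np.array_equal(a.channel_488, b.channel_488)
        assert np.array_equal(a.label_mask, b.label_mask)
        c = rx.generate_image_set(small_config, 4, 3)
        assert not np.array_equal(a.channel_405, c.channel_405)

    def test_default_noise_recovery_within_tolerance(self):
        """Mean OxD recovered over 5 replicates stays within 0.015 of truth."""
        cfg = rx.scenario("control", seed=11)
        red, ox = rx.generate_calibration_sets(cfg)
        est = rx.estimate_calibration(red, ox)
        truth = cfg.oxd_truth("nucleus", 12)
        oxds = []
        for r in range(5):
            roi = rx.measure_roi(rx.generate_image_set(cfg, 12, r), NUCLEUS)
            oxds.append(rx.compute_oxd(roi.i405 / roi.i488, est))
        assert abs(np.mean(oxds) - truth) <= 0.015

    def test_tiff_round_trip(self, tmp_path, small_config):
        img = rx.generate_image_set(small_config, 0, 0)
        img.save(tmp_path / "field")
        loaded = rx.ImageSet.load(tmp_path / "field")
        assert np.array_equal(loaded.label_mask, img.label_mask)
        # intensities survive up to uint16 rounding
        assert np.allclose(loaded.channel_488, img.channel_488, atol=0.5)


class TestCalibrationSets:
    def test_noiseless_endpoint_ratios(self, quiet_config, calib):
        red, ox = rx.generate_calibration_sets(quiet_config)
        for img, expected in ((red, calib.r_red), (ox, calib.r_ox)):
            roi = compartment_mask(img.label_mask, NUCLEUS) | compartment_mask(img.label_mask, CYTOSOL)
            ratios = img.channel_405[roi] / img.channel_488[roi]
            assert ratios == pytest.approx(expected, abs=1e-9)

    def test_noisy_k_recovery_within_2pct(self):
        cfg = rx.scenario("control", seed=5)
        red, ox = rx.generate_calibration_sets(cfg)
        est = rx.estimate_calibration(red, ox)
        assert est.k == pytest.approx(cfg.k_instrument, rel=0.02)


class TestFlowEvents:
    def test_counts_match_fractions_exactly(self):
        """Component counts equal requested fractions before any noise."""
        cfg = rx.scenario("control", seed=1)
        tab = rx.generate_flow_events(cfg, 0, n_events=10_000)
        counts = tab.df["true_phase"].value_counts()
        n_main = 10_000 - counts.get("debris", 0)
        for phase, frac in zip(("G1", "S", "G2"), cfg.phase_truth(0)):
            assert abs(counts[phase] - frac * n_main) <= 1
        assert counts.get("debris", 0) == round(cfg.noise.debris_fraction * 10_000)
        assert (tab.df["dna_fl"] > 0).all()

    def test_degenerate_single_peak(self):
        cfg = rx.scenario("control", seed=1, noise=rx.NoiseParams.zero(),
                          truth_phase_fractions={0: (1.0, 0.0, 0.0)})
        tab = rx.generate_flow_events(cfg, 0, n_events=500)
        assert np.all(tab.df["dna_fl"] == cfg.g1_peak_position)

    def test_two_equal_peaks_at_mu_and_2mu(self):
        """(0.5, 0, 0.5) without debris: equal masses within +/-3 CV of each center."""
        cfg = rx.scenario("control", seed=2,
                          noise=rx.NoiseParams(flow_cv=0.05, debris_fraction=0.0),
                          truth_phase_fractions={0: (0.5, 0.0, 0.5)})
        tab = rx.generate_flow_events(cfg, 0, n_events=40_000)
        dna = tab.df["dna_fl"].to_numpy()
        mu = cfg.g1_peak_position
        near_g1 = np.abs(dna - mu) <= 3 * 0.05 * mu
        near_g2 = np.abs(dna - 2 * mu) <= 3 * 0.05 * 2 * mu
        assert near_g1.mean() == pytest.approx(0.5, abs=0.01)
        assert near_g2.mean() == pytest.approx(0.5, abs=0.01)

    def test_noiseless_g2_at_twice_g1(self):
        cfg = rx.scenario("control", seed=3, noise=rx.NoiseParams.zero())
        tab = rx.generate_flow_events(cfg, 0, n_events=1000)
        df = tab.df
        g1 = df.loc[df.true_phase == "G1", "dna_fl"].unique()
        g2 = df.loc[df.true_phase == "G2", "dna_fl"].unique()
        assert len(g1) == len(g2) == 1 and g2[0] == pytest.approx(2 * g1[0])

    def test_determinism_and_csv_round_trip(self, tmp_path):
        cfg = rx.scenario("hc", seed=9)
        a = rx.generate_flow_events(cfg, 24, n_events=2000)
        b = rx.generate_flow_events(cfg, 24, n_events=2000)
        assert a.df.equals(b.df)
        path = a.to_csv(tmp_path / "events.csv")
        loaded = rx.FlowEventTable.from_csv(path)
        assert loaded.n_events == 2000
        assert "true_phase" not in loaded.df.columns  # truth never leaves the generator

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            rx.scenario("control", truth_phase_fractions={0: (0.6, 0.2, 0.1)})


class TestRootLengths:
    def test_zero_noise_exact_increment(self):
        cfg = rx.scenario("control", seed=1, noise=rx.NoiseParams.zero())
        df = rx.generate_root_lengths(cfg, n_seedlings=3).df
        wide = df.pivot(index="seedling_id", columns="time_h", values="length_mm")
        assert np.allclose(wide[24] - wide[0], 1.4)
        assert np.allclose(wide[48] - wide[24], 1.7)

    def test_determinism(self):
        cfg = rx.scenario("hu", seed=4)
        assert rx.generate_root_lengths(cfg).df.equals(rx.generate_root_lengths(cfg).df)

    def test_default_noise_rate_recovery(self):
        cfg = rx.scenario("control", seed=6)
        res = rx.growth_rate(rx.generate_root_lengths(cfg), (0, 24))
        assert res.rate("control") == pytest.approx(1.4, abs=0.1)

    def test_csv_round_trip(self, tmp_path):
        cfg = rx.scenario("hc", seed=2)
        tab = rx.generate_root_lengths(cfg, n_seedlings=5)
        path = tab.to_csv(tmp_path / "roots.csv")
        loaded = rx.RootLengthTable.from_csv(path)
        assert len(loaded.df) == len(tab.df)
        assert loaded.df["length_mm"].to_numpy() == pytest.approx(tab.df["length_mm"].to_numpy())
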