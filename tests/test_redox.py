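import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rogredox as rx
from rogredox.errors import (CalibrationInversionError, InputError,
                             MeasurementError, UndefinedPotentialError)
from rogredox.images import NUCLEUS


def make_image(values_405, values_488, labels, cap=65535):
    return rx.ImageSet(np.asarray(values_405, float), np.asarray(values_488, float),
                       np.asarray(labels), {"saturation_cap": cap})


class TestMeasureRoi:
    def test_constant_image_arithmetic(self):
        """Uniform ROI=100 over background=10 measures 90."""
        labels = np.array([[0, 0, 1], [0, 0, 1], [0, 0, 1]])
        img = make_image(np.where(labels == 1, 100, 10), np.where(labels == 1, 100, 10), labels)
        roi = rx.measure_roi(img, NUCLEUS)
        assert roi.i405 == pytest.approx(90.0)
        assert roi.i488 == pytest.approx(90.0)

    def test_matches_brute_force_pixel_oracle(self, rng):
        labels = rng.choice([0, 1, 2], size=(32, 32), p=[0.5, 0.25, 0.25])
        v405 = rng.uniform(50, 100, (32, 32)) + 400 * (labels > 0)  # ROI above background
        v488 = rng.uniform(50, 100, (32, 32)) + 300 * (labels > 0)
        img = make_image(v405, v488, labels)
        roi = rx.measure_roi(img, NUCLEUS)
        # oracle: plain loops over pixels
        nuc405 = [v405[i, j] for i in range(32) for j in range(32) if labels[i, j] == 1]
        bg405 = [v405[i, j] for i in range(32) for j in range(32) if labels[i, j] == 0]
        assert roi.i405 == pytest.approx(sum(nuc405) / len(nuc405) - sum(bg405) / len(bg405))

    def test_empty_compartment_is_input_error(self):
        labels = np.array([[0, 0], [0, 2]])
        img = make_image(np.ones((2, 2)), np.ones((2, 2)), labels)
        with pytest.raises(InputError):
            rx.measure_roi(img, NUCLEUS)

    def test_saturated_pixels_excluded_and_counted(self):
        labels = np.array([[0, 1, 1, 1]])
        v = np.array([[10.0, 100.0, 200.0, 65535.0]])
        img = make_image(v, v, labels)
        roi = rx.measure_roi(img, NUCLEUS)
        assert roi.n_saturated == 1
        assert roi.i405 == pytest.approx(150.0 - 10.0)

    def test_all_saturated_is_measurement_error(self):
        labels = np.array([[0, 1]])
        v = np.array([[10.0, 65535.0]])
        with pytest.raises(MeasurementError):
            rx.measure_roi(make_image(v, v, labels), NUCLEUS)


class TestEstimateCalibration:
    def test_noiseless_recovery_to_1e9(self, quiet_config, calib):
        red, ox = rx.generate_calibration_sets(quiet_config)
        est = rx.estimate_calibration(red, ox)
        assert est.r_red == pytest.approx(calib.r_red, abs=1e-9)
        assert est.r_ox == pytest.approx(calib.r_ox, abs=1e-9)
        assert est.k == pytest.approx(calib.k, abs=1e-9)

    def test_swapped_inputs_raise_inversion_error(self, quiet_config):
        red, ox = rx.generate_calibration_sets(quiet_config)
        with pytest.raises(CalibrationInversionError):
            rx.estimate_calibration(ox, red)

    def test_noisy_endpoints_within_2pct(self):
        cfg = rx.scenario("control", seed=13)
        red, ox = rx.generate_calibration_sets(cfg)
        est = rx.estimate_calibration(red, ox)
        assert est.r_red == pytest.approx(cfg.r_red, rel=0.02)
        assert est.r_ox == pytest.approx(cfg.r_ox, rel=0.02)


class TestComputeOxd:
    def test_boundary_identities(self, calib):
        assert rx.compute_oxd(calib.r_red, calib) == 0.0
        assert rx.compute_oxd(calib.r_ox, calib) == 1.0

    def test_hand_derived_value(self, calib):
        # 0.9 / (0.5 * 0.9 + 0.9)
        assert rx.compute_oxd(1.1, calib) == pytest.approx(0.6667, abs=1e-4)

    def test_strictly_increasing_in_ratio(self, calib):
        r = np.linspace(calib.r_red, calib.r_ox, 200)
        oxd = rx.compute_oxd(r, calib)
        assert np.all(np.diff(oxd) > 0)

    def test_out_of_range_ratio_clamped_with_warning(self, calib):
        with pytest.warns(UserWarning, match="clamped"):
            assert rx.compute_oxd(2.5, calib) == 1.0
        with pytest.warns(UserWarning):
            assert rx.compute_oxd(0.1, calib) == 0.0


class TestNernst:
    def test_rt_over_zf_constant(self, constants):
        assert constants.rt_zf_mV == pytest.approx(12.848, abs=0.01)

    def test_midpoint_at_half_oxidation(self, constants):
        assert rx.compute_e_probe(0.5, constants) == pytest.approx(constants.e0_probe_mV)

    def test_probe_potential_derived_value(self, constants):
        # -280 - 12.848 * ln(0.6878 / 0.3122)
        assert rx.compute_e_probe(0.3122, constants) == pytest.approx(-290.1, abs=0.1)

    def test_gsh_unit_argument_gives_midpoint(self, constants):
        # choose OxD so that 2 * GSH_tot * (1 - OxD)^2 / OxD = 1
        g = constants.gsh_total_M
        oxd = (1 + 4 * g - np.sqrt(1 + 8 * g)) / (4 * g)
        assert rx.compute_e_gsh(oxd, constants) == pytest.approx(constants.e0_gsh_mV, abs=1e-6)

    def test_gsh_potential_derived_value(self, constants):
        # -240 - 12.848 * ln(2 * 2.5e-3 * 0.6878^2 / 0.3122) = -240 - 12.848*ln(7.5765e-3)
        assert rx.compute_e_gsh(0.3122, constants) == pytest.approx(-177.3, abs=0.1)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_boundary_oxd_is_undefined(self, constants, bad):
        with pytest.raises(UndefinedPotentialError):
            rx.compute_e_probe(bad, constants)
        with pytest.raises(UndefinedPotentialError):
            rx.compute_e_gsh(bad, constants)

    @given(oxd=st.floats(0.01, 0.49))
    @settings(deadline=None, max_examples=40)
    def test_log_odds_antisymmetry(self, oxd):
        """E(OxD) - E0 is antisymmetric about OxD = 0.5."""
        c = rx.NernstConstants()
        lo = rx.compute_e_probe(oxd, c) - c.e0_probe_mV
        hi = rx.compute_e_probe(1.0 - oxd, c) - c.e0_probe_mV
        assert lo == pytest.approx(-hi, abs=1e-9)

    def test_probe_potential_increasing_in_oxd(self, constants):
        oxd = np.linspace(0.01, 0.99, 99)
        e = [rx.compute_e_probe(x, constants) for x in oxd]
        assert np.all(np.diff(e) > 0)


class TestTimecourse:
    def test_single_noiseless_replicate(self, quiet_config, calib):
        cfg = quiet_config
        img = rx.generate_image_set(cfg, 0, 0)
        summary = rx.run_redox_timecourse([img], calib, rx.NernstConstants())
        oxd_pct = summary.grand_mean("nucleus", "oxd_pct")
        assert oxd_pct == pytest.approx(100 * cfg.oxd_truth("nucleus", 0), abs=1e-6)
        row = summary.summary[(summary.summary.compartment == "nucleus")]
        assert row["oxd_sem_pct"].iloc[0] == 0.0  # single replicate: SEM flagged as 0
        assert row["n"].iloc[0] == 1

    def test_noiseless_end_to_end_round_trip(self, quiet_config):
        """Generator -> calibration -> ROI -> OxD recovers truth to 1e-9."""
        cfg = quiet_config
        red, ox = rx.generate_calibration_sets(cfg)
        est = rx.estimate_calibration(red, ox)
        sets = [rx.generate_image_set(cfg, t, 0) for t in (0, 8, 16, 24)]
        summary = rx.run_redox_timecourse(sets, est)
        for comp in ("nucleus", "cytosol"):
            truth = np.mean([cfg.oxd_truth(comp, t) for t in (0, 8, 16, 24)])
            assert summary.grand_mean(comp, "oxd_pct") == pytest.approx(100 * truth, abs=1e-7)

    def test_averaging_order_is_per_replicate_then_mean(self, calib):
        """E is computed per replicate before averaging (the Jensen gap is real)."""
        constants = rx.NernstConstants()
        labels = np.zeros((8, 8), int)
        labels[2:5, 2:5] = 1
        labels[1, 1] = 2
        sets = []
        for i, oxd in enumerate((0.2, 0.4)):
            r = rx.invert_ratio(oxd, calib)
            v488 = np.where(labels > 0, 1000.0, 0.0)
            sets.append(rx.ImageSet(r * v488, v488, labels,
                                    {"timepoint_h": 0, "replicate": i}))
        summary = rx.run_redox_timecourse(sets, calib, constants)
        expected = np.mean([rx.compute_e_probe(x, constants) for x in (0.2, 0.4)])
        jensen_wrong = rx.compute_e_probe(0.3, constants)
        got = summary.grand_mean("nucleus", "e_probe_mV")
        assert got == pytest.approx(expected, abs=1e-6)
        assert abs(got - jensen_wrong) > 0.5  # the two orders genuinely differ

    def test_missing_metadata_rejected(self, quiet_config, calib):
        img = rx.generate_image_set(quiet_config, 0, 0)
        img.metadata.pop("timepoint_h")
        with pytest.raises(InputError):
            rx.run_redox_timecourse([img], calib)
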