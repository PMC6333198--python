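"""Calibration coefficients: quotient propagation, batch adjustment, decay."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osldose.calibration import (
    Co60Source,
    VendorStandardSet,
    calibrate_ct_air,
    calibrate_vendor,
    decay_corrected_dose,
    derive_coefficient,
    vendor_batch_adjustment,
)
from osldose.signal import CorrectedSignal
from osldose.synthetic import simulate_calibration_session
from osldose.uncertainty import UncertainQuantity


class TestDeriveCoefficient:
    def test_exact_ratio(self):
        nd = derive_coefficient(
            UncertainQuantity(45.0, 0.0), CorrectedSignal(45000.0, 0.0)
        )
        assert nd.value == pytest.approx(0.001)
        assert nd.variance == 0.0

    @pytest.mark.parametrize(
        "dose_rel,signal_rel,expected",
        [(0.9, 1.3, 1.6), (5.0, 1.3, 5.2)],
    )
    def test_component_combination(self, dose_rel, signal_rel, expected):
        dose = UncertainQuantity.from_relative(30.0, dose_rel, "D")
        sigma = 30000.0 * signal_rel / 200.0
        nd = derive_coefficient(dose, CorrectedSignal(30000.0, sigma * sigma))
        assert round(nd.rel_two_sigma_pct, 1) == expected

    @given(c=st.floats(0.1, 10.0))
    def test_homogeneous_in_dose(self, c):
        signal = CorrectedSignal(1e4, 1e4)
        base = derive_coefficient(UncertainQuantity(10.0, 0.01), signal)
        scaled = derive_coefficient(UncertainQuantity(10.0 * c, 0.01 * c * c), signal)
        assert scaled.value == pytest.approx(c * base.value, rel=1e-9)
        assert scaled.variance == pytest.approx(c * c * base.variance, rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            derive_coefficient(UncertainQuantity(0.0), CorrectedSignal(1.0))


class TestVendorProtocol:
    def test_published_batch_means(self):
        v = VendorStandardSet(
            (3.0, 20.0),
            (CorrectedSignal(3000.0), CorrectedSignal(20000.0)),
            calibration_batch_mean_sensitivity=0.85,
            experimental_batch_mean_sensitivity=0.93,
        )
        assert round(vendor_batch_adjustment(v), 3) == 1.094

    @pytest.mark.parametrize("cal,exp,expected", [(0.9, 0.9, 1.0), (0.5, 1.0, 2.0)])
    def test_adjustment_ratios(self, cal, exp, expected):
        v = VendorStandardSet((3.0,), (CorrectedSignal(1.0),), cal, exp)
        assert vendor_batch_adjustment(v) == pytest.approx(expected)

    def test_exact_levels_recover_slope(self):
        # signals exactly on a line through the origin, equal batch means
        nd_true = 0.0005
        v = VendorStandardSet(
            (3.0, 20.0),
            (CorrectedSignal(3.0 / nd_true), CorrectedSignal(20.0 / nd_true)),
            1.0,
            1.0,
        )
        nd = calibrate_vendor(v, dose_rel_2sigma_pct=0.0)
        assert nd.value == pytest.approx(nd_true, rel=1e-12)
        assert nd.protocol == "vendor"

    def test_batch_rescaling_invariance(self):
        # scaling all calibration signals by the batch-sensitivity ratio and
        # declaring that batch mean leaves the adjusted coefficient unchanged
        nd_true = 0.0005
        base = VendorStandardSet(
            (3.0, 20.0),
            (CorrectedSignal(3.0 / nd_true), CorrectedSignal(20.0 / nd_true)),
            0.93,
            0.93,
        )
        ratio = 0.93 / 0.85
        rescaled = VendorStandardSet(
            (3.0, 20.0),
            (
                CorrectedSignal(ratio * 3.0 / nd_true),
                CorrectedSignal(ratio * 20.0 / nd_true),
            ),
            0.85,
            0.93,
        )
        a = calibrate_vendor(base)
        b = calibrate_vendor(rescaled)
        assert b.value == pytest.approx(a.value, rel=1e-12)

    def test_noisy_levels_recovered_within_interval(self):
        rng = np.random.default_rng(21)
        nd_true = 0.0005
        hits = 0
        for _ in range(100):
            sig = [
                CorrectedSignal(
                    float(d / nd_true * rng.normal(1.0, 0.0065)),
                    (d / nd_true * 0.0065) ** 2,
                )
                for d in (3.0, 20.0)
            ]
            v = VendorStandardSet((3.0, 20.0), tuple(sig), 1.0, 1.0)
            nd = calibrate_vendor(v, dose_rel_2sigma_pct=0.0)
            hits += abs(nd.value - nd_true) <= 2 * math.sqrt(nd.variance)
        assert hits >= 90

    def test_per_level_mode(self):
        v = VendorStandardSet(
            (0.0, 3.0, 20.0),
            (CorrectedSignal(10.0), CorrectedSignal(3000.0), CorrectedSignal(20000.0)),
            1.0,
            1.0,
        )
        out = calibrate_vendor(v, per_level=True)
        assert len(out) == 2  # the zero level carries no slope information
        assert out[0].value == pytest.approx(0.001)

    def test_all_zero_doses_rejected(self):
        v = VendorStandardSet((0.0,), (CorrectedSignal(10.0),), 1.0, 1.0)
        with pytest.raises(ValueError):
            calibrate_vendor(v)


class TestCtAirProtocol:
    def test_single_pair_ratio(self):
        nd = calibrate_ct_air(
            [CorrectedSignal(30000.0)], [UncertainQuantity(30.0, 0.0)]
        )
        assert nd.value == pytest.approx(0.001)
        assert nd.protocol == "ct_air"

    def test_uncertainty_dominated_by_dose_term(self):
        sig = CorrectedSignal(30000.0, (30000.0 * 1.3 / 200) ** 2)
        doses = [UncertainQuantity.from_relative(30.0, 5.0) for _ in range(3)]
        nd = calibrate_ct_air([sig], doses)
        assert 5.0 < nd.rel_two_sigma_pct < 5.4

    def test_simulated_session_recovery(self, truth):
        sess = simulate_calibration_session(truth, "ct_air", seed=5)
        nd = sess.recover()
        assert abs(nd.value - sess.truth_nd) <= 2 * math.sqrt(nd.variance)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ct_air([], [UncertainQuantity(1.0)])


class TestCo60Protocol:
    SRC = Co60Source(45.0, dt.date(2018, 1, 1))

    def test_no_elapsed_time(self):
        d = decay_corrected_dose(self.SRC, dt.date(2018, 1, 1), 1.0,
                                 dose_rel_2sigma_pct=0.0)
        assert d.expected == pytest.approx(45.0)

    def test_one_half_life_halves_dose(self):
        later = dt.date(2018, 1, 1) + dt.timedelta(days=1925.28)
        d = decay_corrected_dose(self.SRC, later, 1.0)
        assert d.expected == pytest.approx(45.0 * 2 ** -(1925 / 1925.28), rel=1e-9)
        exact = decay_corrected_dose(
            Co60Source(45.0, dt.date(2018, 1, 1), half_life_days=1925.0),
            dt.date(2018, 1, 1) + dt.timedelta(days=1925),
            1.0,
        )
        assert exact.expected == pytest.approx(22.5)

    def test_default_reference_uncertainty(self):
        d = decay_corrected_dose(self.SRC, dt.date(2018, 6, 1), 1.0)
        assert d.rel_two_sigma_pct == pytest.approx(0.9)

    def test_irradiation_before_reference_rejected(self):
        with pytest.raises(ValueError):
            decay_corrected_dose(self.SRC, dt.date(2017, 12, 31), 1.0)

    def test_noise_free_exact_recovery(self, truth_noise_free):
        sess = simulate_calibration_session(truth_noise_free, "megavoltage", seed=1)
        nd = sess.recover()
        assert nd.value == pytest.approx(sess.truth_nd, rel=1e-12)

    def test_propagated_coefficient_spread(self, truth):
        # 4 dosimeters x 3 reads with 0.9% dose uncertainty: near 1.6% total
        sess = simulate_calibration_session(truth, "megavoltage", seed=8)
        nd = sess.recover()
        assert 0.9 < nd.rel_two_sigma_pct < 2.2


class TestCrossProtocolConsistency:
    def test_protocol_chains_agree_on_common_truth(self, truth):
        """All three calibrations of the same simulated system, each applied
        with its matching correction chain, give doses agreeing within the
        propagated uncertainties."""
        from osldose.dose import compute_dose
        from osldose.factors import CorrectionFactorSet
        from osldose.synthetic import simulate_study

        study = simulate_study(truth, seed=17)
        doses = {}
        for p in ("vendor", "ct_air", "megavoltage"):
            nd = simulate_calibration_session(truth, p, seed=29).recover()
            cid = 5
            fs = CorrectionFactorSet(
                k_l=UncertainQuantity(1.0),
                k_f=UncertainQuantity(1.0),
                k_g=UncertainQuantity(truth.k_g[p]),
                k_theta=UncertainQuantity(1.0),
                k_q=UncertainQuantity.from_relative(truth.true_kq[(p, cid)], 2.0),
                protocol=p,
            )
            doses[p] = compute_dose(study.pooled_signal(cid), nd, fs)
        for a in doses.values():
            for b in doses.values():
                gap = abs(a.dose_mGy - b.dose_mGy)
                assert gap <= 2 * math.sqrt(a.variance + b.variance)
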