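"""Unit and property tests for the compartment equations and rate laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourccr import (
    CompartmentState,
    FatigueParameters,
    controller_drive,
    derivatives,
    fatigue_coefficients,
    load_parameters,
    recovery_coefficients,
)
from fourccr.core_model import RateCoefficients, compartment_derivatives

from conftest import random_state


@pytest.mark.parametrize(
    "TL,MA,MR,L,expected",
    [
        (1.0, 0.0, 1.0, 20.0, 20.0),    # fully rested step-on
        (0.0, 0.3, 0.5, 20.0, -6.0),    # deactivation when demand drops
        (0.5, 0.5, 0.2, 20.0, 0.0),     # demand exactly met
        (1.0, 0.2, 0.1, 20.0, 2.0),     # rest-limited recruitment
    ],
)
def test_controller_drive_examples(TL, MA, MR, L, expected):
    assert controller_drive(TL, MA, MR, L) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("bad", [{"TL": -0.1}, {"TL": 1.5}, {"L": 0.0}, {"L": -3.0}])
def test_controller_drive_rejects_malformed_input(bad):
    kwargs = {"TL": 0.5, "MA": 0.1, "MR": 0.5, "L": 20.0, **bad}
    with pytest.raises(ValueError):
        controller_drive(**kwargs)


class TestFatigueCoefficients:
    def test_isometric_limit_is_purely_central(self, sf_params):
        FP, FC = fatigue_coefficients(0.0, sf_params)
        assert FP == 0.0
        assert FC == sf_params.FC0

    def test_high_velocity_limit_is_purely_peripheral(self, sf_params):
        FP, FC = fatigue_coefficients(1e6, sf_params)
        assert FP == pytest.approx(sf_params.FP0, rel=1e-12)
        assert FC == pytest.approx(0.0, abs=1e-12)

    def test_exponential_half_point(self):
        # at V = ln2/k both rates sit exactly halfway
        params = FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.002, RP0=1e-5,
                                   r=10, k=0.0233)
        V = math.log(2) / 0.0233
        FP, FC = fatigue_coefficients(V, params)
        assert FP == pytest.approx(params.FP0 / 2, rel=1e-12)
        assert FC == pytest.approx(params.FC0 / 2, rel=1e-12)

    def test_negative_velocity_rejected(self, sf_params):
        with pytest.raises(ValueError):
            fatigue_coefficients(-1.0, sf_params)

    @given(v1=st.floats(0, 500), v2=st.floats(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_velocity(self, v1, v2):
        """FP never decreases and FC never increases with velocity."""
        params = FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.002, RP0=1e-5,
                                   r=10, k=0.02)
        lo, hi = sorted((v1, v2))
        fp_lo, fc_lo = fatigue_coefficients(lo, params)
        fp_hi, fc_hi = fatigue_coefficients(hi, params)
        assert fp_hi >= fp_lo
        assert fc_hi <= fc_lo


class TestRecoveryCoefficients:
    def test_rest_multiplier_applies_at_zero_load(self):
        params = FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.02, RP0=1.2e-5, r=7.5)
        RP, RC = recovery_coefficients(0.0, params)
        assert RC == pytest.approx(0.15)
        assert RP == 1.2e-5

    def test_loaded_condition_uses_baseline(self):
        params = FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.02, RP0=1.2e-5, r=7.5)
        _, RC = recovery_coefficients(0.4, params)
        assert RC == pytest.approx(0.02)

    def test_peripheral_recovery_is_constant(self, sf_params):
        for tl in (0.0, 0.3, 1.0):
            RP, _ = recovery_coefficients(tl, sf_params)
            assert RP == sf_params.RP0

    def test_branch_flip_switch(self):
        # sensitivity switch: multiplier on the loaded branch instead
        params = FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.02, RP0=1e-5,
                                   r=7.5, rest_multiplier_at_rest=False)
        assert recovery_coefficients(0.0, params)[1] == pytest.approx(0.02)
        assert recovery_coefficients(0.4, params)[1] == pytest.approx(0.15)


class TestDerivatives:
    def test_hand_evaluated_flow_balance(self):
        state = CompartmentState(MA=0.5, MR=0.3, MFP=0.1, MFC=0.1)
        rates = RateCoefficients(FP=0.01, FC=0.005, RP=1e-5, RC=0.02)
        d = compartment_derivatives(state, rates, C=2.0)
        assert d == pytest.approx((1.9925, -1.997999, 0.004999, 0.0005), abs=1e-12)

    def test_rested_unloaded_state_is_stationary(self, sf_params):
        d = derivatives(CompartmentState(0.0, 1.0, 0.0, 0.0), 0.0, 0.0, sf_params)
        assert d == (0.0, 0.0, 0.0, 0.0)

    def test_pool_conserved_on_randomized_inputs(self, sf_params):
        """The four derivatives cancel term-by-term: the total pool is
        conserved to floating-point rounding of the largest flow."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            state = random_state(rng)
            TL = rng.uniform(0, 1)
            V = rng.uniform(0, 200)
            d = derivatives(state, TL, V, sf_params)
            tol = max(1e-15, 4 * np.spacing(max(abs(x) for x in d)))
            assert abs(sum(d)) <= tol

    @given(
        tl=st.floats(0, 1), ma=st.floats(0, 1), mr=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_controller_sign_convention(self, tl, ma, mr):
        """Positive drive needs unmet demand and available rest; drive is
        never positive once the active pool covers the target."""
        C = controller_drive(tl, ma, mr, 20.0)
        if C > 0:
            assert tl > ma and mr > 0
        if tl <= ma:
            assert C <= 0


class TestTypesAndLoader:
    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            CompartmentState(MA=0.5, MR=0.6, MFP=0.0, MFC=0.0)  # sum 1.1
        with pytest.raises(ValueError):
            CompartmentState(MA=-0.1, MR=1.1, MFP=0.0, MFC=0.0)

    def test_negative_k_stored_as_magnitude(self):
        params = FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.002, RP0=1e-5,
                                   r=10, k=-0.0233)
        assert params.k == 0.0233

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            FatigueParameters(FC0=-0.01, FP0=0.02, RC0=0.002, RP0=1e-5)
        with pytest.raises(ValueError):
            FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.002, RP0=1e-5, r=0.5)
        with pytest.warns(UserWarning):
            FatigueParameters(FC0=0.01, FP0=0.02, RC0=0.002, RP0=1e-5, r=10, L=5)

    def test_loader_computes_fp0_from_ratio(self, tmp_path):
        cfg = tmp_path / "params.json"
        cfg.write_text(
            '{"muscle_group": "shoulder_flexors", "FC0": 0.01, "RC0": 0.002,'
            ' "r": 15, "L": 20, "k": -0.0086, "RP0": 1.2e-5,'
            ' "FP0_over_RP0": 1211, "provenance": "fitted table"}'
        )
        params = load_parameters(cfg)
        assert params.FP0 == pytest.approx(1211 * 1.2e-5)
        assert params.k == 0.0086
        assert params.muscle_group == "shoulder_flexors"

    def test_loader_requires_a_peripheral_rate(self):
        with pytest.raises(KeyError):
            load_parameters({"FC0": 0.01, "RC0": 0.002, "RP0": 1e-5})
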