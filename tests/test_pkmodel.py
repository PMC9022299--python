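"""Unit tests for the two-compartment infusion kinetics."""

import math

import numpy as np
import pytest

from levsim.pkmodel import (
    IndividualParameters,
    Regimen,
    derive_disposition,
    ode_oracle,
    steady_state_concentration,
    steady_state_trough,
    time_course,
    time_to_target,
    typical_clearance,
    typical_clearance_power_only,
)


class TestTypicalClearance:
    @pytest.mark.parametrize(
        "crcl, expected",
        [
            (0.0, 3.5),                 # power term vanishes, non-renal component only
            (120.0, 4.5),               # 3.5 + 1**2.5
            (240.0, 3.5 + 2.0**2.5),    # ~9.157 L/h
        ],
    )
    def test_values(self, crcl, expected, pop):
        assert typical_clearance(crcl, pop) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self, pop):
        grid = np.linspace(0, 300, 50)
        cl = typical_clearance(grid, pop)
        assert np.all(np.diff(cl) > 0)

    def test_negative_crcl_rejected(self, pop):
        with pytest.raises(ValueError):
            typical_clearance(-1.0, pop)

    def test_power_only_reading(self, pop):
        # the rejected literal reading drops the non-renal component entirely
        assert typical_clearance_power_only(120.0, pop) == pytest.approx(1.0)
        assert typical_clearance_power_only(240.0, pop) == pytest.approx(2.0**2.5)


class TestDisposition:
    def test_rate_constant_identities(self):
        ind = IndividualParameters(cl=4.5, v1=20.7, q=31.9, v2=33.5)
        d = derive_disposition(ind)
        assert d.k10 == pytest.approx(4.5 / 20.7, rel=1e-12)
        assert d.k12 == pytest.approx(31.9 / 20.7, rel=1e-12)
        assert d.k21 == pytest.approx(31.9 / 33.5, rel=1e-12)
        assert d.lambda1 + d.lambda2 == pytest.approx(d.k10 + d.k12 + d.k21, rel=1e-10)
        assert d.lambda1 * d.lambda2 == pytest.approx(d.k10 * d.k21, rel=1e-10)
        assert d.lambda1 > d.lambda2 > 0

    def test_large_peripheral_volume_limit(self):
        # v2 -> infinity with q fixed: k21 -> 0, slow exponential -> 0
        ind = IndividualParameters(cl=4.5, v1=20.7, q=31.9, v2=1e9)
        d = derive_disposition(ind)
        assert d.k21 < 1e-7
        assert d.lambda2 < 1e-7

    def test_ordering_over_random_parameters(self):
        rng = np.random.default_rng(12345)
        for _ in range(50):
            cl, v1, q, v2 = rng.uniform(0.5, 80, 4)
            d = derive_disposition(IndividualParameters(cl=cl, v1=v1, q=q, v2=v2))
            assert d.lambda1 > d.lambda2 > 0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            IndividualParameters(cl=0.0, v1=20.7, q=31.9, v2=33.5)


class TestSteadyState:
    def test_continuous_infusion_plateau(self):
        ind = IndividualParameters(cl=4.5, v1=20.7, q=31.9, v2=33.5)
        reg = Regimen(dose_mg=3000, tau_h=24, tinf_h=24)
        for t in (0.0, 3.7, 12.0, 23.99):
            assert steady_state_concentration(ind, reg, t) == pytest.approx(
                125.0 / 4.5, rel=1e-9
            )

    def test_continuous_trough_equals_rate_over_cl(self, typical_subject):
        ind = typical_subject(240.0)
        reg = Regimen(dose_mg=4500, tau_h=24, tinf_h=24)
        assert steady_state_trough(ind, reg) == pytest.approx(
            187.5 / ind.cl, rel=1e-9
        )
        assert 187.5 / ind.cl == pytest.approx(20.48, abs=0.005)

    def test_continuity_at_end_of_infusion(self, typical_subject):
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1500, tau_h=12, tinf_h=4)
        eps = 1e-9
        left = steady_state_concentration(ind, reg, 4.0 - eps)
        right = steady_state_concentration(ind, reg, 4.0 + eps)
        assert left == pytest.approx(right, rel=1e-6)

    def test_dose_homogeneity(self, typical_subject):
        ind = typical_subject(200.0)
        lo = Regimen(dose_mg=1000, tau_h=8, tinf_h=4)
        hi = Regimen(dose_mg=2000, tau_h=8, tinf_h=4)
        for t in (1.0, 4.0, 7.9):
            assert steady_state_concentration(ind, hi, t) == pytest.approx(
                2.0 * steady_state_concentration(ind, lo, t), rel=1e-12
            )

    def test_zero_dose(self, typical_subject):
        assert steady_state_trough(typical_subject(160.0), Regimen(0.0, 12, 0.5)) == 0.0

    def test_time_outside_interval_rejected(self, typical_subject):
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1500, tau_h=12, tinf_h=0.5)
        for t in (-0.1, 12.0, 15.0):
            with pytest.raises(ValueError):
                steady_state_concentration(ind, reg, t)

    def test_trough_matches_ode_oracle(self, typical_subject):
        # numerical integration over 40 doses, sampled just before the next dose
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1500, tau_h=12, tinf_h=0.5)
        n_doses = 40
        t_tr = n_doses * reg.tau_h - 1e-9
        ode = ode_oracle(ind, reg, [t_tr], n_doses)[0]
        assert steady_state_trough(ind, reg) == pytest.approx(ode, rel=1e-6)

    def test_trough_increasing_in_infusion_duration(self, typical_subject):
        ind = typical_subject(160.0)
        troughs = [
            steady_state_trough(ind, Regimen(1500, 12, tinf)) for tinf in (0.5, 4, 6)
        ]
        assert troughs[0] < troughs[1] < troughs[2]

    def test_trough_decreasing_in_clearance(self, pop):
        reg = Regimen(1500, 8, 4)
        troughs = [
            steady_state_trough(
                IndividualParameters(cl=cl, v1=pop.v1_pop, q=pop.q_pop, v2=pop.v2_pop),
                reg,
            )
            for cl in (4.0, 6.0, 9.0, 14.0)
        ]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))


class TestRegimenValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dose_mg=-1, tau_h=8, tinf_h=1),
            dict(dose_mg=1000, tau_h=0, tinf_h=1),
            dict(dose_mg=1000, tau_h=8, tinf_h=0),
            dict(dose_mg=1000, tau_h=8, tinf_h=10),
            dict(dose_mg=1000, tau_h=8, tinf_h=1, loading_dose_mg=1500),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            Regimen(**kwargs)

    def test_continuous_encoding(self):
        reg = Regimen(dose_mg=3000, tau_h=24, tinf_h=24)
        assert reg.is_continuous
        assert reg.rate_mg_per_h == pytest.approx(125.0)


class TestTimeCourse:
    def test_washout_after_single_dose(self, typical_subject):
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1500, tau_h=12, tinf_h=0.5)
        d = derive_disposition(ind)
        # peak >> terminal-phase intercept, so reaching 1e-6 x peak takes
        # well over 20 terminal half-lives
        t_half = math.log(2) / d.lambda2
        t = np.linspace(0, 0.5 + 30 * t_half, 400)
        conc = time_course(ind, reg, t, n_doses=1)
        assert conc[-1] < 1e-6 * conc.max()

    def test_convergence_to_steady_state(self, typical_subject):
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1500, tau_h=12, tinf_h=0.5)
        trough_15 = time_course(ind, reg, [15 * 12 - 1e-9], n_doses=15)[0]
        assert trough_15 == pytest.approx(steady_state_trough(ind, reg), rel=1e-3)

    def test_loading_equal_to_maintenance_is_plain_superposition(self, typical_subject):
        ind = typical_subject(200.0)
        plain = Regimen(dose_mg=1000, tau_h=8, tinf_h=4)
        loaded = Regimen(dose_mg=1000, tau_h=8, tinf_h=4,
                         loading_dose_mg=1000, loading_tinf_h=4)
        t = np.linspace(0, 40, 200)
        np.testing.assert_allclose(
            time_course(ind, loaded, t, 5), time_course(ind, plain, t, 5), rtol=1e-12
        )

    def test_negative_times_rejected(self, typical_subject):
        with pytest.raises(ValueError):
            time_course(typical_subject(160.0), Regimen(1500, 12, 0.5), [-1.0, 0.0], 1)


class TestTimeToTarget:
    def test_never_when_envelope_below_target(self, typical_subject):
        ind = typical_subject(240.0)  # CL ~9.16 L/h; 1000 mg/day CI plateau ~4.5 mg/L
        reg = Regimen(dose_mg=1000, tau_h=24, tinf_h=24)
        assert time_to_target(ind, reg, 12.0) == math.inf

    def test_zero_dose_never(self, typical_subject):
        assert time_to_target(typical_subject(160.0), Regimen(0.0, 12, 0.5), 12.0) == math.inf

    def test_crossing_is_exact(self, typical_subject):
        ind = typical_subject(200.0)
        reg = Regimen(dose_mg=3000, tau_h=24, tinf_h=24)
        t_star = time_to_target(ind, reg, 12.0)
        assert 0 < t_star < 48
        conc = time_course(ind, reg, [t_star], n_doses=5)[0]
        assert conc == pytest.approx(12.0, rel=1e-6)

    def test_loading_dose_reaches_target_sooner(self, typical_subject):
        ind = typical_subject(200.0)
        plain = Regimen(dose_mg=3000, tau_h=24, tinf_h=24)
        loaded = Regimen(dose_mg=3000, tau_h=24, tinf_h=24,
                         loading_dose_mg=1500, loading_tinf_h=0.5)
        assert time_to_target(ind, loaded, 12.0) < time_to_target(ind, plain, 12.0)

    def test_invalid_target_rejected(self, typical_subject):
        with pytest.raises(ValueError):
            time_to_target(typical_subject(160.0), Regimen(1500, 12, 0.5), 0.0)


class TestOdeOracle:
    def test_zero_dose_identically_zero(self, typical_subject):
        conc = ode_oracle(typical_subject(160.0), Regimen(0.0, 8, 1), [0, 4, 12], 3)
        np.testing.assert_array_equal(conc, 0.0)

    def test_agrees_with_superposition_three_doses(self, typical_subject):
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1000, tau_h=8, tinf_h=4)
        t = np.array([1.0, 4.0, 6.5, 8.0, 12.0, 16.5, 20.0, 23.9])
        closed = time_course(ind, reg, t, 3)
        ode = ode_oracle(ind, reg, t, 3)
        np.testing.assert_allclose(closed, ode, rtol=1e-6)

    def test_mass_conservation_during_infusion(self, typical_subject):
        # d(A1+A2)/dt + k10*A1 must equal the infusion rate
        ind = typical_subject(160.0)
        reg = Regimen(dose_mg=1000, tau_h=8, tinf_h=4)
        d = derive_disposition(ind)
        h = 1e-4
        for t_mid in (1.0, 2.5, 3.5):
            _, a1m, a2m = ode_oracle(ind, reg, [t_mid - h], 1, return_amounts=True)
            _, a1c, a2c = ode_oracle(ind, reg, [t_mid], 1, return_amounts=True)
            _, a1p, a2p = ode_oracle(ind, reg, [t_mid + h], 1, return_amounts=True)
            total_rate = ((a1p[0] + a2p[0]) - (a1m[0] + a2m[0])) / (2 * h)
            assert total_rate + d.k10 * a1c[0] == pytest.approx(
                reg.rate_mg_per_h, rel=1e-5
            )
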