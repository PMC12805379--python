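"""Unit and property tests for the Bloch-McConnell simulation core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cestfit as cf
from cestfit.spin_dynamics import (
    InvalidModelError,
    cpmg_pulse_count,
    exchange_generator,
    microscopic_rates,
)

from conftest import ode_propagate


class TestMicroscopicRates:
    @pytest.mark.parametrize(
        "pops, kex, expected",
        [
            # direct arithmetic from kex partitioning
            ({"A": 0.975, "B": 0.025}, {("A", "B"): 300.0}, {("A", "B"): 7.5, ("B", "A"): 292.5}),
            (
                {"E": 0.9828, "B": 0.015},
                {("E", "B"): 297.0},
                {("E", "B"): 297.0 * 0.015 / 0.9978, ("B", "E"): 297.0 * 0.9828 / 0.9978},
            ),
            # equal populations split kex evenly
            ({"X": 0.5, "Y": 0.5}, {("X", "Y"): 80.0}, {("X", "Y"): 40.0, ("Y", "X"): 40.0}),
        ],
    )
    def test_examples(self, pops, kex, expected):
        rates = microscopic_rates(pops, kex)
        for key, val in expected.items():
            assert rates[key] == pytest.approx(val, rel=1e-12)

    def test_zero_populations_rejected(self):
        with pytest.raises(InvalidModelError):
            microscopic_rates({"A": 0.0, "B": 0.0}, {("A", "B"): 100.0})

    def test_negative_kex_rejected(self):
        with pytest.raises(InvalidModelError):
            microscopic_rates({"A": 0.9, "B": 0.1}, {("A", "B"): -5.0})

    @settings(deadline=None, derandomize=True)
    @given(
        p=st.floats(1e-4, 0.49),
        q=st.floats(1e-4, 0.49),
        kex=st.floats(1.0, 2e4),
    )
    def test_detailed_balance_property(self, p, q, kex):
        pops = {"A": 1.0 - p - q, "B": p, "C": q}
        rates = microscopic_rates(pops, {("A", "B"): kex, ("B", "C"): kex / 2})
        for a, b in [("A", "B"), ("B", "C")]:
            assert rates[(a, b)] * pops[a] == pytest.approx(
                rates[(b, a)] * pops[b], rel=1e-12
            )
            assert rates[(a, b)] + rates[(b, a)] == pytest.approx(
                kex if (a, b) == ("A", "B") else kex / 2, rel=1e-12
            )


class TestExchangeGenerator:
    def test_two_state_matrix(self, two_state_model):
        G = exchange_generator(two_state_model)
        np.testing.assert_allclose(G, [[-7.5, 292.5], [7.5, -292.5]], rtol=1e-12)

    def test_columns_sum_to_zero_and_stationarity(self, triangular_model):
        G = exchange_generator(triangular_model)
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            G @ np.array(triangular_model.populations), 0.0, atol=1e-12
        )

    def test_unconnected_pair_has_zero_rates(self):
        m = cf.ExchangeModel(
            states=("E", "B", "I"),
            populations=(0.97, 0.02, 0.01),
            kex={("E", "B"): 100.0, ("E", "I"): 50.0},  # bifurcated: no B-I edge
        )
        assert m.rate("B", "I") == 0.0
        assert m.rate("I", "B") == 0.0


class TestPropagate:
    def test_zero_matrix_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(cf.propagate(np.zeros((3, 3)), 5.0, v), v)

    def test_diagonal_decay(self):
        r = np.array([1.0, 2.0, 3.0])
        out = cf.propagate(np.diag(-r), 0.7, np.ones(3))
        np.testing.assert_allclose(out, np.exp(-r * 0.7), rtol=1e-12)

    def test_matches_ode_oracle_on_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            A = rng.normal(0.0, 30.0, (9, 9))
            A -= np.diag(A.sum(axis=0))  # exchange-like: columns sum to 0
            A -= np.diag(rng.uniform(0.5, 20.0, 9))  # add relaxation
            v0 = rng.uniform(0.0, 1.0, 9)
            got = cf.propagate(A, 0.05, v0)
            ref = ode_propagate(A, 0.05, v0).real
            np.testing.assert_allclose(got, ref, rtol=1e-8, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cf.propagate(np.array([[np.nan, 0.0], [0.0, 1.0]]), 1.0, np.ones(2))


class TestCEST:
    def test_far_off_resonance_decays_at_r1(self):
        m = cf.ExchangeModel(states=("A",), populations=(1.0,), kex={})
        spin = cf.SpinSystem("N15", {"A": 0.0}, {"A": 1.0}, {"A": 10.0})
        # offset >= 100 * b1 away from resonance
        exp = cf.CESTExperiment(b0=18.8, b1=17.0, t_ex=0.4, offsets=np.array([5000.0]))
        prof = cf.simulate_cest_profile(m, spin, exp)
        assert prof.intensity_ratio[0] == pytest.approx(np.exp(-0.4), abs=1e-3)

    def test_zero_irradiation_time_is_identity(self, two_state_model, simple_spin):
        exp = cf.CESTExperiment.from_ppm(
            18.8, 17.0, 0.0, np.arange(-6, 6.01, 0.5), "N15"
        )
        prof = cf.simulate_cest_profile(two_state_model, simple_spin, exp)
        np.testing.assert_allclose(prof.intensity_ratio, 1.0)

    def test_two_dips_at_state_shifts(self, two_state_model, simple_spin):
        exp = cf.CESTExperiment.from_ppm(
            18.8, 17.0, 0.45, np.arange(-7, 7.001, 0.05), "N15"
        )
        prof = cf.simulate_cest_profile(two_state_model, simple_spin, exp)
        ppm = exp.offsets_ppm("N15")
        y = prof.intensity_ratio
        from scipy.signal import find_peaks

        # prominence filter merges the sub-0.02 saturation ripples at the
        # bottom of the major dip into a single minimum
        peaks, props = find_peaks(-y, prominence=0.02)
        minima_ppm = ppm[peaks]
        minima_depth = y[peaks]
        assert len(minima_ppm) == 2
        b1_ppm = 17.0 / (0.10136767 * 800.0)
        order = np.argsort(minima_depth)
        deeper, shallower = minima_ppm[order[0]], minima_ppm[order[1]]
        assert abs(deeper - 0.0) <= b1_ppm
        assert abs(shallower - 3.0) <= b1_ppm

    def test_profile_bounded(self, triangular_model):
        spin = cf.SpinSystem(
            "N15",
            {"E": 0.0, "B": 2.0, "I": 4.0},
            {s: 1.0 for s in "EBI"},
            {s: 10.0 for s in "EBI"},
        )
        for b1 in (17.0, 130.0):
            exp = cf.CESTExperiment.from_ppm(
                16.4, b1, 0.5, np.arange(-7, 7.01, 0.25), "N15"
            )
            prof = cf.simulate_cest_profile(triangular_model, spin, exp)
            assert np.all(prof.intensity_ratio >= -1.05)
            assert np.all(prof.intensity_ratio <= 1.05)

    def test_vanishing_minor_state_reduces_model(self):
        """A three-state model with one population -> 0 equals the embedded
        two-state model to 1e-10."""
        tri = cf.ExchangeModel(
            states=("E", "B", "I"),
            populations=(1.0 - 0.025 - 1e-14, 0.025, 1e-14),
            kex={("E", "B"): 300.0, ("E", "I"): 170.0, ("B", "I"): 1667.0},
        )
        two = cf.ExchangeModel(
            states=("E", "B"), populations=(0.975, 0.025), kex={("E", "B"): 300.0}
        )
        spin3 = cf.SpinSystem(
            "N15",
            {"E": 0.0, "B": 3.0, "I": 5.0},
            {s: 1.0 for s in "EBI"},
            {s: 10.0 for s in "EBI"},
        )
        spin2 = cf.SpinSystem(
            "N15", {"E": 0.0, "B": 3.0}, {s: 1.0 for s in "EB"}, {s: 10.0 for s in "EB"}
        )
        exp = cf.CESTExperiment.from_ppm(18.8, 25.0, 0.4, np.arange(-6, 6.01, 0.5), "N15")
        p3 = cf.simulate_cest_profile(tri, spin3, exp)
        p2 = cf.simulate_cest_profile(two, spin2, exp)
        np.testing.assert_allclose(
            p3.intensity_ratio, p2.intensity_ratio, atol=1e-10
        )

    def test_negative_t_ex_rejected(self):
        with pytest.raises(ValueError):
            cf.CESTExperiment(b0=18.8, b1=17.0, t_ex=-0.1, offsets=np.array([0.0]))


class TestCPMG:
    def test_single_state_gives_intrinsic_r2(self):
        m = cf.ExchangeModel(states=("A",), populations=(1.0,), kex={})
        spin = cf.SpinSystem("N15", {"A": 0.0}, {"A": 1.0}, {"A": 10.0})
        exp = cf.CPMGExperiment(11.7, 0.02, np.arange(50, 1001, 50))
        prof = cf.simulate_cpmg_profile(m, spin, exp)
        np.testing.assert_allclose(prof.r2_eff, 10.0, atol=1e-9)

    def test_no_shift_difference_means_no_dispersion(self, two_state_model):
        spin = cf.SpinSystem(
            "N15", {"A": 1.7, "B": 1.7}, {s: 1.0 for s in "AB"}, {s: 10.0 for s in "AB"}
        )
        exp = cf.CPMGExperiment(11.7, 0.02, np.arange(50, 1001, 50))
        prof = cf.simulate_cpmg_profile(two_state_model, spin, exp)
        assert np.ptp(prof.r2_eff) < 1e-9

    def test_two_state_dispersion_decreasing_and_matches_ode(
        self, two_state_model, simple_spin
    ):
        exp = cf.CPMGExperiment(11.7, 0.02, np.arange(50, 1001, 50))
        prof = cf.simulate_cpmg_profile(two_state_model, simple_spin, exp)
        assert np.all(np.diff(prof.r2_eff) <= 1e-9)
        # brute-force check at the fastest pulsing rate
        from cestfit.spin_dynamics import exchange_generator
        from cestfit.constants import larmor_mhz

        K = exchange_generator(two_state_model)
        omega = 2 * np.pi * np.array([0.0, 3.0]) * larmor_mhz(11.7, "N15")
        L = K.astype(complex) - np.diag(np.array([10.0, 10.0]) + 1j * omega)
        n = cpmg_pulse_count(0.02, 1000.0)
        delta = 0.02 / n
        m = np.array(two_state_model.populations, dtype=complex)
        for _ in range(n):
            m = ode_propagate(L, delta / 2, m)
            m = np.conj(m)
            m = ode_propagate(L, delta / 2, m)
        ref = -np.log(abs(m[0]) / 0.975) / 0.02
        assert prof.r2_eff[-1] == pytest.approx(ref, abs=0.5)

    def test_fast_limit_approaches_population_average(self):
        # fast exchange: kex = 4000 s^-1, strong pulsing collapses dispersion
        m = cf.ExchangeModel(
            states=("A", "B"), populations=(0.95, 0.05), kex={("A", "B"): 4000.0}
        )
        spin = cf.SpinSystem(
            "N15", {"A": 0.0, "B": 2.0}, {s: 1.0 for s in "AB"},
            {"A": 10.0, "B": 20.0},
        )
        exp = cf.CPMGExperiment(11.7, 0.02, np.array([10000.0]))
        prof = cf.simulate_cpmg_profile(m, spin, exp)
        avg = 0.95 * 10.0 + 0.05 * 20.0
        assert prof.r2_eff[0] == pytest.approx(avg, abs=0.2)

    def test_incompatible_nu_cpmg_lists_admissible_values(self):
        with pytest.raises(ValueError, match="admissible"):
            cpmg_pulse_count(0.02, 65.0)
        assert cpmg_pulse_count(0.02, 50.0) == 2
        assert cpmg_pulse_count(0.02, 1000.0) == 40
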