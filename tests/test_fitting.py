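"""Tests for global fitting, model comparison, scans and bootstrap."""

from dataclasses import replace

import numpy as np
import pytest

import cestfit as cf
from cestfit.fitting import FitProblem, StartConfig, chi2_reduced
from cestfit.models import ModelSpec, Topology

from conftest import make_two_state_cest_dataset


class TestChi2Reduced:
    def test_perfect_agreement_is_zero(self):
        _, data, _ = make_two_state_cest_dataset(n_sites=1, noise=0.0, seed=0)
        simulated = [p.intensity_ratio.copy() for p in data.cest]
        assert chi2_reduced(data, simulated, n_params=0) == 0.0

    def test_unit_residuals_give_one(self):
        _, data, _ = make_two_state_cest_dataset(n_sites=1, noise=0.0, seed=0)
        simulated = [p.intensity_ratio + p.sigma for p in data.cest]
        assert chi2_reduced(data, simulated, 0) == pytest.approx(1.0, rel=1e-12)

    def test_too_few_points_rejected(self):
        _, data, _ = make_two_state_cest_dataset(n_sites=1, noise=0.0, seed=0)
        simulated = [p.intensity_ratio for p in data.cest]
        with pytest.raises(ValueError):
            chi2_reduced(data, simulated, n_params=data.n_points)

    def test_expectation_near_one_for_correct_model(self):
        """E[chi2_red] of the generating model over noise realizations is 1
        within 3 sqrt(2/dof)."""
        model, data, _ = make_two_state_cest_dataset(n_sites=2, noise=0.0, seed=0)
        clean = [p.intensity_ratio.copy() for p in data.cest]
        rng = np.random.default_rng(123)
        sigma = 0.005
        chis = []
        for _ in range(100):
            noisy = replace(
                data,
                cest=[
                    replace(
                        p,
                        intensity_ratio=y + rng.normal(0.0, sigma, len(y)),
                        sigma=np.full(len(y), sigma),
                    )
                    for p, y in zip(data.cest, clean)
                ],
            )
            chis.append(chi2_reduced(noisy, clean, 0))
        dof = 100 * data.n_points
        assert np.mean(chis) == pytest.approx(1.0, abs=3 * np.sqrt(2.0 / dof))


class TestFitGlobal:
    def test_noiseless_self_consistency(self):
        """Fitting noiseless two-state data with the generating spec recovers
        kex and p_B to relative 1e-4."""
        model, data, guesses = make_two_state_cest_dataset(
            n_sites=3, noise=0.0, seed=2
        )
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        fit = cf.fit_global(
            data,
            spec,
            starts=StartConfig(n_starts=1, init={"p_B": 0.03, "kex_EB": 400.0}),
            seed=0,
            guesses=guesses,
        )
        assert fit.best_values["kex_EB"] == pytest.approx(300.0, rel=1e-4)
        assert fit.best_values["p_B"] == pytest.approx(0.025, rel=1e-4)
        assert fit.chi2_red < 1e-6

    def test_deterministic_given_seed(self):
        _, data, guesses = make_two_state_cest_dataset(n_sites=2, noise=0.005, seed=3)
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        fits = [
            cf.fit_global(
                data, spec, starts=StartConfig(n_starts=3), seed=11, guesses=guesses
            )
            for _ in range(2)
        ]
        assert fits[0].best_values == fits[1].best_values
        assert fits[0].chi2_red == fits[1].chi2_red

    def test_missing_uncertainties_rejected(self):
        model, data, _ = make_two_state_cest_dataset(n_sites=1, noise=0.0, seed=0)
        data.cest[0].sigma = None
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        with pytest.raises(ValueError, match="uncertaint"):
            FitProblem(data, spec)

    def test_wrong_sign_constraint_pushes_to_boundary(self):
        """Constraining dw_BI to the wrong sign forces the boundary (dw ~ 0)
        and degrades chi2 relative to the correctly signed fit."""
        tri = cf.ExchangeModel(
            states=("E", "B", "I"),
            populations=(1.0 - 0.015 - 0.005, 0.015, 0.005),
            kex={("E", "B"): 297.0, ("E", "I"): 170.0, ("B", "I"): 1667.0},
            topology=Topology.TRIANGULAR,
        )
        spin = cf.SpinSystem(
            "N15",
            {"E": 0.0, "B": 3.0, "I": 5.0},  # true dw_BI = +2 ppm
            {s: 1.0 for s in "EBI"},
            {s: 10.0 for s in "EBI"},
        )
        rng = np.random.default_rng(4)
        data = cf.Dataset(nuclei={"s0": "N15"})
        for b1 in (18.1, 51.8):
            exp = cf.CESTExperiment.from_ppm(
                16.4, b1, 0.5, np.arange(-7, 7.01, 0.25), "N15"
            )
            p = cf.simulate_cest_profile(tri, spin, exp)
            y = p.intensity_ratio + rng.normal(0, 0.005, len(p.intensity_ratio))
            data.cest.append(
                replace(p, site_id="s0", intensity_ratio=y, sigma=np.full(len(y), 0.005))
            )
        guesses = {"s0": {"w": 0.0, "dw1": 3.0, "dw12": 2.0, "r2": 10.0, "r1": 1.0}}
        init = {
            "p_B": 0.015,
            "p_I": 0.005,
            "kex_EB": 297.0,
            "kex_EI": 170.0,
            "kex_BI": 1667.0,
        }
        results = {}
        for sign in (+1, -1):
            spec = cf.apply_sign_constraints(
                ModelSpec(topology=Topology.TRIANGULAR, states=("E", "B", "I")),
                {"s0": sign},
            )
            g = dict(guesses)
            if sign == -1:
                g = {"s0": {**guesses["s0"], "dw12": -0.2}}
            # anchor the B dip near its assignment so the fit cannot dodge
            # the constraint by relabelling the two minor states
            results[sign] = cf.fit_global(
                data,
                spec,
                starts=StartConfig(n_starts=1, init=init),
                seed=0,
                guesses=g,
                dw1_window=0.5,
            )
        good, bad = results[+1], results[-1]
        assert bad.chi2_red > good.chi2_red
        dw_bi_bad = bad.per_site_shifts["s0"]["I"] - bad.per_site_shifts["s0"]["B"]
        assert dw_bi_bad == pytest.approx(0.0, abs=0.05)
        dw_bi_good = good.per_site_shifts["s0"]["I"] - good.per_site_shifts["s0"]["B"]
        assert dw_bi_good == pytest.approx(2.0, abs=0.3)


class TestCompareModels:
    def test_identical_specs_give_identical_results(self):
        _, data, guesses = make_two_state_cest_dataset(n_sites=2, noise=0.005, seed=5)
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        ranked = cf.compare_models(
            data,
            [spec, spec],
            seed=0,
            starts=StartConfig(n_starts=1, init={"p_B": 0.02, "kex_EB": 300.0}),
            guesses=guesses,
        )
        assert ranked[0].chi2_red == pytest.approx(ranked[1].chi2_red, rel=1e-9)
        assert ranked[0].best_values == ranked[1].best_values

    def test_needs_two_specs(self):
        _, data, _ = make_two_state_cest_dataset(n_sites=1, noise=0.0, seed=0)
        with pytest.raises(ValueError):
            cf.compare_models(data, [ModelSpec(topology=Topology.TWO_STATE)], seed=0)


class TestScan:
    def test_flat_scan_when_intermediate_unpopulated(self):
        """On data generated without an I state the chi2 surface is flat in
        kex_EI within noise."""
        _, data, guesses = make_two_state_cest_dataset(
            n_sites=3, noise=0.005, seed=6, b1_list=(25.0,), step=0.5
        )
        for g in guesses.values():
            g["dw12"] = 1.0
        spec = ModelSpec(topology=Topology.TRIANGULAR, states=("E", "B", "I"))
        init = {
            "p_B": 0.025,
            "p_I": 2e-4,
            "kex_EB": 300.0,
            "kex_EI": 200.0,
            "kex_BI": 1000.0,
        }
        curve = cf.scan_kex(
            data,
            spec,
            grid=[50.0, 200.0, 800.0],
            seed=0,
            starts=StartConfig(n_starts=1, init=init),
            guesses=guesses,
        )
        assert curve.ok.all()
        assert np.nanmax(curve.chi2_red) - np.nanmin(curve.chi2_red) < 0.05

    def test_grid_validation(self):
        _, data, _ = make_two_state_cest_dataset(n_sites=1, noise=0.0, seed=0)
        spec = ModelSpec(topology=Topology.TRIANGULAR, states=("E", "B", "I"))
        with pytest.raises(ValueError):
            cf.scan_kex(data, spec, grid=[100.0, 200.0], seed=0)
        with pytest.raises(ValueError):
            cf.scan_kex(data, spec, grid=[-1.0, 100.0, 200.0], seed=0)


@pytest.fixture(scope="module")
def small_fit():
    _, data, guesses = make_two_state_cest_dataset(
        n_sites=4, noise=0.005, seed=7, b1_list=(25.0,), step=0.5
    )
    return data, guesses


class TestBootstrap:

    def test_zero_noise_gives_zero_width_intervals(self):
        _, data, guesses = make_two_state_cest_dataset(
            n_sites=3, noise=0.0, seed=8, b1_list=(25.0,), step=0.5
        )
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        boot = cf.bootstrap_uncertainties(
            data,
            spec,
            n_trials=5,
            seed=0,
            starts=StartConfig(n_starts=1, init={"p_B": 0.02, "kex_EB": 350.0}),
            guesses=guesses,
        )
        lo, hi = boot.intervals["kex_EB"]
        assert hi - lo == pytest.approx(0.0, abs=0.5)

    def test_same_seed_reproduces_distributions(self, small_fit):
        data, guesses = small_fit
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        kw = dict(
            n_trials=6,
            starts=StartConfig(n_starts=1, init={"p_B": 0.02, "kex_EB": 350.0}),
            guesses=guesses,
        )
        b1 = cf.bootstrap_uncertainties(data, spec, seed=42, **kw)
        b2 = cf.bootstrap_uncertainties(data, spec, seed=42, **kw)
        for k in b1.samples:
            np.testing.assert_array_equal(b1.samples[k], b2.samples[k])
        b3 = cf.bootstrap_uncertainties(data, spec, seed=43, **kw)
        assert any(
            not np.array_equal(b1.samples[k], b3.samples[k]) for k in b1.samples
        )

    def test_minimum_trials(self, small_fit):
        data, guesses = small_fit
        spec = ModelSpec(topology=Topology.TWO_STATE, states=("E", "B"))
        with pytest.raises(ValueError):
            cf.bootstrap_uncertainties(data, spec, n_trials=1, seed=0)
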