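"""Parameter-recovery surface: the well model, the three fitters, and the
Latin-hypercube search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pdacsim.calibration import (
    LHSConfig, WellModelParams, fit_growth_rate, fit_release_curve,
    fit_viability, lhs_search, simulate_well, viability_curve, well_model_rhs,
)
from pdacsim.fibre import ReleaseLaw, simulate_release_invitro


class TestWellModel:
    def test_no_drug_gives_exact_exponential_growth(self):
        p = WellModelParams(phi=0.04, aliquot_concentrations=(0.0, 0.0, 0.0))
        y = simulate_well(p, 72.0)
        assert y[0] == pytest.approx(np.exp(0.04 * 72.0), rel=1e-6)

    def test_no_kill_keeps_dead_constant(self):
        p = WellModelParams(delta_m=0.0)
        y = simulate_well(p, 72.0, y0=(1.0, 0.25, 0.0))
        assert y[1] == pytest.approx(0.25, abs=1e-9)

    def test_kill_moves_cells_never_destroys(self):
        # d(P_L + P_D)/dt = phi * P_L identically
        p = WellModelParams(phi=0.03, delta_m=0.2, ic50=0.3)
        for state in ([1.0, 0.0, 0.0], [2.0, 1.0, 5.0], [0.5, 0.1, 0.01]):
            d = well_model_rhs(state, p)
            assert d[0] + d[1] == pytest.approx(p.phi * state[0])

    def test_aliquots_jump_drug_concentration(self):
        p = WellModelParams(phi=0.0, delta_m=0.0, lam=0.0,
                            aliquot_times=(10.0,), aliquot_concentrations=(3.0,))
        y = simulate_well(p, 20.0)
        assert y[2] == pytest.approx(3.0, rel=1e-9)

    def test_increasing_aliquot_times_enforced(self):
        with pytest.raises(ValueError):
            WellModelParams(aliquot_times=(48.0, 24.0))


class TestFitGrowthRate:
    def test_noiseless_recovery_exact(self):
        t = np.arange(0, 121, 12.0)
        phi, resid = fit_growth_rate(t, 1e4 * np.exp(0.03 * t))
        assert abs(phi - 0.03) < 1e-6
        assert resid < 1e-3

    def test_constant_counts_give_zero_rate(self):
        phi, _ = fit_growth_rate([0, 10, 20, 30], [5.0, 5.0, 5.0, 5.0])
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_rate([0, 1, 2], [1.0, 0.0, 2.0])

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 120, 12.0)
        ok = 0
        for _ in range(20):
            counts = 1e4 * np.exp(0.03 * t)
            counts *= 1 + 0.05 * rng.standard_normal(len(t))
            phi, _ = fit_growth_rate(t, counts)
            ok += abs(phi - 0.03) / 0.03 < 0.10
        assert ok >= 18


class TestFitViability:
    def test_noiseless_self_consistency(self):
        truth = WellModelParams(phi=0.03, delta_m=0.05, ic50=0.5, lam=0.05)
        scales = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0])
        v = viability_curve(truth, scales)
        schedule = dataclasses.replace(truth, delta_m=1.0, ic50=1.0)
        dm, ic50, _ = fit_viability(scales, v, schedule)
        assert abs(dm - 0.05) / 0.05 < 0.01
        assert abs(ic50 - 0.5) / 0.5 < 0.01

    def test_no_kill_signal_reported_unidentifiable(self):
        schedule = WellModelParams()
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_viability([0.1, 1.0], [1.0, 1.0], schedule)

    def test_zero_delta_m_forward_model_gives_full_viability(self):
        p = WellModelParams(delta_m=0.0)
        v = viability_curve(p, np.array([0.1, 1.0, 10.0]))
        np.testing.assert_allclose(v, 1.0, rtol=1e-8)


class TestFitReleaseCurve:
    TRUTH = dict(k=5e-5, d_const=3e-6, c0=500.0, a_out=0.08)

    def _curve(self, times):
        law = ReleaseLaw(kind="fvm", k=self.TRUTH["k"], eps=0.1,
                         d_const=self.TRUTH["d_const"], c0=self.TRUTH["c0"])
        return simulate_release_invitro(law, 0.05, 5.0, self.TRUTH["a_out"], times)

    def test_noiseless_recovery_within_five_percent(self):
        times = np.concatenate([[0.17, 0.5, 1, 1.5], np.arange(2, 11),
                                np.arange(24, 121, 24)]).astype(float)
        fit = fit_release_curve(times, self._curve(times))
        for name in ("k", "d_const", "c0", "a_out"):
            assert abs(getattr(fit, name) - self.TRUTH[name]) / self.TRUTH[name] < 0.05, name

    def test_fitted_curve_monotone_and_bounded(self):
        times = np.linspace(0.5, 120, 30)
        fit = fit_release_curve(times, self._curve(times))
        law = ReleaseLaw(kind="fvm", k=fit.k, eps=fit.eps, d_const=fit.d_const,
                         c0=fit.c0)
        pred = simulate_release_invitro(law, 0.05, 5.0, fit.a_out, times)
        assert (np.diff(pred) >= -1e-9).all()
        assert pred.max() <= fit.c0

    def test_non_monotone_data_rejected_unless_cleaned(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        data = np.array([10.0, 30.0, 20.0, 40.0])
        with pytest.raises(ValueError):
            fit_release_curve(times, data)
        fit = fit_release_curve(times, data, clean=True, n_starts=1)
        assert fit.c0 > 0


class TestLHSSearch:
    @staticmethod
    def _simulator(sample, seed):
        # cheap analytic stand-in: a deterministic curve plus seeded noise
        rng = np.random.default_rng(seed)
        t = np.arange(10.0)
        return (sample["p0"] * 100 * t + sample["d_max"]
                + 0.01 * rng.standard_normal(10))

    def _config(self, n_samples=50, seed=4):
        target = self._simulator({"p0": 0.05, "d_max": 15.0}, 999)
        return LHSConfig(bounds={"p0": (0.01, 0.2), "d_max": (5.0, 40.0)},
                         n_samples=n_samples, n_reps=3, seed=seed,
                         target_series=target)

    def test_argmin_by_construction(self):
        best, table = lhs_search(self._config(), self._simulator)
        assert best["mse"] == table["mse"].min()

    def test_same_seed_reproduces_table(self):
        _, t1 = lhs_search(self._config(), self._simulator)
        _, t2 = lhs_search(self._config(), self._simulator)
        pd.testing.assert_frame_equal(t1, t2)

    def test_stratification_each_stratum_once(self):
        cfg = self._config(n_samples=100)
        _, table = lhs_search(cfg, self._simulator)
        for name, (lo, hi) in cfg.bounds.items():
            strata = np.floor((table[name] - lo) / (hi - lo) * 100).astype(int)
            assert sorted(strata) == list(range(100))

    def test_failing_samples_flagged_not_fatal(self):
        def flaky(sample, seed):
            if sample["p0"] > 0.1:
                raise RuntimeError("boom")
            return self._simulator(sample, seed)

        best, table = lhs_search(self._config(), flaky)
        assert (table["flag"] == "failed").any()
        assert np.isfinite(best["mse"])
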