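"""Study harnesses: volume measurement, outcome classification, ensembles,
sensitivity grid, sweeps and the synthetic fixture generator."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdacsim import VCBMParams, init_hexagonal_tissue
from pdacsim.experiments import (
    classify_outcome, convergence_analysis, generate_fixtures, run_ensemble,
    sensitivity_grid, tumour_volume,
)
from pdacsim.lattice import CANCER


def brute_force_volume(points, sigma):
    """Exhaustive extent oracle: for the principal radial axis (farthest
    cell from the centroid), width = 2 max radial extent and length = 2 max
    perpendicular extent, volume = width*length^2/2*sigma^3."""
    centre = points.mean(axis=0)
    rel = points - centre
    best_r, best_i = -1.0, 0
    for i, p in enumerate(rel):
        r = np.hypot(*p)
        if r > best_r:
            best_r, best_i = r, i
    u = rel[best_i] / best_r
    perp_max = max(abs(-u[1] * p[0] + u[0] * p[1]) for p in rel)
    width, length = 2 * best_r, 2 * perp_max
    return width * length**2 / 2 * sigma**3


class TestTumourVolume:
    def test_no_tumour_is_zero(self, hex_tissue):
        assert tumour_volume(hex_tissue) == 0.0

    def test_hand_placed_extrema_match_oracle(self):
        t = init_hexagonal_tissue(11, 11, 1.0)
        chosen = [0, 17, 44, 60, 120]
        t.cell_type[chosen] = CANCER
        expect = brute_force_volume(t.positions[chosen], t.sigma)
        assert tumour_volume(t) == pytest.approx(expect)

    def test_default_scale_is_sigma_0_1728(self, hex_tissue):
        assert hex_tissue.sigma == 0.1728

    def test_alternative_reading_flag(self):
        t = init_hexagonal_tissue(9, 9, 1.0)
        t.cell_type[[0, 40, 80]] = CANCER
        v1 = tumour_volume(t, mode="caliper")
        v2 = tumour_volume(t, mode="squared")
        assert v1 > 0 and v2 > 0 and v1 != v2


class TestClassifyOutcome:
    @pytest.mark.parametrize("final,initial,expect", [
        (0.5, 100.0, "eradicate"),
        (50.0, 100.0, "stabilise"),
        (150.0, 100.0, "growth"),
    ])
    def test_rule(self, final, initial, expect):
        assert classify_outcome(final, initial) == expect

    @given(st.floats(0.0, 1e4), st.floats(1.001, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_partition_exactly_one_class(self, final, initial):
        assert classify_outcome(final, initial) in {"eradicate", "stabilise",
                                                    "growth"}


class TestRunEnsemble:
    def test_identical_seeds_zero_sd(self):
        run = lambda seed: np.full(5, 7.0)  # seed-independent
        s = run_ensemble(run, 4, base_seed=3)
        np.testing.assert_allclose(s["sd"], 0.0)

    def test_order_independent_summary(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            return rng.normal(10, 2, size=6)

        a = run_ensemble(run, 8, base_seed=0)
        finals = [run(s)[-1] for s in reversed(range(8))]
        np.testing.assert_allclose(sorted(a["finals"]), sorted(finals))

    def test_sem_shrinks_like_sqrt_n(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            return rng.normal(10, 2, size=3)

        df = convergence_analysis(run, ns=(10, 100, 1000), base_seed=11)
        assert df["sem_final"].is_monotonic_decreasing
        assert -0.8 < df.attrs["loglog_slope"] < -0.2

    def test_failures_excluded_and_counted(self):
        def run(seed):
            if seed % 3 == 0:
                raise RuntimeError("boom")
            return np.full(4, float(seed))

        s = run_ensemble(run, 9, base_seed=0)
        assert s["failures"] == 3
        assert s["n"] == 6


class TestSensitivityGrid:
    @staticmethod
    def _run_fn(params, seed):
        # analytic stand-in: volume grows with p0 and shrinks with g_age
        rng = np.random.default_rng(seed)
        return 100 * params.p0 / params.g_age + 0.001 * rng.uniform()

    def test_grid_shape_and_reference(self):
        base = VCBMParams()
        df = sensitivity_grid(base, self._run_fn, n=3,
                              weights=(0.5, 1.0, 1.5), params=("p0", "g_age"))
        # 2 diag blocks of 3 + 2 off-diag blocks of 9
        assert len(df) == 2 * 3 + 2 * 9
        ident = df[(df.param_a == "p0") & (df.param_b == "p0") & (df.w_a == 1.0)]
        control = np.mean([self._run_fn(base, i) for i in range(3)])
        assert ident["mean_final_volume"].iloc[0] == pytest.approx(control, rel=1e-3)

    def test_increasing_g_age_decreases_volume(self):
        base = VCBMParams()
        df = sensitivity_grid(base, self._run_fn, n=2,
                              weights=(0.5, 1.0, 2.0), params=("g_age",))
        diag = df[(df.param_a == "g_age") & (df.param_b == "g_age")]
        vols = diag.sort_values("w_a")["mean_final_volume"].to_numpy()
        assert (np.diff(vols) < 0).all()

    def test_probability_overflow_flagged(self):
        base = VCBMParams(p0=0.9)
        df = sensitivity_grid(base, self._run_fn, n=1, weights=(2.25,),
                              params=("p0",))
        # p0 * 2.25 > 1 is clipped (warned), never fatal
        assert np.isfinite(df["mean_final_volume"]).all()


class TestGenerateFixtures:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        a = generate_fixtures("counts", tmp_path / "a", seed=9, noise=0.05)
        b = generate_fixtures("counts", tmp_path / "b", seed=9, noise=0.05)
        assert (tmp_path / "a" / "counts.csv").read_bytes() == \
               (tmp_path / "b" / "counts.csv").read_bytes()
        assert a["sidecar"] == b["sidecar"]

    def test_release_fixture_monotone_with_sidecar(self, tmp_path):
        res = generate_fixtures("release", tmp_path, seed=2, noise=0.02)
        df = pd.read_csv(res["path"])
        assert (np.diff(df["cumulative_released_ug"]) >= -1e-9).all()
        sidecar = json.loads((tmp_path / "release.json").read_text())
        assert sidecar["params"]["c0"] == 500.0

    def test_viability_fixture_decreases_with_dose(self, tmp_path):
        res = generate_fixtures("viability", tmp_path, seed=1, noise=0.0)
        v = res["data"]["viability_fraction"].to_numpy()
        assert (np.diff(v) < 0).all()

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_fixtures("bogus", tmp_path)
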