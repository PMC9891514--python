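"""Cell update rules: mechanics, proliferation, differentiation, drug death,
disintegration and the composed hourly step."""

import numpy as np
import pytest

from pdacsim import DeathParams, VCBMParams, init_hexagonal_tissue, seed_tumour
from pdacsim.agents import (
    attempt_mcc_differentiation, attempt_proliferation, death_probability,
    disintegrate_dead, hooke_displacements, nutrient_distance,
    nutrient_distances, proliferation_probability, vcbm_step,
)
from pdacsim.lattice import CANCER, DEAD, HEALTHY, MCC

from conftest import make_pair_tissue


class TestHooke:
    def test_equilibrium_has_zero_displacement(self, hex_tissue, params):
        # set every spring to its current length: the network is at rest
        i, j = hex_tissue.edges[:, 0], hex_tissue.edges[:, 1]
        hex_tissue.rest_length = np.linalg.norm(
            hex_tissue.positions[i] - hex_tissue.positions[j], axis=1)
        disp = hooke_displacements(hex_tissue, params)
        np.testing.assert_allclose(disp, 0.0, atol=1e-12)

    def test_interior_of_pristine_hex_grid_is_balanced(self, hex_tissue, params):
        # away from the boundary every spring is at the mature rest length,
        # so interior displacements vanish by symmetry
        disp = hooke_displacements(hex_tissue, params)
        centre = hex_tissue.positions.mean(axis=0)
        interior = np.linalg.norm(hex_tissue.positions - centre, axis=1) < 2.5
        np.testing.assert_allclose(disp[interior], 0.0, atol=1e-12)

    def test_stretched_pair_attracts_by_spring_arithmetic(self):
        # pair at distance 2s with rest s and lambda_m = 1: each cell moves
        # distance s toward the other
        t = make_pair_tissue(distance=2.0, rest=1.0)
        p = VCBMParams(lambda_m=1.0)
        disp = hooke_displacements(t, p)
        # cell 0 sits at the origin, cell 1 at (2, 0): each moves distance
        # s toward the other
        np.testing.assert_allclose(disp[0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(disp[1], [-1.0, 0.0], atol=1e-12)

    def test_compressed_pair_repels(self):
        t = make_pair_tissue(distance=0.5, rest=1.0)
        p = VCBMParams(lambda_m=0.3)
        disp = hooke_displacements(t, p)
        assert disp[0, 0] < 0 < disp[1, 0]

    def test_perturbed_pair_relaxes_monotonically(self):
        t = make_pair_tissue(distance=1.6, rest=1.0)
        p = VCBMParams(lambda_m=0.3)
        errs = []
        for _ in range(20):
            disp = hooke_displacements(t, p)
            t.positions = t.positions + disp
            errs.append(abs(np.linalg.norm(t.positions[1] - t.positions[0]) - 1.0))
        assert all(b < a for a, b in zip(errs, errs[1:]))


class TestNutrientDistance:
    def test_adjacent_healthy_cell(self, seeded_tissue):
        i = np.flatnonzero(seeded_tissue.cell_type == CANCER)[0]
        assert nutrient_distance(seeded_tissue, i) == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self, rng):
        t = seed_tumour(init_hexagonal_tissue(10, 10, 1.0))
        t.positions += rng.normal(0, 0.05, t.positions.shape)
        idx = np.arange(t.n_cells)
        fast = nutrient_distances(t, idx)
        healthy = t.positions[t.cell_type == HEALTHY]
        for i in idx:
            brute = np.linalg.norm(healthy - t.positions[i], axis=1).min()
            assert fast[i] == pytest.approx(brute)

    def test_no_healthy_cells_returns_inf(self, hex_tissue):
        hex_tissue.cell_type[:] = CANCER
        assert nutrient_distance(hex_tissue, 0) == np.inf


class TestProliferationProbability:
    def test_linear_form(self):
        p = VCBMParams(p0=0.2, d_max=10.0)
        assert proliferation_probability(0.0, p) == pytest.approx(0.2)
        assert proliferation_probability(10.0, p) == pytest.approx(0.0)
        assert proliferation_probability(5.0, p) == pytest.approx(0.1)

    def test_quiescent_beyond_dmax(self):
        p = VCBMParams(d_max=10.0)
        assert proliferation_probability(10.0001, p) == 0.0
        assert proliferation_probability(np.inf, p) == 0.0

    def test_p0_derives_from_phi(self):
        p = VCBMParams(phi=0.03, dt_cells=1.0)
        assert p.p0 == pytest.approx(1 - np.exp(-0.03))


class TestDeathProbability:
    def test_no_drug_no_kill(self):
        assert death_probability(0.0, DeathParams(), 1.0) == 0.0

    def test_half_saturation(self):
        dp = DeathParams(delta_m=0.2, ic50=0.5)
        assert death_probability(0.5, dp, 1.0) == pytest.approx(1 - np.exp(-0.1))

    def test_saturation_limit_and_monotonicity(self):
        dp = DeathParams(delta_m=0.2, ic50=0.5)
        cs = np.linspace(0, 1e6, 101)
        ps = np.array([death_probability(c, dp, 1.0) for c in cs])
        assert (np.diff(ps) >= -1e-15).all()
        assert ps[-1] == pytest.approx(1 - np.exp(-0.2), rel=1e-4)


class TestProliferationAttempt:
    def _ready(self, tissue, i):
        tissue.cooldown[i] = 0
        tissue.maturity[i] = 1.0

    def test_certain_division_creates_one_daughter(self, rng):
        t = seed_tumour(init_hexagonal_tissue(9, 9, 1.0))
        i = np.flatnonzero(t.cell_type == CANCER)[0]
        p = VCBMParams(p0=1.0, d_max=1e9)
        self._ready(t, i)
        n = t.n_cells
        assert attempt_proliferation(t, i, p, rng, d_neut=0.0)
        assert t.n_cells == n + 1
        assert t.cell_type[-1] == CANCER
        assert t.maturity[-1] == pytest.approx(1 / p.p_age)
        # mother and daughter are s/p_age apart
        d = np.linalg.norm(t.positions[i] - t.positions[-1])
        assert d == pytest.approx(p.s / p.p_age)

    def test_contact_inhibition_blocks_division(self, rng):
        # compress the packing so every neighbour is within s/p_age
        t = seed_tumour(init_hexagonal_tissue(9, 9, 0.4))
        t.spacing = 0.4
        i = np.flatnonzero(t.cell_type == CANCER)[0]
        p = VCBMParams(p0=1.0, d_max=1e9, s=1.0, p_age=2.0)
        self._ready(t, i)
        for _ in range(1000):
            assert not attempt_proliferation(t, i, p, rng, d_neut=0.0)

    def test_empirical_division_fraction_matches_probability(self, rng):
        # binomial check at p_d = 0.1
        t = seed_tumour(init_hexagonal_tissue(5, 5, 1.0))
        i = np.flatnonzero(t.cell_type == CANCER)[0]
        p = VCBMParams(p0=0.1, d_max=1e9)
        n, hits = 20_000, 0
        for _ in range(n):
            t2 = t.copy()
            t2.cooldown[i] = 0
            t2.maturity[i] = 1.0
            if attempt_proliferation(t2, i, p, rng, d_neut=0.0):
                hits += 1
        band = 3 * np.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) < band


class TestMCCDifferentiation:
    def test_interior_cell_ineligible(self, rng):
        t = init_hexagonal_tissue(9, 9, 1.0)
        t.cell_type[:] = CANCER  # no healthy neighbours anywhere
        p = VCBMParams(p_MCC=1.0)
        assert not attempt_mcc_differentiation(t, 40, p, rng)

    def test_certain_differentiation_replaces_healthy_neighbour(self, rng):
        t = seed_tumour(init_hexagonal_tissue(9, 9, 1.0))
        i = np.flatnonzero(t.cell_type == CANCER)[0]
        p = VCBMParams(p_MCC=1.0)
        h0, m0, n0 = t.count(HEALTHY), t.count(MCC), t.n_cells
        assert attempt_mcc_differentiation(t, i, p, rng)
        assert t.count(HEALTHY) == h0 - 1
        assert t.count(MCC) == m0 + 1
        assert t.n_cells == n0  # converted in place


class TestDisintegration:
    def test_rest_length_shrinks_linearly(self):
        t = seed_tumour(init_hexagonal_tissue(9, 9, 1.0))
        i = np.flatnonzero(t.cell_type == CANCER)[0]
        p = VCBMParams(d_age=10)
        t.cell_type[i] = DEAD
        t.disintegration_left[i] = 10
        t.disintegration_total[i] = 10
        incident = (t.edges[:, 0] == i) | (t.edges[:, 1] == i)
        t.rest_decrement[incident] = t.rest_length[incident] / 10
        living_rest = t.rest_length[~incident].copy()
        disintegrate_dead(t, p)
        np.testing.assert_allclose(t.rest_length[incident], 0.9)
        np.testing.assert_allclose(t.rest_length[~incident], living_rest)

    def test_removed_after_clock_expires(self):
        t = seed_tumour(init_hexagonal_tissue(9, 9, 1.0))
        i = np.flatnonzero(t.cell_type == CANCER)[0]
        t.cell_type[i] = DEAD
        t.disintegration_left[i] = 1
        t.disintegration_total[i] = 10
        n = t.n_cells
        disintegrate_dead(t, VCBMParams(d_age=10))
        assert t.n_cells == n - 1
        assert t.count(DEAD) == 0


class TestVcbmStep:
    def test_all_events_disabled_keeps_counts(self, rng):
        # tissue large enough that the domain-expansion rule stays dormant
        t = seed_tumour(init_hexagonal_tissue(25, 25, 1.0))
        p = VCBMParams(p0=0.0, p_MCC=0.0)
        counts = (t.count(HEALTHY), t.count(CANCER))
        for _ in range(5):
            vcbm_step(t, p, DeathParams(delta_m=0.0), None, rng)
        assert (t.count(HEALTHY), t.count(CANCER)) == counts

    def test_saturating_drug_kills_all_tumour_cells(self, rng):
        t = seed_tumour(init_hexagonal_tissue(9, 9, 1.0))
        t.cell_type[[0, 1, 2]] = CANCER
        p = VCBMParams(p0=0.0, p_MCC=0.0, d_age=2)
        dp = DeathParams(delta_m=50.0, ic50=0.1)
        lookup = lambda pos: np.full(len(np.atleast_2d(pos)), 1e9)
        for _ in range(6):
            vcbm_step(t, p, dp, lookup, rng)
        assert t.count(CANCER) + t.count(MCC) == 0

    def test_identical_seed_identical_trajectory(self):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            t = seed_tumour(init_hexagonal_tissue(12, 12, 1.0))
            p = VCBMParams(phi=0.3, age_mean=5, g_age=4)
            for _ in range(30):
                vcbm_step(t, p, DeathParams(delta_m=0.0), None, rng)
            out.append((t.n_cells, t.positions.copy(), t.cell_type.copy()))
        assert out[0][0] == out[1][0]
        np.testing.assert_array_equal(out[0][1], out[1][1])
        np.testing.assert_array_equal(out[0][2], out[1][2])

    def test_healthy_cells_never_proliferate(self, rng):
        t = init_hexagonal_tissue(10, 10, 1.0)  # all healthy
        p = VCBMParams(p0=1.0, d_max=1e9)
        n = t.n_cells
        for _ in range(5):
            vcbm_step(t, p, DeathParams(delta_m=0.0), None, rng)
        assert t.n_cells == n
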