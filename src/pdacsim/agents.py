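"""VCBM update rules, composed into a one-hour step.

Cancer cells proliferate with a probability that decays linearly with
distance to the nearest healthy cell (the nutrient proxy), are contact
inhibited when fully crowded, differentiate into invasive mesenchymal-like
cancer cells (MCCs) at the tumour boundary, die under gemcitabine via a
Michaelis-Menten hazard, and disintegrate after death.  Movement is
overdamped Hooke's-law relaxation on the Delaunay spring network.

Within-step event order (fixed for determinism): drug-death draws on the
configuration produced by the previous hour, dead-cell disintegration,
proliferation and MCC differentiation, spring relaxation, geometry rebuild,
domain expansion.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial import cKDTree

from . import lattice
from .lattice import CANCER, DEAD, HEALTHY, MCC, Tissue

log = logging.getLogger(__name__)


@dataclasses.dataclass
class VCBMParams:
    """Tumour-growth parameters of the cell-based model.

    phi is the in vitro exponential proliferation rate (per hour) from which
    the per-step proliferation ceiling p0 = 1 - exp(-phi*dt) derives; g_age
    the mean cell-cycle delay (h); p_age the division factor (daughters are
    born with rest lengths s/p_age); d_max the maximum nutrient distance for
    proliferation (model units); p_MCC the per-step boundary differentiation
    probability; d_age the dead-cell disintegration time (h); lambda_m the
    damping/mobility constant of the spring relaxation.
    """

    phi: float = 0.03
    g_age: float = 24.0
    age_mean: float = 50.0
    p_age: float = 2.0
    d_max: float = 15.0
    p_MCC: float = 5e-4
    d_age: float = 48.0
    lambda_m: float = 0.3
    s: float = 1.0
    dt_cells: float = 1.0
    p0: float | None = None  # explicit override of 1 - exp(-phi*dt)

    def __post_init__(self):
        if self.p0 is None:
            self.p0 = 1.0 - np.exp(-self.phi * self.dt_cells)
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p_MCC <= 1.0):
            raise ValueError("p0 and p_MCC must be probabilities")
        for name in ("g_age", "d_max", "d_age", "lambda_m", "s", "dt_cells", "p_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_age < 1:
            raise ValueError("p_age must be >= 1")

    def scaled(self, **weights) -> "VCBMParams":
        """Copy with named parameters multiplied by weights (probabilities
        clipped to [0, 1] with a warning)."""
        d = dataclasses.asdict(self)
        for name, w in weights.items():
            d[name] = d[name] * w
        for p in ("p0", "p_MCC"):
            if d[p] is not None and d[p] > 1.0:
                log.warning("%s clipped to 1 after scaling (was %.3f)", p, d[p])
                d[p] = 1.0
        return VCBMParams(**d)


@dataclasses.dataclass
class DeathParams:
    """Michaelis-Menten pharmacodynamics: hazard delta_m * C/(C + IC50)."""

    delta_m: float = 0.05
    ic50: float = 0.1

    def __post_init__(self):
        if self.delta_m < 0:
            raise ValueError("delta_m must be nonnegative")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")


def hooke_displacements(tissue: Tissue, params: VCBMParams) -> np.ndarray:
    """Overdamped spring-network displacements.

    For each cell i: lambda_m * sum_j u_ij * (s_ij - |r_ij|) with
    r_ij = r_i - r_j, summed over Delaunay neighbours.  Coincident
    neighbours contribute nothing (warned).
    """
    disp = np.zeros_like(tissue.positions)
    if len(tissue.edges) == 0:
        return disp
    i = tissue.edges[:, 0]
    j = tissue.edges[:, 1]
    rij = tissue.positions[i] - tissue.positions[j]
    dist = np.linalg.norm(rij, axis=1)
    ok = dist > 1e-12
    if not ok.all():
        log.warning("%d coincident neighbour pairs skipped", int((~ok).sum()))
    u = np.zeros_like(rij)
    u[ok] = rij[ok] / dist[ok, None]
    f = (tissue.rest_length - dist)[:, None] * u
    np.add.at(disp, i, f)
    np.add.at(disp, j, -f)
    return params.lambda_m * disp


def apply_hooke(tissue: Tissue, params: VCBMParams) -> Tissue:
    disp = hooke_displacements(tissue, params)
    tissue.positions = tissue.positions + disp
    xmin, xmax, ymin, ymax = tissue.bounds
    np.clip(tissue.positions[:, 0], xmin, xmax, out=tissue.positions[:, 0])
    np.clip(tissue.positions[:, 1], ymin, ymax, out=tissue.positions[:, 1])
    return tissue


def nutrient_distance(tissue: Tissue, cell_id: int) -> float:
    """Distance from a cell to the nearest healthy cell centre (the nutrient
    proxy at the tumour periphery); +inf if no healthy cells remain."""
    healthy = tissue.mask(HEALTHY)
    if not healthy.any():
        return np.inf
    d = np.linalg.norm(tissue.positions[healthy] - tissue.positions[cell_id], axis=1)
    return float(d.min())


def nutrient_distances(tissue: Tissue, indices: np.ndarray) -> np.ndarray:
    """Vectorised nutrient distances for many cells via a KD-tree."""
    healthy = tissue.mask(HEALTHY)
    if not healthy.any():
        return np.full(len(indices), np.inf)
    tree = cKDTree(tissue.positions[healthy])
    d, _ = tree.query(tissue.positions[indices])
    return d


def proliferation_probability(d_neut: float, params: VCBMParams) -> float:
    """p0 * (1 - d/d_max) within the proliferative rim, 0 beyond it."""
    if d_neut > params.d_max:
        return 0.0
    return params.p0 * (1.0 - d_neut / params.d_max)


def death_probability(c_local: float, dp: DeathParams, dt: float) -> float:
    """Per-step death probability 1 - exp(-beta*dt) with Michaelis-Menten
    hazard beta = delta_m * c/(c + IC50)."""
    c = np.maximum(c_local, 0.0)
    beta = dp.delta_m * c / (c + dp.ic50)
    return 1.0 - np.exp(-beta * dt)


def _spawn_daughter(tissue: Tissue, mother: int, params: VCBMParams,
                    rng: np.random.Generator) -> None:
    """Place mother and daughter s/p_age apart about the mother's prior
    position, at a uniform random angle."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])
    half = params.s / params.p_age / 2.0
    prior = tissue.positions[mother].copy()
    tissue.positions[mother] = prior + half * u
    pos_d = prior - half * u
    xmin, xmax, ymin, ymax = tissue.bounds
    pos_d = np.clip(pos_d, [xmin, ymin], [xmax, ymax])
    tissue.positions[mother] = np.clip(tissue.positions[mother], [xmin, ymin], [xmax, ymax])
    cooldown_d = int(rng.poisson(params.age_mean))
    tissue.ids = np.append(tissue.ids, tissue.next_id)
    tissue.next_id += 1
    tissue.positions = np.vstack([tissue.positions, pos_d])
    tissue.cell_type = np.append(tissue.cell_type, tissue.cell_type[mother])
    tissue.age = np.append(tissue.age, 0)
    tissue.cooldown = np.append(tissue.cooldown, cooldown_d)
    tissue.maturity = np.append(tissue.maturity, 1.0 / params.p_age)
    tissue.disintegration_left = np.append(tissue.disintegration_left, 0)
    tissue.disintegration_total = np.append(tissue.disintegration_total, 0)
    tissue.voronoi_area = np.append(tissue.voronoi_area, 0.0)
    tissue.cooldown[mother] = int(round(params.g_age))


def attempt_proliferation(tissue: Tissue, cell_id: int, params: VCBMParams,
                          rng: np.random.Generator,
                          d_neut: float | None = None,
                          neighbours=None) -> bool:
    """One division attempt; returns True if a daughter was created.

    Requires a cancer/MCC cell off cooldown and fully mature.  Contact
    inhibition: no division if every Delaunay neighbour lies within
    s/p_age.  A rebuild is expected after the sweep that calls this.
    """
    if tissue.cell_type[cell_id] not in (CANCER, MCC):
        return False
    if tissue.cooldown[cell_id] > 0 or tissue.maturity[cell_id] < 1.0:
        return False
    if d_neut is None:
        d_neut = nutrient_distance(tissue, cell_id)
    p = proliferation_probability(d_neut, params)
    if rng.uniform() >= p:
        return False
    if neighbours is None:
        adj = tissue.neighbour_lists()
        neighbours = adj[cell_id]
    if len(neighbours) > 0:
        d = np.linalg.norm(
            tissue.positions[neighbours] - tissue.positions[cell_id], axis=1)
        if (d < params.s / params.p_age).all():
            return False  # contact inhibited
    _spawn_daughter(tissue, cell_id, params, rng)
    return True


def attempt_mcc_differentiation(tissue: Tissue, cell_id: int, params: VCBMParams,
                                rng: np.random.Generator,
                                neighbours=None) -> bool:
    """Boundary cancer cells convert a healthy Delaunay neighbour into an
    MCC daughter (in place) with probability p_MCC; lowest-id neighbour is
    chosen.  Interior cells are ineligible."""
    if tissue.cell_type[cell_id] != CANCER:
        return False
    if neighbours is None:
        adj = tissue.neighbour_lists()
        neighbours = adj[cell_id]
    healthy_nb = [n for n in neighbours if tissue.cell_type[n] == HEALTHY]
    if not healthy_nb:
        return False
    if rng.uniform() >= params.p_MCC:
        return False
    chosen = min(healthy_nb, key=lambda n: tissue.ids[n])
    tissue.cell_type[chosen] = MCC
    tissue.age[chosen] = 0
    tissue.maturity[chosen] = 1.0
    tissue.cooldown[chosen] = int(rng.poisson(params.age_mean))
    return True


def disintegrate_dead(tissue: Tissue, params: VCBMParams) -> Tissue:
    """Shrink dead cells' incident rest lengths by s_ij/d_age per hour and
    remove records whose disintegration clock has run out."""
    dead = tissue.mask(DEAD)
    if dead.any():
        incident = dead[tissue.edges[:, 0]] | dead[tissue.edges[:, 1]]
        tissue.rest_length[incident] = np.maximum(
            tissue.rest_length[incident] - tissue.rest_decrement[incident], 0.0)
        tissue.disintegration_left[dead] -= 1
        gone = np.flatnonzero(dead & (tissue.disintegration_left <= 0))
        if len(gone):
            lattice.remove_cells(tissue, gone)
    return tissue


def _apply_deaths(tissue: Tissue, death_params: DeathParams, params: VCBMParams,
                  drug_lookup, rng: np.random.Generator) -> int:
    tum = np.flatnonzero(tissue.tumour_mask)
    if len(tum) == 0 or drug_lookup is None:
        return 0
    c = np.asarray(drug_lookup(tissue.positions[tum]), dtype=float)
    p = death_probability(c, death_params, params.dt_cells)
    dies = rng.uniform(size=len(tum)) < p
    victims = tum[dies]
    if len(victims):
        tissue.cell_type[victims] = DEAD
        d_age = int(round(params.d_age))
        tissue.disintegration_left[victims] = d_age
        tissue.disintegration_total[victims] = d_age
        incident = np.isin(tissue.edges[:, 0], victims) | np.isin(tissue.edges[:, 1], victims)
        tissue.rest_decrement[incident] = tissue.rest_length[incident] / d_age
    return len(victims)


def _mature(tissue: Tissue, params: VCBMParams) -> None:
    """Advance daughter maturity linearly from 1/p_age to 1 over g_age hours
    and let the corresponding rest lengths follow."""
    growing = (tissue.maturity < 1.0) & (tissue.cell_type != DEAD)
    if not growing.any():
        return
    rate = (1.0 - 1.0 / params.p_age) / params.g_age * params.dt_cells
    tissue.maturity[growing] = np.minimum(tissue.maturity[growing] + rate, 1.0)
    i, j = tissue.edges[:, 0], tissue.edges[:, 1]
    touch = growing[i] | growing[j]
    dead_edge = (tissue.cell_type[i] == DEAD) | (tissue.cell_type[j] == DEAD)
    upd = touch & ~dead_edge
    m = np.minimum(tissue.maturity[i[upd]], tissue.maturity[j[upd]])
    tissue.rest_length[upd] = params.s * m


def vcbm_step(tissue: Tissue, params: VCBMParams, death_params: DeathParams,
              drug_lookup, rng: np.random.Generator,
              expand_margin: float = 10.0,
              compute_areas: bool = False) -> Tissue:
    """One Delta-t advance of the cell world.

    ``drug_lookup`` maps an (n, 2) position array to local drug
    concentrations (None disables drug death).  ``compute_areas`` requests
    full Voronoi areas in the final rebuild (tumour-cell areas are always
    refreshed, for the uptake sinks).
    """
    _apply_deaths(tissue, death_params, params, drug_lookup, rng)
    disintegrate_dead(tissue, params)

    # proliferation + differentiation sweep over the pre-sweep tumour cells,
    # in index order, using geometry from the last rebuild
    adj = tissue.neighbour_lists()
    tum = np.flatnonzero(tissue.tumour_mask)
    if len(tum):
        d_neut = nutrient_distances(tissue, tum)
        for d, idx in zip(d_neut, tum):
            attempt_proliferation(tissue, idx, params, rng, d_neut=d,
                                  neighbours=adj[idx])
            attempt_mcc_differentiation(tissue, idx, params, rng,
                                        neighbours=adj[idx])

    _mature(tissue, params)
    apply_hooke(tissue, params)
    # Voronoi areas are only needed for the uptake sinks (tumour cells) or
    # when a full snapshot is requested
    need_areas = compute_areas or drug_lookup is not None
    tum_idx = np.flatnonzero(tissue.tumour_mask)
    lattice.rebuild_geometry(
        tissue, compute_areas=need_areas,
        area_subset=None if compute_areas else tum_idx)
    lattice.expand_domain(tissue, margin=expand_margin)

    tissue.age += 1
    tissue.cooldown = np.maximum(tissue.cooldown - 1, 0)
    return tissue
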