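"""Coupled VCBM + drug-field simulation runs.

The agent world advances on 1 h steps; between agent steps the drug field
(and, when implanted, the fibre) advances with shorter PDE sub-steps.  The
fibre couples to the field through the continuity condition -- its outer
Dirichlet boundary is the local TME concentration -- and the per-row
released mass is deposited as a line source, so the joint fibre+TME drug
ledger closes to round-off.

Unit bookkeeping: the tissue and grid live in model units (1 unit = sigma
mm, sigma^3 mm^3 per model volume); the fibre solver works in physical mm.
Concentrations convert by sigma^3 and the released mass (ug) is unit-free.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import lattice
from .agents import DeathParams, VCBMParams, vcbm_step
from .dosing import Protocol, administer
from .fibre import FibreState, fibre_step
from .lattice import CANCER, DEAD, HEALTHY, MCC, Tissue
from .tme_field import DrugGrid, deposit_line_flux, make_grid, step_field


def tumour_centroid(tissue: Tissue) -> np.ndarray:
    tm = tissue.tumour_mask
    if tm.any():
        return tissue.positions[tm].mean(axis=0)
    xmin, xmax, ymin, ymax = tissue.bounds
    return np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])


def _volume(tissue: Tissue) -> float:
    from .experiments import tumour_volume

    return tumour_volume(tissue)


def _record(rows, t_h, tissue: Tissue, grid: DrugGrid | None,
            fib: FibreState | None) -> None:
    rows.append({
        "time_h": t_h,
        "volume_mm3": _volume(tissue),
        "n_healthy": tissue.count(HEALTHY),
        "n_cancer": tissue.count(CANCER),
        "n_mcc": tissue.count(MCC),
        "n_dead": tissue.count(DEAD),
        "tme_drug_ug": 0.0 if grid is None else grid.total_mass(),
        "fibre_drug_ug": 0.0 if fib is None else fib.total_mass(),
    })


def grow_tumour(params: VCBMParams, seed: int, n_rows: int = 40, n_cols: int = 40,
                spacing: float = 1.0, sigma: float = 0.1728,
                max_hours: int = 792, stop_volume: float | None = None,
                record_every: int = 24, expand_margin: float = 10.0,
                init_age_poisson: bool = False) -> tuple[Tissue, pd.DataFrame]:
    """Drug-free growth from a single seeded cancer cell.

    Stops at ``max_hours`` or when the measured volume first reaches
    ``stop_volume`` (mm^3).  ``init_age_poisson`` additionally draws every
    initial cell's proliferation cooldown from Poisson(age_mean) at t=0
    (default: only daughters sample their birth age).
    """
    rng = np.random.default_rng(seed)
    tissue = lattice.init_hexagonal_tissue(n_rows, n_cols, spacing, sigma=sigma)
    lattice.seed_tumour(tissue)
    if init_age_poisson:
        tissue.cooldown = rng.poisson(params.age_mean, tissue.n_cells).astype(np.int64)
        tissue.cooldown[tissue.cell_type == CANCER] = 0
    rows: list[dict] = []
    _record(rows, 0, tissue, None, None)
    for t in range(1, max_hours + 1):
        vcbm_step(tissue, params, DeathParams(delta_m=0.0), None, rng,
                  expand_margin=expand_margin)
        if t % record_every == 0:
            _record(rows, t, tissue, None, None)
        if stop_volume is not None and _volume(tissue) >= stop_volume:
            if t % record_every != 0:
                _record(rows, t, tissue, None, None)
            break
    return tissue, pd.DataFrame(rows)


def build_treatment_grid(tissue: Tissue, protocol: Protocol,
                         voxels_per_unit: float = 1.0, margin: float = 5.0,
                         depth_h: float = 1.0, D: float = 12.0,
                         lam: float = 0.1, nu_c: float = 0.05) -> DrugGrid:
    """Drug grid sized to cover the tissue, all dose sites and the fibre
    span, with a margin (model units)."""
    xmin, xmax, ymin, ymax = tissue.bounds
    centre = tumour_centroid(tissue)
    # placement sites can sit at distance d_m/sigma in any direction
    reach = protocol.d_m / tissue.sigma if protocol.kind != "none" else 0.0
    half_fibre = (protocol.fibre_length_mm / tissue.sigma / 2.0
                  if protocol.kind == "fibre" else 0.0)
    xmin = min(xmin, centre[0] - reach)
    xmax = max(xmax, centre[0] + reach)
    ymin = min(ymin, centre[1] - reach, centre[1] - half_fibre)
    ymax = max(ymax, centre[1] + reach, centre[1] + half_fibre)
    xmin -= margin
    xmax += margin
    ymin -= margin
    ymax += margin
    nx = max(int(round((xmax - xmin) * voxels_per_unit)), 3)
    ny = max(int(round((ymax - ymin) * voxels_per_unit)), 3)
    return make_grid((xmin, xmax, ymin, ymax), nx, ny, depth_h=depth_h,
                     D=D, lam=lam, nu_c=nu_c)


def run_treatment(tissue: Tissue, params: VCBMParams, death_params: DeathParams,
                  protocol: Protocol, seed: int, hours: int = 792,
                  dt_pde: float = 0.1, grid_kwargs: dict | None = None,
                  record_every: int = 24,
                  expand_margin: float = 10.0) -> tuple[Tissue, pd.DataFrame]:
    """Administer a protocol to a grown tumour and simulate ``hours`` on.

    Returns the final tissue and the recorded time series (volume, cell
    counts, TME and fibre drug mass).
    """
    rng = np.random.default_rng(seed)
    tissue = tissue.copy()
    grid = build_treatment_grid(tissue, protocol, **(grid_kwargs or {}))
    # uptake sinks need tumour-cell Voronoi areas up front
    tum = np.flatnonzero(tissue.tumour_mask)
    tissue.voronoi_area = lattice.voronoi_areas(
        tissue.positions, tissue.bounds, subset=tum,
        mirror_margin=6.0 * tissue.spacing)
    grid, fib = administer(protocol, tissue, grid)
    sigma3 = tissue.sigma**3

    fibre_rows = fibre_col = None
    length_model = None
    if fib is not None:
        yc = grid.y_centres
        length_model = fib.L / tissue.sigma
        fibre_rows = np.flatnonzero((yc >= fib.y0) & (yc <= fib.y0 + length_model))
        fibre_col = grid.voxel_index((fib.x_F, yc[fibre_rows[0]]))[0]
        assert len(fibre_rows) == fib.J

    n_sub = max(int(round(1.0 / dt_pde)), 1)
    dt = 1.0 / n_sub
    rows: list[dict] = []
    _record(rows, 0, tissue, grid, fib)
    for t in range(1, hours + 1):
        for s in range(n_sub):
            t_now = (t - 1) + s * dt
            if fib is not None and fib.total_mass() > 1e-12:
                bc_model = np.maximum(grid.values[fibre_rows, fibre_col], 0.0)
                fib, flux_phys = fibre_step(fib, bc_model / sigma3, t_now, dt)
                released = flux_phys * fib.seg_len * dt  # ug per cross-section
                yc = grid.y_centres[fibre_rows]

                def flux_fn(y, yc=yc, released=released, dt=dt, hy=grid.hy):
                    j = int(np.argmin(np.abs(yc - y)))
                    return released[j] / (hy * dt)

                deposit_line_flux(grid, fib.x_F, fib.y0, length_model,
                                  flux_fn, dt)
            step_field(grid, tissue, None, dt)
        vcbm_step(tissue, params, death_params, grid.lookup, rng,
                  expand_margin=expand_margin)
        if t % record_every == 0 or t == hours:
            _record(rows, t, tissue, grid, fib)
    return tissue, pd.DataFrame(rows)


@dataclasses.dataclass
class RunResult:
    tissue: Tissue
    series: pd.DataFrame
    seed: int


def run_protocol(params: VCBMParams, death_params: DeathParams,
                 protocol: Protocol, seed: int, grow_kwargs: dict | None = None,
                 treat_hours: int = 792, dt_pde: float = 0.1,
                 grid_kwargs: dict | None = None,
                 burn_in: Tissue | None = None) -> RunResult:
    """Grow (or reuse) an untreated tumour to the trigger volume, then
    treat.  ``burn_in`` short-circuits the growth phase with a pre-grown
    tissue (paired-arm designs)."""
    if burn_in is None:
        gk = dict(grow_kwargs or {})
        gk.setdefault("stop_volume", protocol.start_volume)
        tissue, _ = grow_tumour(params, seed=seed, **gk)
    else:
        tissue = burn_in
    proto = dataclasses.replace(protocol)
    proto._administered = False
    tissue, series = run_treatment(tissue, params, death_params, proto,
                                   seed=seed + 1_000_003, hours=treat_hours,
                                   dt_pde=dt_pde, grid_kwargs=grid_kwargs)
    return RunResult(tissue=tissue, series=series, seed=seed)
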