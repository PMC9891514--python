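"""In-silico study designs and the synthetic-data generator.

Tumour size is reported the way calipers would measure it: width is the
longest tumour diameter (twice the largest radial extent of tumour cells
from the tumour centroid), length the diameter along the perpendicular
axis, and volume = width * length^2 / 2 scaled by sigma^3 (sigma = 0.1728
mm per model unit).  Outcomes classify as eradicate (< 1 mm^3), stabilise
(< initial volume) or growth.

The module provides ensemble runners, the placement/dose sweep, the
pairwise parameter sensitivity grid, a convergence analysis, and generators
for the synthetic calibration fixtures (cumulative release curves, cell
counts, viability fractions, control growth percentiles) with sidecar JSON
recording the generating parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import DeathParams, VCBMParams
from .fibre import ReleaseLaw, simulate_release_invitro
from .lattice import Tissue
from .simulate import grow_tumour, run_protocol

SIGMA_DEFAULT = 0.1728

# Desk-scale study conditions: a reduced arena for the directional
# placement/dose comparisons (full-scale defaults are n = 500 replicates on
# a domain of ~10^6 cells; these sizes keep a 50-replicate paired comparison
# tractable on one CPU, see docs/methods.md).
DESK_SCALE = {
    "n_rows": 28, "n_cols": 28, "stop_volume": 1.5, "max_hours": 700,
    "treat_hours": 72, "dt_pde": 0.2, "n": 50, "dose": 500.0,
}

SENSITIVITY_WEIGHTS = (0.25, 0.75, 1.25, 1.75, 2.25)
SENSITIVITY_PARAMS = ("p0", "p_MCC", "d_max", "g_age", "p_age")
INJECTION_DISTANCES_MM = (0.0, 0.9, 1.7, 2.5, 3.5)
FIBRE_DISTANCES_MM = (0.0, 0.9, 1.7, 2.5, 3.5, 4.3)


@dataclasses.dataclass
class Outcome:
    """Result of one treated (or control) run."""

    series: pd.DataFrame
    final_volume: float
    classification: str
    seed: int


def tumour_volume(tissue: Tissue, sigma: float | None = None,
                  mode: str = "caliper") -> float:
    """Caliper-style tumour volume in mm^3.

    mode 'caliper' (default): width * length^2 / 2 * sigma^3 with width and
    length the tumour diameters along the principal radial axis and its
    perpendicular.  mode 'squared' is the alternative literal reading
    width^2 * length^2 * sigma^3.
    """
    sigma = tissue.sigma if sigma is None else sigma
    tm = tissue.tumour_mask
    if not tm.any():
        return 0.0
    pts = tissue.positions[tm]
    centre = pts.mean(axis=0)
    rel = pts - centre
    r = np.linalg.norm(rel, axis=1)
    imax = int(np.argmax(r))
    width = 2.0 * r[imax]
    if width == 0.0:
        return 0.0
    u = rel[imax] / r[imax]
    perp = np.abs(rel[:, 0] * (-u[1]) + rel[:, 1] * u[0])
    length = 2.0 * perp.max()
    if mode == "caliper":
        return float(width * length**2 / 2.0 * sigma**3)
    if mode == "squared":
        return float(width**2 * length**2 * sigma**3)
    raise ValueError(f"unknown volume mode {mode!r}")


def classify_outcome(final_v: float, initial_v: float) -> str:
    """Eradicate (< 1 mm^3), stabilise (< initial volume) or growth."""
    if final_v < 1.0:
        return "eradicate"
    if final_v < initial_v:
        return "stabilise"
    return "growth"


def run_ensemble(run_fn, n: int, base_seed: int = 0) -> dict:
    """n independent seeded runs of ``run_fn(seed) -> pandas.Series-like
    volume series``; returns per-time mean/sd and the final volumes.

    The summary depends only on the seed set, not the execution order.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    finals = []
    all_series = []
    failures = 0
    for i in range(n):
        try:
            series = run_fn(base_seed + i)
        except Exception:  # per-run failures excluded, counted
            failures += 1
            continue
        all_series.append(series)
        finals.append(float(np.asarray(series)[-1]))
    if not all_series:
        raise RuntimeError("every replicate failed")
    lengths = {len(s) for s in all_series}
    m = min(lengths)
    arr = np.vstack([np.asarray(s)[:m] for s in all_series])
    return {
        "n": len(all_series),
        "failures": failures,
        "mean": arr.mean(axis=0),
        "sd": arr.std(axis=0, ddof=1) if len(all_series) > 1 else np.zeros(m),
        "finals": np.array(finals),
        "sem_final": (np.std(finals, ddof=1) / np.sqrt(len(finals))
                      if len(finals) > 1 else 0.0),
    }


def convergence_analysis(run_fn, ns=(10, 50, 100), base_seed: int = 0) -> pd.DataFrame:
    """Standard error of the ensemble-mean final volume versus n.

    Under Monte-Carlo scaling the SEM shrinks like 1/sqrt(n); the returned
    table includes the fitted log-log slope (ideal -0.5).  Each ensemble
    uses a disjoint seed block so the estimates are independent.
    """
    rows = []
    for block, n in enumerate(ns):
        summ = run_ensemble(run_fn, n, base_seed=base_seed + 100_000 * block)
        rows.append({"n": n, "mean_final": summ["finals"].mean(),
                     "sem_final": summ["sem_final"]})
    df = pd.DataFrame(rows)
    slope = np.polyfit(np.log(df["n"]), np.log(df["sem_final"]), 1)[0]
    df.attrs["loglog_slope"] = float(slope)
    return df


def sensitivity_grid(base_params: VCBMParams, run_fn, n: int = 10,
                     weights=SENSITIVITY_WEIGHTS, params=SENSITIVITY_PARAMS,
                     base_seed: int = 0) -> pd.DataFrame:
    """Pairwise perturbation grid of mean final tumour volume.

    For every ordered parameter pair (a, b) and weight pair (wa, wb) the
    mean final control volume over n replicates is recorded; diagonal
    blocks (a == b) vary the single parameter.  ``run_fn(params, seed)``
    must return a final volume.
    """
    rows = []
    for a in params:
        for b in params:
            for wa in weights:
                for wb in weights:
                    if a == b and wa != wb:
                        continue
                    w = {a: wa} if a == b else {a: wa, b: wb}
                    try:
                        scaled = base_params.scaled(**w)
                    except ValueError:
                        rows.append({"param_a": a, "param_b": b, "w_a": wa,
                                     "w_b": wb, "mean_final_volume": np.nan,
                                     "flag": "invalid"})
                        continue
                    finals = [run_fn(scaled, base_seed + i) for i in range(n)]
                    rows.append({"param_a": a, "param_b": b, "w_a": wa,
                                 "w_b": wb,
                                 "mean_final_volume": float(np.mean(finals)),
                                 "flag": ""})
    return pd.DataFrame(rows)


def placement_sweep(params: VCBMParams, death_params: DeathParams,
                    protocol_kind: str, distances_mm=None, doses=(500.0,),
                    n: int = 10, n_sites: int = 1, base_seed: int = 0,
                    release: ReleaseLaw | None = None,
                    start_volume: float = 100.0,
                    grow_kwargs: dict | None = None,
                    treat_hours: int = 792, dt_pde: float = 0.1,
                    grid_kwargs: dict | None = None,
                    burn_ins: list | None = None) -> pd.DataFrame:
    """Outcome table over (placement distance, dose).

    Each cell holds the per-replicate final volume and classification plus
    the modal classification, long format.  ``burn_ins`` optionally supplies
    one pre-grown tissue per replicate, shared across cells (paired design).
    """
    from .dosing import Protocol

    if distances_mm is None:
        distances_mm = (FIBRE_DISTANCES_MM if protocol_kind == "fibre"
                        else INJECTION_DISTANCES_MM)
    rows = []
    for d_m in distances_mm:
        for dose in doses:
            for i in range(n):
                proto = Protocol(kind=protocol_kind, n_sites=n_sites, d_m=d_m,
                                 total_dose=dose, release=release,
                                 start_volume=start_volume)
                burn = None if burn_ins is None else burn_ins[i].copy()
                res = run_protocol(params, death_params, proto,
                                   seed=base_seed + i, grow_kwargs=grow_kwargs,
                                   treat_hours=treat_hours, dt_pde=dt_pde,
                                   grid_kwargs=grid_kwargs, burn_in=burn)
                v0 = float(res.series["volume_mm3"].iloc[0])
                vf = float(res.series["volume_mm3"].iloc[-1])
                rows.append({"kind": protocol_kind, "n_sites": n_sites,
                             "d_m_mm": d_m, "dose_ug": dose,
                             "replicate": i, "seed": base_seed + i,
                             "initial_volume": v0, "final_volume": vf,
                             "classification": classify_outcome(vf, max(v0, 1.0 + 1e-9))})
    df = pd.DataFrame(rows)
    modal = (df.groupby(["d_m_mm", "dose_ug"])["classification"]
             .agg(lambda s: s.mode().iloc[0]).rename("modal_classification"))
    return df.merge(modal, on=["d_m_mm", "dose_ug"])


def grow_burn_in_cohort(params: VCBMParams, n: int, base_seed: int,
                        **grow_kwargs) -> list[Tissue]:
    """n independent drug-free tumours grown to the treatment trigger,
    reusable across the arms of a paired comparison."""
    return [grow_tumour(params, seed=base_seed + i, **grow_kwargs)[0]
            for i in range(n)]


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_fixtures(kind: str, outdir, seed: int = 0, noise: float = 0.0,
                      params: dict | None = None) -> dict:
    """Write a synthetic calibration fixture CSV plus a sidecar JSON with
    the generating parameters.

    kinds: 'release' (cumulative in vitro release via the forward fibre
    model, multiplicative noise), 'counts' (exponential cell growth),
    'viability' (endpoint viability under aliquot dosing via the well
    model), 'growth' (control VCBM volume percentiles).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    p = dict(params or {})
    if kind == "release":
        p.setdefault("k", 5e-5)
        p.setdefault("eps", 0.1)
        p.setdefault("d_const", 3e-6)
        p.setdefault("c0", 500.0)
        p.setdefault("a_out", 0.08)
        p.setdefault("r_total", 0.05)
        p.setdefault("L", 5.0)
        p.setdefault("n_replicates", 3)
        # autosampler-style dense sampling through the burst (3-min), then
        # 15-min to 10 h and 12-hourly through the 3-week sustained phase;
        # the reported curve is the replicate mean.  The schedule is chosen
        # so the burst parameter k is well identified at assay noise levels.
        times = np.asarray(p.setdefault(
            "times", list(np.unique(np.concatenate([
                np.arange(0.05, 2.01, 0.05), np.arange(2.25, 10.1, 0.25),
                [12.0, 15.0, 18.0, 21.0], np.arange(24.0, 505.0, 12.0)])))), float)
        law = ReleaseLaw(kind="fvm", k=p["k"], eps=p["eps"],
                         d_const=p["d_const"], c0=p["c0"])
        rel = simulate_release_invitro(law, p["r_total"], p["L"], p["a_out"], times)
        reps = rel[None, :] * (1.0 + noise * rng.standard_normal(
            (int(p["n_replicates"]), len(rel))))
        rel = np.maximum(reps.mean(axis=0), 0.0)
        if noise > 0:
            from scipy.optimize import isotonic_regression

            rel = isotonic_regression(rel).x  # cumulative quantity
        df = pd.DataFrame({"time_h": times, "cumulative_released_ug": rel})
        path = outdir / "release.csv"
    elif kind == "counts":
        p.setdefault("phi", 0.03)
        p.setdefault("n0", 1e4)
        times = np.asarray(p.setdefault("times", list(np.arange(0.0, 121.0, 12.0))), float)
        counts = p["n0"] * np.exp(p["phi"] * times)
        counts = counts * (1.0 + noise * rng.standard_normal(len(counts)))
        df = pd.DataFrame({"time_h": times, "count": np.maximum(counts, 1.0)})
        path = outdir / "counts.csv"
    elif kind == "viability":
        from .calibration import WellModelParams, viability_curve

        p.setdefault("phi", 0.03)
        p.setdefault("delta_m", 0.05)
        p.setdefault("ic50", 0.5)
        p.setdefault("lam", 0.05)
        p.setdefault("aliquot_times", [24.0, 48.0, 72.0])
        p.setdefault("aliquot_concentrations", [2.0, 1.0, 0.5])
        p.setdefault("dose_scales", [0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0])
        p.setdefault("n_replicates", 3)
        wp = WellModelParams(phi=p["phi"], delta_m=p["delta_m"], ic50=p["ic50"],
                             lam=p["lam"], aliquot_times=p["aliquot_times"],
                             aliquot_concentrations=p["aliquot_concentrations"])
        v = viability_curve(wp, np.asarray(p["dose_scales"], float))
        reps = v[None, :] * (1.0 + noise * rng.standard_normal(
            (int(p["n_replicates"]), len(v))))
        v = reps.mean(axis=0)
        df = pd.DataFrame({"dose_scale": p["dose_scales"],
                           "viability_fraction": np.clip(v, 0.0, 1.2)})
        path = outdir / "viability.csv"
    elif kind == "growth":
        vp = VCBMParams(**p.get("vcbm", {}))
        n = p.setdefault("n", 5)
        hours = p.setdefault("hours", 120)
        series = []
        for i in range(n):
            _, s = grow_tumour(vp, seed=seed + i, max_hours=hours,
                               n_rows=p.setdefault("n_rows", 24),
                               n_cols=p.setdefault("n_cols", 24))
            series.append(s["volume_mm3"].to_numpy())
        m = min(len(s) for s in series)
        arr = np.vstack([s[:m] for s in series])
        t = np.arange(m) * 24.0
        df = pd.DataFrame({
            "time_h": t,
            "volume_p25": np.percentile(arr, 25, axis=0),
            "volume_p50": np.percentile(arr, 50, axis=0),
            "volume_p75": np.percentile(arr, 75, axis=0),
        })
        p["vcbm"] = dataclasses.asdict(vp)
        path = outdir / "growth.csv"
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    df.to_csv(path, index=False)
    sidecar = {"kind": kind, "seed": seed, "noise": noise,
               "params": {k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
                          for k, v in p.items()}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)
    return {"path": str(path), "sidecar": sidecar, "data": df}
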