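"""Fitting procedures for the model's rate parameters.

Three fitters mirror how the platform is calibrated against bench data:

* ``fit_release_curve`` -- nonlinear least squares of the single
  cross-section fibre model (well-mixed exterior of effective volume
  a_out) against a cumulative in vitro release curve, for (k, D_const,
  C0, A_out).
* ``fit_growth_rate`` -- exponential growth rate phi from cell counts.
* ``fit_viability`` -- drug kill parameters (delta_m, IC50) from endpoint
  viability under impulse ("aliquot") dosing, using the simplified
  well-mixed ODE model with phi and the drug decay rate lambda held fixed.

A Latin-hypercube search estimates the remaining tumour-growth parameters
(g_age, d_max, p0, p_MCC) by minimising the mean squared distance between
simulated and target volume series.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .fibre import ReleaseLaw, simulate_release_invitro


@dataclasses.dataclass
class WellModelParams:
    """Parameters of the well-mixed in vitro model.

    State (P_L, P_D, C): live cells grow at rate phi and die at
    delta_m*C/(C+IC50); drug decays at lam between aliquots and jumps by
    ``aliquot_concentrations[i]`` at ``aliquot_times[i]``.
    """

    phi: float = 0.03
    delta_m: float = 0.05
    ic50: float = 0.5
    lam: float = 0.05
    aliquot_times: tuple = (24.0, 48.0, 72.0)
    aliquot_concentrations: tuple = (2.0, 1.0, 0.5)

    def __post_init__(self):
        if self.delta_m < 0 or self.ic50 <= 0:
            raise ValueError("delta_m >= 0 and ic50 > 0 required")
        ts = list(self.aliquot_times)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("aliquot times must be strictly increasing")


@dataclasses.dataclass
class ReleaseFitParams:
    """Fitted in vitro release parameters."""

    k: float
    d_const: float
    c0: float
    a_out: float
    eps: float = 0.1
    residual: float = 0.0


@dataclasses.dataclass
class LHSConfig:
    """Latin-hypercube search design over (g_age, d_max, p0, p_MCC)."""

    bounds: dict
    n_samples: int = 1000
    n_reps: int = 30
    seed: int = 0
    target_series: np.ndarray | None = None

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.n_samples < 1 or self.n_reps < 1:
            raise ValueError("n_samples and n_reps must be >= 1")


def well_model_rhs(state, params: WellModelParams):
    """Right-hand side between aliquots: growth, Michaelis-Menten kill,
    drug decay.  Kill moves live cells to dead, so d(P_L + P_D)/dt =
    phi * P_L identically."""
    p_l, p_d, c = state
    kill = params.delta_m * c / (c + params.ic50)
    return np.array([
        params.phi * p_l - kill * p_l,
        kill * p_l,
        -params.lam * c,
    ])


def simulate_well(params: WellModelParams, t_end: float, y0=(1.0, 0.0, 0.0),
                  rtol: float = 1e-9, atol: float = 1e-12) -> np.ndarray:
    """Integrate the well model to t_end with exact impulse handling:
    integrate to each aliquot time, add the aliquot mass to C, restart."""
    t = 0.0
    y = np.asarray(y0, dtype=float)
    events = [(float(ta), float(ca)) for ta, ca in
              zip(params.aliquot_times, params.aliquot_concentrations)
              if ta < t_end]
    for ta, ca in events:
        if ta > t:
            sol = solve_ivp(lambda _, s: well_model_rhs(s, params), (t, ta), y,
                            rtol=rtol, atol=atol, method="LSODA")
            y = sol.y[:, -1]
            t = ta
        y[2] += ca
    if t_end > t:
        sol = solve_ivp(lambda _, s: well_model_rhs(s, params), (t, t_end), y,
                        rtol=rtol, atol=atol, method="LSODA")
        y = sol.y[:, -1]
    return y


def viability_curve(params: WellModelParams, dose_scales: np.ndarray,
                    t_end: float = 72.0) -> np.ndarray:
    """Endpoint viability P_L(treated)/P_L(untreated) for scaled aliquot
    concentrations (a dilution series of the same schedule)."""
    untreated = np.exp(params.phi * t_end)  # P_L(0)=1, no drug
    out = np.empty(len(dose_scales))
    for i, s in enumerate(np.asarray(dose_scales, dtype=float)):
        p = dataclasses.replace(
            params,
            aliquot_concentrations=tuple(s * np.asarray(params.aliquot_concentrations)))
        y = simulate_well(p, t_end)
        out[i] = y[0] / untreated
    return out


def fit_growth_rate(times, counts) -> tuple[float, float]:
    """Least-squares exponential growth rate phi for N(t) = N(0) e^(phi t).

    Returns (phi_hat, residual_norm).  Fit is linear in log space (exact
    for noiseless data) refined by nonlinear least squares on the counts.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 3:
        raise ValueError("need at least 3 counts")
    if (counts <= 0).any():
        raise ValueError("counts must be positive")
    slope, logn0 = np.polyfit(times, np.log(counts), 1)

    def resid(p):
        return p[1] * np.exp(p[0] * times) - counts

    sol = least_squares(resid, x0=[slope, np.exp(logn0)], method="lm")
    return float(sol.x[0]), float(np.sqrt(2 * sol.cost))


def fit_viability(dose_scales, viability, schedule: WellModelParams,
                  t_end: float = 72.0, n_starts: int = 5,
                  seed: int = 0) -> tuple[float, float, dict]:
    """Fit (delta_m, IC50) to endpoint viability fractions.

    ``schedule`` fixes phi, lam and the aliquot schedule (concentrations
    from the calibrated release model); ``dose_scales`` are the dilution
    factors of the measured conditions.  Raises if the data carry no kill
    signal (all viability ~= 1), where delta_m is unidentifiable.
    """
    dose_scales = np.asarray(dose_scales, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if np.all(viability > 0.99):
        raise ValueError("viability ~1 at all doses: delta_m unidentifiable")
    rng = np.random.default_rng(seed)

    def resid(x):
        dm, ic50 = np.exp(x)
        p = dataclasses.replace(schedule, delta_m=dm, ic50=ic50)
        return viability_curve(p, dose_scales, t_end) - viability

    best = None
    starts = [(0.05, 1.0)] + [
        (10 ** rng.uniform(-2.5, 0.0), 10 ** rng.uniform(-1.5, 1.5))
        for _ in range(n_starts - 1)
    ]
    for dm0, ic0 in starts:
        sol = least_squares(resid, x0=np.log([dm0, ic0]), method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    dm, ic50 = np.exp(best.x)
    return float(dm), float(ic50), {"residual": float(np.sqrt(2 * best.cost))}


def fit_release_curve(times, cumulative, r_total: float = 0.05, L: float = 5.0,
                      eps: float = 0.1, M: int = 24, n_starts: int = 3,
                      seed: int = 0, clean: bool = False) -> ReleaseFitParams:
    """Fit (k, D_const, C0, A_out) of the single cross-section fibre model
    to a cumulative release curve.

    Non-monotone data raise unless ``clean=True`` (isotonic pre-clean by
    pool-adjacent-violators, which does not bias the late-time slope the
    way a running maximum would).  Parameters are optimised in log space
    with seeded multi-start trust-region least squares on relative
    residuals.
    """
    times = np.asarray(times, dtype=float)
    cumulative = np.asarray(cumulative, dtype=float)
    if (np.diff(cumulative) < -1e-9 * max(cumulative.max(), 1.0)).any():
        if not clean:
            raise ValueError("cumulative release must be nondecreasing "
                             "(pass clean=True to pre-clean isotonically)")
        from scipy.optimize import isotonic_regression

        cumulative = isotonic_regression(cumulative).x
    rng = np.random.default_rng(seed)
    plateau = cumulative.max()

    def forward(x):
        # clamp so optimizer excursions cannot overflow exp
        k, d_const, c0, a_out = np.exp(np.clip(x, -60.0, 60.0))
        law = ReleaseLaw(kind="fvm", k=k, eps=eps, d_const=d_const, c0=c0)
        return simulate_release_invitro(law, r_total, L, a_out, times, M=M)

    scale = np.maximum(cumulative, 0.05 * plateau)

    def resid(x):
        # relative residuals: measurement noise is multiplicative
        return (forward(x) - cumulative) / scale

    v_f = np.pi * r_total**2 * L
    starts = [np.log([1e-4, 1e-5, plateau * 1.3, 2.0 * v_f])]
    for _ in range(n_starts - 1):
        starts.append(np.log([
            10 ** rng.uniform(-5.0, -3.0), 10 ** rng.uniform(-6.5, -4.5),
            plateau * rng.uniform(1.05, 2.5), v_f * 10 ** rng.uniform(-0.5, 1.0)]))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0=x0, method="trf", x_scale="jac",
                                max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("release-curve fit failed from every start")
    k, d_const, c0, a_out = np.exp(best.x)
    return ReleaseFitParams(k=float(k), d_const=float(d_const), c0=float(c0),
                            a_out=float(a_out), eps=eps,
                            residual=float(np.sqrt(2 * best.cost)))


def lhs_search(config: LHSConfig, simulator) -> tuple[dict, pd.DataFrame]:
    """Latin-hypercube search for VCBM growth parameters.

    ``simulator(sample: dict, seed: int) -> volume series`` is evaluated
    ``n_reps`` times per sample against ``config.target_series`` (mean
    squared residual over the overlapping horizon).  Returns the argmin
    sample and the full table; fully reproducible from ``config.seed``.
    Failed samples are flagged with infinite residual, not fatal.
    """
    names = list(config.bounds)
    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    unit = sampler.random(config.n_samples)
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    samples = qmc.scale(unit, lo, hi)
    target = np.asarray(config.target_series, dtype=float)
    rows = []
    for si, x in enumerate(samples):
        sample = dict(zip(names, x))
        residuals = []
        failed = False
        for r in range(config.n_reps):
            try:
                series = np.asarray(simulator(sample, config.seed + 7919 * si + r),
                                    dtype=float)
            except Exception:
                failed = True
                break
            m = min(len(series), len(target))
            residuals.append(float(np.mean((series[:m] - target[:m]) ** 2)))
        rows.append({**sample, "sample_index": si,
                     "mse": np.inf if failed else float(np.mean(residuals)),
                     "flag": "failed" if failed else ""})
    table = pd.DataFrame(rows)
    best_row = table.loc[table["mse"].idxmin()]
    best = {n: float(best_row[n]) for n in names}
    best["mse"] = float(best_row["mse"])
    return best, table
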