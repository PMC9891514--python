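# Methods

## The model

`pdacsim` simulates a pancreatic (PDAC) tumour growing in a 2-D cross
section of healthy tissue and its response to gemcitabine delivered
locally, either as free-drug point injections or from an implanted
drug-eluting polymeric fibre.  It is a hybrid model: cells are discrete
agents, drug is a continuum field.

### Cell world (Voronoi cell-based model)

Cell centres are points in a rectangle; cell shapes are the Voronoi
polygons of the centres, clipped to the rectangle so every cell volume
`W_i` is finite; mechanics act on springs along the Delaunay edges.  The
initial tissue is a hexagonal packing of healthy cells with mature rest
length `s` (one model unit); one central cell is converted to a cancer
cell to seed the tumour.

Each hour, in fixed order:

1. **Drug death.**  Every cancer/MCC cell draws death with probability
   `1 - exp(-beta*dt)`, `beta = delta_m * C/(C + IC50)` using the voxel
   concentration nearest its centre (Michaelis–Menten pharmacodynamics).
   Dead cells keep their position and disintegrate over `d_age` hours;
   each incident rest length shrinks by `s_ij/d_age` per hour and the
   record is removed when the clock expires, leaving empty space.
2. **Disintegration bookkeeping** for previously killed cells.
3. **Proliferation.**  A cancer/MCC cell off cooldown and fully mature
   divides with probability `p_d = p0*(1 - d_neut/d_max)` for
   `d_neut <= d_max`, else 0, where `d_neut` is the distance to the
   nearest healthy cell centre (nutrient proxy; cells beyond `d_max`
   are quiescent — the necrotic core) and `p0 = 1 - exp(-phi*dt)`.
   Contact inhibition: no division if every Delaunay neighbour is closer
   than `s/p_age`.  Mother and daughter are placed `s/p_age` apart at a
   uniform random angle about the mother's prior position; the daughter's
   rest lengths grow linearly from `s/p_age` to `s` over `g_age` hours;
   the daughter's first proliferation cooldown is Poisson(mean 50) hours
   (cell-cycle heterogeneity), the mother resets to `g_age`.
4. **MCC differentiation.**  A boundary cancer cell (one with a healthy
   Delaunay neighbour) converts, with probability `p_MCC` per hour, its
   lowest-id healthy neighbour in place into a mesenchymal-like cancer
   cell (EMT); MCCs then move, proliferate and die like cancer cells.
5. **Mechanics.**  Overdamped Hooke relaxation
   `dr_i = lambda_m * sum_j u_ij (s_ij - |r_ij|)` over Delaunay
   neighbours, with `r_ij = r_i - r_j`, so stretched springs attract and
   compressed springs repel.
6. **Geometry rebuild** (Delaunay, clipped Voronoi areas) and **domain
   expansion**: when a tumour cell comes within 10 model units of the
   populated boundary, whole hexagonal rings of fresh healthy tissue are
   appended outside the current rectangle.

One model unit is `sigma = 0.1728` mm.  Tumour volume is measured the
way calipers measure it: `width * length^2 / 2 * sigma^3`, width the
longest tumour diameter through the tumour centroid and length the
diameter along the perpendicular axis.  (An alternative literal reading
`width^2*length^2*sigma^3` is available behind a flag.)  Outcomes at the
horizon classify as *eradicate* (< 1 mm^3), *stabilise* (< initial
volume) or *growth*.

### Drug in the microenvironment

`C(x, y, t)` obeys `dC/dt = D lap C - lambda C - uptake + sources` on a
voxel grid with no-flux boundaries.  The solver is a conservative
finite-volume scheme: diffusion advances by backward Euler with a cached
sparse LU factorisation; decay, which commutes with diffusion, is applied
as an exact exponential factor; each cancer/MCC cell removes drug from
the voxel containing its centre at rate `nu_c * W_i * C` with the sink
integrated implicitly (`C /(1 + dt*u)`), which preserves non-negativity
for any step without clipping.  Deposits are single-voxel (point
injections; ties at voxel faces resolve to the lower index) or per-row
line deposits (the fibre).  A mass ledger (decay, uptake, source, in ug)
is accumulated every sub-step so conservation can be audited; the closed
system conserves mass to round-off.

The field advances with sub-steps (default 0.1 h, desk studies 0.2 h)
between the hourly agent updates, reflecting the separation of timescales
between diffusion and cellular events.

### Drug inside the fibre

The implant is a thin cylinder (radius `r_total`, length `L`, physical
mm) whose interior concentration obeys radially symmetric diffusion with
the swelling-controlled diffusivity `D_F(t) = k/(t + eps) + D_const`:
large at implantation (burst) and decaying to the slow sustained rate.
The cross-section is discretised into `M` concentric annuli (zero-area
inner face at r = 0, so no ghost value is needed) and advanced
implicitly; the outer boundary is Dirichlet at the local exterior
concentration (continuity condition `F(r_total, y, t) = C(x_F, y, t)`),
one cross-section per TME voxel row spanned by the fibre.  The release
flux per unit length is computed from the discrete mass decrement, so
fibre mass lost equals TME mass gained exactly (first-order operator
splitting within each sub-step).  Units: the radial solver works in mm;
only concentrations cross the interface, converted by `sigma^3`; released
mass in ug is unit-free.

Against the classical Bessel-series solution for diffusion out of a
cylinder with zero surface concentration, the solver at M = 200 agrees
to ~1e-4 in released fraction.

### Prescribed release profiles

Four alternative release laws replace the radial solver behind the same
interface, each parameterised by a rate `gamma` (and half-effect `eta`
for the sigmoid shapes) and each conserving the load `C0`:

* constant: rate `gamma*C0` until exhausted (empty at `t = 1/gamma`);
* exponential: rate `gamma * remaining`, so `remaining = C0 e^(-gamma t)`;
* Emax: cumulative `R(t) = C0 * gamma t/(gamma t + eta)` (hyperbolic,
  front-loaded);
* Imax: rate `gamma C0 eta/(eta + gamma t)`, cumulative
  `C0 eta log(1 + gamma t/eta)` capped at `C0` (slowly waning).

The exact functional forms of the sigmoid laws were an open design
choice; these were selected for the described qualitative behaviour
(front-loaded vs sustained, both conserving total drug) and are isolated
behind `ReleaseLaw` so alternatives can be swapped without touching the
solvers.

### Dosing protocols

A protocol fires once, when the measured tumour volume first reaches the
trigger (default 100 mm^3; desk studies use a reduced trigger).  Free
drug: 1 site at distance `d_m` from the tumour centroid, or 4 sites at
quarter turns each carrying `C0/4`.  Fibre: the line source is placed at
horizontal offset `d_m/sigma`, vertically centred on the tumour.  The
drug grid is sized at administration to cover tissue, sites and fibre
with a margin; cells that later expand past it read the nearest boundary
voxel.

### Calibration

* **Release curve** (`fit_release_curve`): the in vitro assay is modelled
  with a single cross-section and a well-mixed exterior of effective
  volume `A_out`, so release plateaus at `C0*A_out/(A_out + V_fibre)`;
  `A_out` is an effective scaling, not the physical bath volume.
  (k, D_const, C0, A_out) are fitted by trust-region least squares in log
  space on relative residuals (measurement noise is multiplicative), with
  seeded multi-start; `eps` is held fixed.  Non-monotone data are
  rejected unless isotonic pre-cleaning (PAVA) is requested — PAVA rather
  than a running maximum, which would bias the late-time slope.  A
  Fisher-information analysis of the assay design guided the synthetic
  sampling schedule (below): `A_out` is intrinsically weakly identified
  (~17% at assay noise) and is treated as a nuisance parameter in
  recovery checks; the release parameters (k, D_const, C0) are identified
  to ~4–6%.
* **Growth rate** (`fit_growth_rate`): `phi` from `N(t) = N0 e^(phi t)`,
  log-linear solution refined by nonlinear least squares.
* **Kill parameters** (`fit_viability`): a well-mixed ODE model — live
  cells grow at `phi` and move to the dead pool at the Michaelis–Menten
  rate; drug decays at `lambda` and jumps at scheduled aliquot times
  (impulse dosing handled exactly by integrate–jump–restart).  With `phi`
  and `lambda` fixed, (delta_m, IC50) are fitted to endpoint viability
  `P_L(72 h treated)/P_L(72 h untreated)` across a dilution series of the
  aliquot schedule.  All-ones viability is reported as unidentifiable
  rather than silently fitted.  The in vitro sample-and-replace dilution
  is ignored in the forward model (optional correction flag).
* **Growth parameters** (`lhs_search`): Latin-hypercube sample (default
  1000 samples x 30 replicates) over (g_age, d_max, p0, p_MCC),
  minimising the mean squared distance to a target volume series;
  reproducible from the seed; failed samples are flagged, not fatal.

### Synthetic data generator

No experimental data ship with the package; `generate_fixtures` creates
the three calibration inputs (plus control-growth percentiles) from the
forward models, with generating parameters in a sidecar JSON:

* *release*: triplicate cumulative curves with multiplicative noise per
  replicate, reported as the replicate mean, sampled densely through the
  burst (3-min), 15-min to 10 h, then 12-hourly to 3 weeks — a schedule
  chosen a priori so the burst parameter k is well identified at 2%
  assay noise;
* *counts*: exponential growth with multiplicative noise;
* *viability*: the well model across a 7-point dilution series,
  triplicate with multiplicative noise, reported as the mean.

What these fixtures do not emulate: correlated measurement drift,
detection limits, plate effects, sampling-dilution artefacts, or any
biological deviation from the forward models (the recovery tests are
deliberate inverse crimes — they validate the fitters, not the models'
realism against wet-lab data).

## Default parameters

Fitted values from the original bench data are not distributed; defaults
are this package's own choices, all configurable.

| parameter | default | units | rationale |
|---|---|---|---|
| `phi` | 0.03 | /h | in vitro PDAC doubling ~23 h |
| `g_age` | 24 | h | cell-cycle delay |
| `age_mean` | 50 | h | Poisson birth-age mean |
| `p_age` | 2 | — | daughters born at s/2 |
| `d_max` | 15 | model units | proliferative rim thickness |
| `p_MCC` | 5e-4 | /h | MCCs remain a small minority of the tumour |
| `d_age` | 48 | h | dead-cell disintegration |
| `lambda_m` | 0.3 | — | stable overdamped relaxation |
| `D` | 12 | units^2/h | ~0.36 mm^2/h gemcitabine diffusivity / sigma^2 |
| `lambda` | 0.1 | /h | ~7 h tissue half-life |
| `nu_c` | 0.05 | /h per unit vol | per-cell uptake |
| `delta_m` | 0.05 | /h | maximal kill rate |
| `IC50` | 0.1 | ug/unit vol | half-effect concentration |
| `k` | 5e-5 | mm^2 | burst scale; with `eps` gives ~35% release in 30 min |
| `eps` | 0.1 | h | burst timescale |
| `D_const` | 3e-6 | mm^2/h | sustained release over ~3 weeks |
| `C0` | 500 | ug | fibre load |
| `r_total`, `L` | 0.05, 5 | mm | fibre geometry |
| `A_out` | 0.08 | mm^3 | effective bath volume (67% plateau) |

## Problem sizes

Full-scale studies in this field run n = 500 replicates on domains of
order 10^6 cells.  The desk-scale defaults used by the test suite and the
acceptance script (`pdacsim.experiments.DESK_SCALE`) are the package's
own reduced study conditions: a 28 x 28-cell initial tissue, tumours
grown drug-free to a 1.5 mm^3 trigger volume (a few hundred tumour
cells), 72 h of treatment, PDE sub-step 0.2 h, and n = 50 paired
replicates per arm (each replicate's grown tumour is shared between the
arms of a comparison, and compared with a one-sided Wilcoxon signed-rank
test).  Convergence analyses use 20 x 20 tissues grown 168 h with
disjoint seed blocks per ensemble size.

## Numerical choices

* Implicit (unconditionally stable) solvers everywhere a PDE is stepped;
  the TME operator is factorised once per (grid, dt) and reused.
* Sub-stepping: drug field at 0.1–0.2 h inside the 1 h agent step.
* Boundary Voronoi cells are clipped to the domain rectangle by
  mirroring boundary-adjacent points across the sides, which makes the
  rectangle an exact Voronoi boundary; areas therefore tile the domain
  exactly.
* Tie-breaks are deterministic (lowest id for centre/neighbour ties,
  lower voxel index for deposits on voxel faces); a single seeded
  generator drives all stochastic draws in documented order, so any
  workflow is reproducible from (config, seed).
* Degenerate inputs (collinear centres, zero-radius fibres, non-monotone
  release data, empty tissues) raise informative errors rather than
  propagating NaNs.

## Known limitations

* 2-D only; no stroma/ECM, vasculature, interstitial pressure or drug
  resistance; cell uptake is a point sink rather than surface flux.
* The domain-expansion trigger interprets "distance to empty space" as
  distance to the populated bounding rectangle; interior holes left by
  disintegrated cells do not trigger expansion (cells relax into them).
* Healthy cells neither proliferate nor take up drug; tissue is a
  passive mechanical and nutrient-proxy background.
* `A_out` (release-bath scaling) is weakly identified from a single
  release curve; its recovery is reported but not guaranteed.
* The treated-tumour comparisons at desk scale demonstrate directional
  orderings (placement, multiplicity), not calibrated effect sizes at
  in vivo scale.
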