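# Methods

This note documents the models implemented in `pcbrtm`, their
assumptions, the default parameterization, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Compartmental model

Each flask × congener pair is one autonomous ODE system; congeners do
not interact, and every compartment is tracked as mass (or a
concentration times a fixed phase volume), so the sum over compartments
is an exact invariant. Units: water/air concentrations ng/L, sediment
ng/g, PUF ng, SPME ng/cm, time days; transfer velocities cm/d with
areas in cm² (1 L = 1000 cm³). All unit reconciliation happens inside
the right-hand-side assembly; no term is ever in anything but ng/d.

**Aqueous phase and bioavailability.** `c_w` is the *total* aqueous
concentration, dissolved plus cell-sorbed. With a linear isotherm on
suspended cells (`k_cell`, L/g; dose `x_cells`, g/L) the freely
dissolved fraction is the bioavailability factor

    B = 1 / (1 + k_cell · x_cells).

Every exchange process — sediment sorption, air–water transfer, SPME
uptake, biodegradation — sees `B·c_w`. This is one consistent reading of
a bioavailability correction: cells are a passive, instantaneously
equilibrating reservoir riding in the water column. Cells are present
only in the overlying water; porewater has B = 1.

**Biodegradation** is first order on the freely dissolved pool of the
overlying water only (`k_bio·B·c_w·V_w`, ng/d), not in porewater and
not on sorbed phases: aerobic dioxygenase attack needs dissolved
substrate and oxygen, and settled beds are oxygen-limited. Degraded
mass accumulates in an explicit `m_degraded` sink so conservation
audits hold with active degradation. Loss of degrader activity over
time is *not* modelled mechanistically; it is represented, when needed,
by refitting `k_bio` over time windows.

**Shaken sediment** is a well-mixed two-site sorbent. Each site relaxes
by a linear driving force toward its share of the sorption equilibrium:

    dS_i/dt = −k_i · (S_i − f_i · f_avail · (K_d/1000) · B·c_w),

with `f_fast + f_slow = 1` and `f_avail` the fraction of the inventory
that exchanges at all. When `k_fast = k_slow` the split is unobservable
(a property test pins this).

**Nonshaken sediment** is a bed of identical spherical particles.
Intraparticle transport is retarded pore diffusion,
`∂c/∂t = (D_eff/R_f)(1/r²)∂/∂r(r²∂c/∂r)`, with a single lumped
retardation factor `R_f = 1 + ρ·K_d·(1−ε)/ε` supplied as one number
(any linear local-equilibrium sorption variant collapses onto it), a
zero-flux centre, and the porewater concentration as a Dirichlet
surface boundary. Porewater exchanges with the overlying water across a
boundary-layer film, `k_bl·A_int·(c_pw − B·c_w)`. The porewater volume
`v_pw` (default 0.004 L) is the pore space of 10 g of dry sediment at
bed porosity 0.5 and solids density 2.5 g/cm³.

**Air–water exchange** is a two-film flux
`v_aw·A_aw·(B·c_w − c_a/K_H)` with the dimensionless Henry constant
`K_H` (air/water concentration ratio).

**Samplers** remove real mass from their source compartments. The PUF
is air-side-limited uptake toward a PUF–air partition equilibrium; the
SPME coating is first-order relaxation toward
`K_fw·V_coat·(B·c_w)` per cm. The *observation* model for SPME adds the
fouling term: the reported fiber load is

    m_apparent = m_spme + α_fiber · (1 − B) · c_w · V_w / L_fiber,

a fraction `α_fiber` of the cell-sorbed aqueous pool attributed to
fouled fiber and spread over the deployed length. Fouling never enters
the dynamics — it is a measurement artefact, which is exactly why it
can reverse the aqueous treatment/control comparison while the airborne
comparison still shows a decrease.

## Default parameters

The registry ships an *illustrative* three-congener set (a di-, tri-
and tetrachlorobiphenyl with round-number partition coefficients of
realistic magnitude); real work should load a property CSV. Transport
and sampler defaults were chosen once so that a default flask
reproduces the scale of real microcosm measurements (control PUF
accumulations of order 10²–10³ ng by day 35; SPME loads of order
1 ng/cm; treatment/control contrasts of tens of percent):

| parameter | default | units | meaning |
|---|---|---|---|
| `m_sed`, `v_w`, `v_a` | 10, 0.1, 0.15 | g, L, L | 250-mL flask, 1:10 sediment:liquid |
| `k_fast`, `k_slow` | 0.5, 0.02 | 1/d | two-site desorption rates |
| `f_avail`, `f_fast` | 0.5, 0.6 | – | available fraction, fast share |
| `v_aw` | 100 (shaken) / 20 (still) | cm/d | air–water transfer velocity |
| `k_bl` | 0.5 | cm/d | bed boundary-layer velocity |
| particle | R = 50 μm, D_eff = 0.4 cm²/d, R_f = 1000, ε = 0.5 | | silt-sized, strongly sorbing |
| PUF | 2.5 × 1.9 cm, k = 50 cm/d, K_PUF–air = 10⁵ | | strong air-side sink |
| SPME | 10 μm PDMS, 30 cm, K_fw = 10⁴, k = 2/d, 3.8·10⁻⁸ L/cm | | equilibrium-type sampler |
| `k_cell` | 8 | L/g | B = 1/3 at the 0.25 g/L cell dose |
| `α_fiber` | 0.15 (nonshaken treatments) | – | fouling attribution |
| `k_bio` | 17 (shaken) / 0.6 (nonshaken) for the degradable congener | 1/d | fixed treatment rates |

## Synthetic-data generator

`design_for_scenario` encodes the three study arms: shaken and
nonshaken contaminated-lake sediment (sampling days 3/11/16/35 and
16/35/75) and a nonshaken harbor sediment ~9× more contaminated.
Sediment inventories are partitioned over the three congeners so the
totals and the LC fraction match the two sediments (6350 ng/g with 51%
LC; 59 000 ng/g with 44% LC). Measurements are drawn per replicate as
`truth × LogNormal` with unit mean — multiplicative noise is the
generative counterpart of analysing log₁₀-transformed masses — at
default CVs of 0.25 (PUF) and 0.35 (SPME), calibration knobs
representing the spread of triplicate measurements rather than
literature constants. Blanks and surrogate recoveries (truncated-normal
in (0, 1.5]) are generated with the same seeding discipline: one
`numpy` generator per call, fully determined by the seed.

What the generator does **not** emulate: full 171-peak congener
profiles of commercial Aroclor mixtures (three peaks stand in for the
LC/non-LC structure), congener co-elution statistics, instrument drift,
correlated replicate errors, time-varying degrader activity, and
anaerobic dechlorination. Passing end-to-end tests therefore show the
*pipeline logic and its statistical behaviour* are right under the
assumed noise model — not that the model reproduces any particular
field dataset.

## Measurement pipeline

The canonical reduction order is **censor → surrogate-correct →
aggregate**. The order matters (correction can lift a censored mass
back across the LOQ) and is pinned by a regression test. Choices made
where the workflow is ambiguous:

- **LOQ** = blank mean + 1.96·SD (sample SD, ddof = 1) — a reporting
  limit for a single measurement. The standard-error variant
  (SD/√n) is available behind `sd_over_sqrt_n=True`.
- **"Below the LOQ"** is strict: a mass exactly at the LOQ is kept.
- **Pairing**: sacrificially sampled triplicates have no natural
  pairing, so the paired t-test pairs by replicate index; Welch's
  two-sample test is available via `pairing="welch"`. Both are exposed
  because neither is canonical for this design.
- **Log offset**: censored zeros enter `log10(mass + ε)` with ε = half
  the smallest positive mass in the comparison set (ε = 0 when no zeros
  are present, so clean comparisons are exactly scale-invariant);
  comparisons touching a zero are flagged `censor_dominated`.
- **No multiple-testing correction** by default (per-time-point tests
  at α = 0.05), matching common practice for these designs.
- Degenerate comparisons (zero-variance paired differences) return
  `p = NaN` with a `degenerate` flag instead of raising.

## Calibration

`fit_parameters` minimizes a weighted sum of squared residuals between
replicate-mean observations and the forward model, by default in log₁₀
space with the same ε rule as the pipeline. The optimizer is L-BFGS-B
within bounds, started from a seeded Latin-hypercube sample (default 8
starts; the model surface in `k_bio` is smooth and monotone, so few
starts suffice); results are deterministic given the seed. Model
performance per series is the squared Pearson correlation between
time-averaged observations and predictions — a shape metric that is
blind to affine offsets, reported as a diagnostic, not used as the
objective. Time-windowed refits — the way to represent degrader
activity that decays between sampling windows — are done by filtering
the long table to a day range before fitting; there is no separate
windowing API. Identifiability beyond bounds-hit flags is out of scope.

## Numerics

- **Integration**: `scipy.integrate.solve_ivp`, LSODA by default
  (shaken treatments mix 17/d degradation with 0.02/d desorption),
  relative tolerance 10⁻⁸. Trajectory values more negative than
  `10·tol·max|y|` raise; smaller excursions are clipped to zero.
- **Particle grid**: conservative finite volumes (shell mass change
  telescopes exactly to the surface flux). Shell edges are graded
  quadratically toward the particle surface,
  `r_k = R(1 − (1 − k/n)²)`, which resolves the early-time release
  front; at 50 shells the fractional-uptake error against the classical
  series solution stays below 0.3% down to τ = 10⁻³.
- **Series oracle**: the eigenfunction series (200 terms) for
  τ ≥ 10⁻³; the equivalent short-time form `6√(τ/π) − 3τ` below, where
  the series truncates poorly.
- **Closed-form equilibrium**: all capacities are linear in the freely
  dissolved concentration, so the no-degradation equilibrium is a
  one-line mass balance; it doubles as an oracle for long-horizon
  integrations (agreement to <0.1% per phase is asserted).
- **Problem sizes**: simulation-study tests use 12 particle shells,
  3 congeners, 20 calibration seeds and 50 generator seeds — sizes at
  which the statistical assertions are stable from seed to seed.

## Known limitations

- No oxygen dynamics, microbial growth/decay, or temperature
  dependence; `k_bio` is piecewise-constant at best.
- Single representative particle radius; no particle-size distribution
  or nonlinear isotherms.
- The fouling model is the simplest linear attribution consistent with
  the reversal signature; the true fiber–cell interaction is unknown.
- The illustrative congener properties are not literature values;
  conclusions about specific congeners require a user-supplied property
  table.
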