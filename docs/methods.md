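# Methods

`tabletpress` is an agent-style, event-driven model of direct-compression
tableting on a rotary press. It resolves the press into four interacting
stages — hopper, filling pipe, feed frame, die — and advances them one
die-fill event at a time, so that every simulated tablet carries a complete,
lot-resolved record of where its powder came from and what state it was in
at every stage. This note documents the physical sub-models, the default
parameterisation, the numerics, and the choices that were genuinely open.

## Material flow

**Event clock.** One event is one die fill/compression/ejection. Events
occur every `60 / (turret_rpm * n_stations)` seconds (0.75 s, i.e. 80
tablets/min, at the default 20 rpm turret with 4 stations). A single die
agent represents all stations alternately; only one die is compressed at a
time on the real press, so no information is lost at the per-tablet level.

**Hopper.** A pure reservoir: a timeline of `(start time, material, lot)`
intervals. The hopper material of the moment is stamped into every freshly
created pipe layer; cumulative dispensed mass is the reference side of the
conservation ledger.

**Filling pipe.** The pipe is two concentric plug-flow regions: a fast
central *midstream* and a slower *outer ring*, with an integer velocity
ratio (default 2:1). Both are discretised into layers of one shared height,
chosen so that one event's extraction — one outer layer plus
`velocity_ratio` midstream layers — is exactly the dosing volume:

    h_layer = V_dos / (A_outer + velocity_ratio * A_mid)

Layers never mix radially or axially; the radial split plus the velocity
difference is the entire residence-time model of the pipe. With the default
geometry (45 mm pipe, 33 mm midstream, 200 mm height) a layer is 0.286 mm
tall and the pipe holds 699 layers, giving transit times of ~4.4 min
(midstream) and ~8.7 min (outer ring) — which is what delays and smears the
response of tablet properties to a feed change. The pipe inner diameter and
height are not geometric constants of any specific press here; they are
exposed in `PressConfig` as structural parameters.

**Feed frame.** Twelve interspaces of the paddle wheel are modelled as
twelve compartments of fixed capacity (default `3 * V_dos` ≈ 2.1 cm³),
each an ideal, instantaneously mixed stirred tank. Per event the wheel
advances `round(paddle_rpm * n_compartments / fills_per_min)` positions
(9 by default); every compartment that lands on or sweeps past the inlet
position is topped up to capacity from an inlet holdup fed by the pipe
extraction, mixing ideally with its residual powder. The die is filled from
the compartment over the die plus the ones rotating in behind it, with
descending shares (default 40/35/25), each donating its share of the dosing
volume and losing it. Because 9 and 12 share a factor of 3, the compartments
fall into three fixed 4-cycles, each permanently serving one donor share;
this is a consequence of quantising the rotation per event and is invisible
in the tablet series at the default kinematics.

**Mass ledger.** All bookkeeping is in absolute masses per `(material,
lot)`. After every event the identity

    hopper dispensed = pipe + inlet holdup + feed frame + Σ tablet masses

is asserted at relative 1e-9 (the pipe side re-summed layer by layer, not
taken from the running total). A violation aborts the run with a
timestamped diagnostic. In practice the ledger holds at ~1e-14.

## Compaction physics

All mixing is volume-additive: specific volumes add with mass fractions, so
every mixed density is the mass-weighted harmonic mean of its components.

* **Fill density and weight.** `1/rho_fill = Σ x_i / rho_fill,i`;
  tablet mass `m = π (D/2)² h_dos rho_fill`. The fill densities are the
  *apparent consolidated* bulk densities (0.73 / 1.41 g/cm³ for the two
  DCPA grades), above the cylinder bulk densities (0.68 / 1.33), because
  the paddle wheel consolidates a well-flowing powder into the die; the
  basis is switchable in the config.
* **Compressibility.** The Kawakita model in density form, mixed
  volume-additively:
  `1/rho(P) = Σ x_i/rho0_i · (1+(1−a_i) b_i P)/(1+b_i P)`.
  Inverting it for the stress that produces a given in-die density is, for
  a binary blend, a quadratic in P solved in closed form (numerically
  stable pq-formula; the admissible root is the positive one that
  reproduces the target density through the forward model). More components
  fall back to bracketed root finding on [0, 10⁴] MPa. Below 20 MPa the
  model is evaluated but flagged with a `LowStressWarning`, as the Kawakita
  form is unreliable at very low stress.
* **Press compliance.** The punch distance at maximum force is
  `h = h_min + c·F`, with `c` the machine compliance in mm/kN. The coupled
  system `P = invert(rho(h(P)))`, `F = P·A_die` is solved by bracketed root
  finding on the self-consistency residual (monotone in P) to 1e-6 MPa; a
  relaxed fixed-point iteration was rejected because the iteration map has
  slope ≈ −1 near the solution at realistic compliance, where plain
  iteration oscillates. With `c = 0` the solve reduces exactly to a single
  inversion at `h_min`. The reported `(P, F, h)` triple is exactly
  self-consistent by construction.
* **Elastic recovery.** Two-point calibration per material: state densities
  (at maximum stress, at zero axial stress in-die, and out-of-die) measured
  at a low and a high stress (30/400 MPa). The instantaneous in-die
  recovery is linear in stress (line through the two calibration deltas);
  the slow post-ejection recovery is the mean of the two calibration
  values. For blends, each state density is first mixed volume-additively
  at both calibration stresses and the line is re-derived at blend level; a
  measured-minus-predicted correction offset (per material, linearly
  blended, default 0) completes the prediction.
* **Porosity and strength.** `ε = 1 − rho_out/rho_s,mix` with the mixture
  solid density again harmonic (the consistent volume-additive choice; no
  published rule exists for it). Strength follows the exponential
  porosity-strength law `σ = σ0(x)·e^(−kb(x) ε)` with composition mixing
  rules `σ0(x) = c1·e^(c2 x) + c3` and `kb(x) = m·x + n`, where `x` is the
  mass fraction of the designated reference grade (A150 here).

## Calibration

* `fit_kawakita`: nonlinear least squares of the density form over a
  configurable stress window (default 20–350 MPa, below the model's trust
  floor points are dropped). Starting values come from the data (density at
  the lowest retained stress; an asymptote guess 5 % above the maximum;
  b = 0.01/MPa). R² is reported on density.
* `fit_recovery`: replicate state-density triplets at exactly two stress
  levels are averaged per level; the recovery line is then exact through
  the two points, so noiseless round trips are exact by construction and
  the correction offset is zero for two-point data.
* `fit_rd`: linear least squares of ln σ against porosity (kb = −slope,
  σ0 = exp(intercept)); R² on the fitted log variable. Duplicate-porosity
  data are rejected as ill-conditioned.
* `derive_strength_mixing`: with supports at x = 0, ½, 1 the exponential
  σ0 rule has the closed form `e^(c2/2) = (s1−s0)/(s0.5−s0) − 1`, then c1,
  c3 by linear solve — exact, no iteration. Supports must grow strictly
  and super-linearly (growth ratio > 2), otherwise no exponential fits.
  Under measurement noise c1 and c3 are a nearly degenerate pair (a small
  vertical shift trades against the amplitude); the shape parameters c2,
  m, n and the *evaluated* σ0(x), kb(x) curves are the stable quantities,
  and that is what the recovery tests assert.
* `error_metric_f`: mean absolute relative error with the **simulated**
  value in the denominator, evaluated at matched sampling times.
* Sweeps (`sweep_midstream_diameter`, `sweep_fill_ratios`): rerun the
  changeover scenario over a parameter grid and score the tablet-weight
  series against a reference at the experimental sampling schedule. With a
  simulator-generated reference the generating value scores f = 0 exactly
  (the model is fully deterministic), which is the self-consistency check
  used in the tests.

## The bundled case study

`build_case_study()` assembles, from published constants only, the
changeover of anhydrous dicalcium phosphate from the coarse grade A150
(x50 = 167 µm) to the fine grade A60 (x50 = 64 µm) and back: A150 feed for
1 min, A60 for 12 min, A150 until minute 25; tablets sampled every minute
except every two minutes between minutes 8 and 18. The three feed intervals
carry distinct lot labels, so the two A150 episodes remain traceable in
every tablet.

Two inputs are *not* published and are set here as the package's own
calibration, with these rationales:

* **Machine compliance 0.048 mm/kN** (scenario only; the generic config
  default stays 0). A rigid press would drive the fine-grade tablets to
  unphysical states — in-die densities above the solid density and stresses
  in the thousands of MPa — because the heavier A60 fill meets the same
  3.2 mm punch gap. The real press deflects; 0.048 mm/kN places the
  simulated operating points at ≈64 MPa on pure A150 and ≈185 MPa around
  75 wt% A60, bracketing the reported ≈60 and ≈200 MPa anchors with
  balanced error.
* **Recovery calibration triplets.** Only the calibration *procedure* and
  its stresses (30/400 MPa, ten tablets) are published, not the densities.
  The scenario synthesises them: in-die densities from each grade's
  Kawakita fit, instantaneous recovery growing linearly to 3 % of the
  in-die density at 400 MPa, slow recovery a constant 0.015 g/cm³ —
  modest values appropriate for a brittle, fragmenting excipient.

A known and deliberate feature of the resulting transition: tablet weight
and compression stress track the A60 fraction exactly monotonically, but
tensile strength is *valley-shaped* at low A60 content (plateau 0.449 MPa,
valley 0.434 MPa near x_A60 ≈ 0.27, fine-grade plateau 1.048 MPa). The
exponential σ0 mixing rule collapses by an order of magnitude over the
first half of the composition axis, faster than the porosity reduction can
compensate; only in the A60-rich half does strength rise with the fraction.
The shape tests assert exactly this structure rather than global
co-monotonicity.

## Synthetic data

The fixture generators produce every dataset the calibration loop needs,
from known ground truth: compressibility curves (default grid = the six
calibration stresses 30–400 MPa; a dense 20–350 MPa grid emulates a
compaction-simulator curve), compactability curves over a porosity grid
spanning 0.15–0.55, replicate recovery triplets, and reference tablet-weight
time series sampled on the experimental schedule. Noise models:
multiplicative Gaussian (density-like data; 1 % for compressibility, 0.1 %
for the precise state-density triplets) and lognormal (strength data, 5 %),
all seeded and exactly reproducible. Reference series can carry a 1.5 %
weight CV and an 11.7 % composition RSD, mirroring typical replicate
scatter of weighing and dye-assay measurements.

What passing tests on these fixtures do and do not show: they demonstrate
that the fitting code recovers the generating model and that the simulator
is self-consistent — not that the underlying constitutive models describe
any particular real powder. Real compaction data contain systematic
deviations the generators deliberately omit (volume contraction of real
mixtures against the additive rule, stress-range-dependent model error,
segregation), so calibration against real curves will always carry model
error on top of the noise floor quantified here.

## Numerical choices

* Units: g/cm³, cm internally (mm at the API surface for geometry), MPa;
  force = stress × die area, reported in kN.
* Blend fractions are validated to sum to 1 within 1e-9 and stored
  renormalised, so long mixing chains cannot drift.
* Quadratic root selection uses the stable `q = −(b + sign(b)√disc)/2`
  form; candidate roots are accepted only if positive and verified against
  the forward model at relative 1e-6.
* Unreachable targets (below the zero-stress blend density or at/above the
  blend asymptote) raise a dedicated `UnreachableDensityError`.
* The published A60 Kawakita fit has an asymptote (3.177 g/cm³) *above*
  the solid density (2.849 g/cm³); this is tolerated with a warning, since
  the fit is only trusted inside its 20–350 MPa window, but it is the
  reason a rigid-press extrapolation to heavy fills misbehaves — see the
  compliance discussion above.
* The simulation contains no randomness at all; two runs are bit-identical,
  and byte-identical CSVs are asserted in the tests. Seeds exist only in
  the synthetic-data generators.

## Event ordering

Within one event: fill die → advance pipe and extract → rotate feed frame
(refilling inlet passers from the extracted powder) → compress → eject →
ledger check. Extraction precedes the rotation because refills consume the
extracted material; the net per-event transfer is the same under either
ordering. A small inlet holdup (≈ 0.25 V_dos in steady state) persists
between events because one of the three donors only reaches the inlet on
the following rotation.

## Problem sizes

The default test and acceptance workloads are sized for a laptop-class
single core: the full 25-minute case study (2000 tablets, ~700-layer pipe)
runs in a few seconds; the two structural sweeps (8 diameters + 8 ratio
sets, each a full changeover rerun) in well under a minute; the
parameter-recovery studies use the generator defaults (6–34 points, 10
replicates).

## Known limitations

* No segregation anywhere (hopper, pipe, feed frame) and no powder exchange
  between compartments over or under the paddles; the CSTR cascade is an
  idealisation that is known to be good at high paddle-to-turret speed
  ratios and will degrade for poorly flowing powders.
* Partial die filling is not modelled: an underfilled donor aborts the run
  rather than producing a light tablet.
* The volume-additive density rule ignores the volume contraction real
  fine/coarse mixtures exhibit (small particles filling interstices), which
  biases blend densities low at mid-composition.
* The strength mixing rule is an interpolation device fitted at three
  compositions; its exponential form is the dominant error source for
  mid-composition strength predictions.
* Environmental effects (humidity, temperature) and particle-size-resolved
  mechanics are out of scope; particle sizes are metadata only.
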