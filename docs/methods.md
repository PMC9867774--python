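# Methods

`notchsim` simulates how a homogeneous pool of multipotent pancreatic
progenitor cells (MPCs) resolves into pro-acinar cells (PACs) and bipotent
duct/endocrine progenitors (BPs) through Notch-mediated lateral inhibition
with both trans-activation and cis-inhibition. This note records the model,
the numerical scheme, the calibrated analysis settings, and the design
choices made where more than one reading was defensible.

## Regulatory model

Each epithelial cell carries five concentrations (µM): Hes1 (H), Dll1 (D),
Jag1 (J), Notch receptor (N) and Ptf1a (P).

* **Hes1** is produced under delayed auto-inhibition
  `a_H · K1²/(K1² + H(t−τ0)²)` multiplied by a Notch-signal activation
  factor `s²/(s² + K2²)` with `s = γ2([N·D_t] + [N·J_t])`, and degrades
  with time constant τ_h. The 40-min delay τ0 with a 20-min lifetime makes
  Hes1 an intrinsic oscillator once trans signal is present.
* **Dll1** is produced by Hes1 repression (`a_D·K3²/(K3²+H²)`) plus Ptf1a
  activation (`a_w·P²/(P²+K6²)`); **Jag1** only by Ptf1a
  (`a_J·P²/(P²+K4²)`). Both ligands are consumed by cis-inhibition with
  the cell's own receptor (rate γ1) and trans-interaction with the
  neighbor-mean receptor (rate γ2), and decay with τ_d, τ_j.
* **Notch** is produced at constant rate a_N and consumed by both cis
  complexes and both trans complexes.
* **Ptf1a** integrates Hes1 repression (`a_P·K5²/(K5²+H²) − P/τ_p`), with
  a 120-min turnover that makes it a temporal average of Hes1 — the slow
  variable whose level ultimately separates PAC from BP/MPC.

Bound complexes use the tight-binding approximation
`[XY] = XY/(X+Y)` (0 when both vanish), which is symmetric and never
exceeds the scarcer species; cis and trans channels are computed
independently on current totals (no binding competition). Trans inputs
`D_t, J_t, N_t` are arithmetic means over **all** graph neighbors, with
mesenchymal neighbors contributing zeros — surface cells therefore receive
diluted signal. This boundary dilution is the only positional cue in the
model.

Two parameter presets are built in (`table1_3d`, `table1_twocell`); they
differ in a_H, a_w, a_P, γ2 and the Hill constants K1, K2, K3, K5, K6.
The rates γ1, γ2 are implemented literally as tabulated even though their
printed units (µM·min⁻¹) are dimensionally odd for rates multiplying a
concentration.

### Perturbations

Genotypes and treatments are declarative `PerturbationSpec`s: parameter
overrides (`dll1_ko`: a_D=a_w=0; `jag1_ko`: a_J=0; `dapt`: K2=0.3;
`mln4924`: K2=0.01; `jag1_rescue`: γ1=0.2, a_J=4), boolean masks removing
single cis/trans channels, a transcriptional delay τ applied to both Dll1
production terms (H(t−τ), P(t−τ)), and a Ptf1a timescale factor δ that
multiplies the whole Ptf1a right-hand side and hence changes its speed but
not its fixed point (asserted in tests). The intermediate Jag1 deficiency
of the heterozygous mutant has no published a_J value and is exposed as an
override rather than a preset.

### Explicit-NICD variant

Optionally NICD is tracked as a sixth variable,
`d[NICD]/dt = a_NICD·γ2([N·D_t]+[N·J_t]) − NICD/τ_NICD`, and the Hes1
activation reads `NICD/(a_NICD·τ_NICD)` in place of the instantaneous
trans signal, so the fast-NICD limit reproduces the simplified model
exactly. In the tissue model τ_NICD = 10 min leaves the fate proportions
at their wild-type values; in the two-cell model the ~10-min effective lag
of the filter falls into the same oscillation-death window as a 10-min
Dll1 delay, and the simplified dynamics are recovered in the faster limit
(τ_NICD ≈ 2 min). Slow NICD (τ_NICD = 45 min) flips the transient
progenitor oscillation from anti-phase to in-phase, as expected.

## Geometry

The tissue is a static graph built in three steps.

1. **Packing.** 400 particles start uniformly in a ball whose density
   matches close packing at the pair equilibrium distance
   r* = (5/4)·ln 5 ≈ 2.012 of the potential `V(r) = e^{−r} − e^{−r/5}`
   (ball radius `r*·(3n/(4π√2))^{1/3}`), and take 100 synchronous gradient
   steps of size 0.1 on the summed pair energy of their *current contact
   neighbors* (midpoint rule, refreshed every 5 iterations). Restricting
   forces to contacts is essential: summing the long-range attraction over
   all particles collapses the aggregate far below the pair equilibrium
   spacing and destroys the published tissue architecture, whereas the
   contact-limited relaxation ends with interior cells at spacing ≈ r*
   and 12–14 contacts.
2. **Contact graph.** Cells i and j are neighbors iff no third cell is
   strictly closer to their midpoint than they are themselves (ties keep
   the edge; the KD-tree implementation is tested against a brute-force
   O(n³) oracle).
3. **Mesenchyme labeling.** Convex-hull vertices and their graph neighbors
   are mesenchymal; the interior remainder is epithelial. Across seeds
   this yields ≈150–170 epithelial cells of 400 (mean ≈155; the reference
   tissue reports 143). Mesenchymal cells never evolve; they only dilute
   neighbor means.

An equal-neighbor control graph assigns each epithelial cell its 12
nearest epithelial cells (symmetrized), removing the boundary dilution.

## Numerics

The coupled delay system is integrated with fixed-step classical RK4 on a
uniform grid (default dt = 0.5 min, horizon 3600 min). Delays must be
integer multiples of dt, so whole-step delayed taps are read directly off
the stored grid; the two interior stages read taps at t+dt/2−τ by linear
interpolation of the bracketing stored values, which are always in the
strict past because all delays (≥ 6 min) far exceed dt. History before
t = 0 is constant at the initial condition. The scheme is deterministic
and bit-reproducible; measured convergence order on an analytic problem is
≈ 4, and halving dt from 0.2 to 0.1 changes the two-cell trajectory by
< 10⁻⁴ relative sup-norm. A structurally independent forward-Euler
integrator serves as a cross-check oracle. States are clipped at 0 after
each step; the removal terms vanish with their species, so clipping only
absorbs O(dt⁵) undershoot.

Initial conditions: two-cell runs start from [0.5, 1.1, 0, 1, 0] and
[0.6, 1, 0, 1, 0]; tissue runs start all cells at 0.1 for every variable,
optionally with i.i.d. uniform multiplicative noise (used only by the
equal-neighbor control, which needs explicit symmetry breaking).

## Readouts and classification

Statistics are computed in the 3200–3600 min window. Peaks and troughs of
each Hes1 trace are local extrema with prominence ≥ 5 % of the window
range and separation ≥ 30 min (periods are ~90–160 min); amplitude is
mean(peaks) − mean(troughs), period the mean adjacent-peak interval
(undefined below two peaks). Mean Ptf1a is the window average.

Fates: PAC if mean Ptf1a > θ_P; otherwise BP if the Hes1 amplitude exceeds
θ_A_high, else MPC. The thresholds were placed once in the widest
log-scale gaps of the pooled readout distributions of a reference
wild-type run (`fit_thresholds`): θ_P between the low/high Ptf1a modes,
and the two widest amplitude gaps among non-PAC cells bounding the
intermediate MPC band. The frozen defaults are θ_P = 1.80 µM,
θ_A_low = 0.53 µM, θ_A_high = 3.08 µM (3D preset) and 1.06/0.30/3.01 for
the two-cell preset; every condition is classified with the same numbers.
The classifier is scale-consistent (rescaling inputs and thresholds
together changes nothing).

Bifurcation onset is measured as the first time the Ptf1a coefficient of
variation across *interior* epithelial cells (no mesenchymal contact)
exceeds 0.5. Restricting to interior cells matters: the surface/interior
asymmetry pushes the all-cell CV past any threshold within the first hour,
which says nothing about fate divergence. By the interior metric the
wild-type tissue bifurcates at ~17 h after a long homogeneous phase.

Trace utilities min–max normalize each series to [0, 1] and align first
peaks (constant or peak-free traces are excluded and flagged); the phase
score of two traces is the zero-lag correlation of the mean-subtracted
series (−1 anti-phase, +1 in-phase).

## Problem sizes and run cost

A 400-cell packing takes ~2 s; a full 3600-min tissue run at dt = 0.5
integrates ~150 epithelial cells in ~5 s on one CPU. Multi-seed statistics
in the test suite and the acceptance script use 3–10 geometry seeds and
re-use one shared geometry per sweep so parameter effects are not
confounded by geometry resampling. Solver cross-checks run on shortened
horizons (200–1200 min) at reduced dt where full-length runs would add
nothing but wall time.

## Known limitations

* The equal-neighbor control at the published K2 = 0.08 does not leave the
  progenitor state in this implementation (tested to 10 800 min and ±90 %
  initial noise): the wild-type pattern is boundary-seeded, and the pure
  bulk lateral-inhibition instability appears only at weaker Notch→Hes1
  response (K2 ≈ 0.2), where cells do segregate and PACs scatter without
  radial enrichment. The qualitative no-surface-bias claim is therefore
  exercised at K2 = 0.2.
* MLN4924 lengthens the mean tissue Hes1 period only slightly
  (≈118 → 122 min); the ≈160-min period of the strong-response regime
  appears in the two-cell K2 scan (K2 = 0.05–0.1).
* Removing Jag1 trans-interaction strongly impairs segregation (MPC
  roughly doubles, PAC drops) but does not abolish it.
* The model is deliberately static in space: no division, growth,
  migration, adhesion sorting, or morphogen gradients; mesenchyme is a
  passive signaling boundary. Ligand-specific receptor affinities (Fringe,
  Dll4) and endocrine lateral inhibition are out of scope.
* Synthetic geometry is an idealized spherical aggregate; real buds are
  lobed, with heterogeneous cell sizes and a basement membrane geometry
  the midpoint rule only caricatures. Agreement of fate statistics
  therefore validates the regulatory logic on an idealized scaffold, not
  organ shape.
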