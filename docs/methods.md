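# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `ctpffr`.

## Perfusion correction (Renkin–Crone)

The per-voxel value of a volume-perfusion-CT map is treated as the tracer
transfer constant K1 and converted to true hyperemic MBF by inverting

    K1 = (1 − a·exp(−b/MBF)) · MBF,   a = 0.904, b = 1.203 mL·min⁻¹·g⁻¹.

The map K1(MBF) is strictly increasing (its derivative is bounded below by
1 − a = 0.096), so the inverse is unique; `mbf_from_k1` brackets the root
in [K1, K1/(1 − a)] — the lower end because K1 < MBF everywhere, the upper
because the extraction ratio K1/MBF falls to 1 − a asymptotically — and
solves by Brent's method (vectorised bisection for whole maps). Per-gram ↔
per-mL conversion uses a tissue density of 1.05 g·mL⁻¹ and happens only at
this boundary; territory flow integration consumes per-mL values.

The correction direction is configurable (`correction` in
`PipelineConfig`): real volume-perfusion maps should use `k1_to_mbf`;
synthetic maps generated by this package already store true MBF, so the
synthetic pipeline defaults to `none`. The forward direction `mbf_to_k1`
exists for sensitivity checks.

## Perfusion territories

Voronoi assignment: each masked voxel goes to the outlet terminal node
nearest its centre, unweighted Euclidean distance in physical mm, voxel
centres at `origin + (index + ½)·spacing`, ties to the smallest outlet id.
Seeding by outlet points (rather than whole centerlines) was chosen
because outlets are the entities that receive flow in the boundary-
condition model; the choice is a genuine open point and is isolated in
`assign_territories`.

## Boundary conditions

Inlet: MAP = 0.4·(SBP − DBP) + DBP from brachial cuff pressures (a single
pair per patient; whether cuff readings are taken at rest or hyperemia is
left to the data source). Outlets: `R_i = (MAP − P_v)/Q_i` with P_v = 5
mmHg, `Q_i` the Voronoi-territory integral of Vol·MBF (mL·min⁻¹). The
identity `R_i·Q_i = MAP − P_v` holds exactly by construction and is
asserted in tests. A territory with zero integrated flow (possible in
synthetic data with extreme noise truncation) is flagged and given a
finite resistance ceiling (10⁶ mmHg·min·mL⁻¹) instead of ∞ so the network
stays solvable.

Internal units at this layer are clinical — mmHg and mL·min⁻¹ — so
computed Q and R are directly comparable to catheter-lab magnitudes;
conversion to SI (1 mmHg = 133.322 Pa, 1 mL·min⁻¹ = ⅙·10⁻⁷ m³·s⁻¹)
happens once at the solver boundary.

## Reduced-order hemodynamics

The package deliberately replaces a 3-D finite-volume CFD solve with a
0-D/1-D nonlinear resistor network. The boundary conditions — the actual
contribution of the perfusion-derived model — are preserved exactly; what
is approximated is the intraluminal pressure-drop law:

* **Viscous term.** Poiseuille resistance `8μ/π ∫ r(x)⁻⁴ dx`, integrated
  analytically over each edge through the linearly tapered lumen (constant
  throat radius inside a stenosis). Because the integral is exact, the
  series resistance is independent of the discretisation step; refinement
  only adds pressure sample points (the refinement test requires < 10⁻³
  FFR change on halving the step).
* **Stenosis term.** An empirical quadratic separation loss of Young–Tsai
  form, `ΔP₂ = b·Q|Q|` with `b = (K_t·ρ/2)(1/A_throat − 1/A_ref)²`,
  K_t = 1.52, lumped on the stenosis exit edge.
* **Constants.** Rigid walls; Newtonian blood, μ = 0.0035 Pa·s,
  ρ = 1050 kg·m⁻³.

Mass conservation is enforced at every network node; momentum reduces to
the edge ΔP(Q) law. The nodal system is solved by Newton iteration with
under-relaxation 0.7, initialised at uniform inlet pressure (MAP). Edge
flow is evaluated with the rationalised root
`Q = 2ΔP/(a + sqrt(a² + 4b|ΔP|))`, which is free of the catastrophic
cancellation the textbook quadratic formula suffers as b → 0. Convergence
requires the maximum nodal mass imbalance to fall below 10⁻¹⁰ mL·min⁻¹,
floored by the roundoff level of the stiffest edge (8·ε·g_max·MAP — a
high-conductance edge amplifies the ~ε·|P| noise of pressure differences,
and demanding less than that would loop forever); a stagnation guard
accepts the best iterate if the residual plateaus within 100× of that
floor. Flow direction is modelled root→leaves; a negative converged edge
flow raises a warning rather than an error.

Per-vessel CTP-FFR is `P(query)/MAP` with the query point 20 mm distal to
the stenosis end along the main (largest-radius) continuation — the
pressure-wire convention of the invasive protocol; where the tree ends
earlier, the most distal point is used and flagged. The offset is a
parameter (`readout_offset_mm`) because the exact reporting location of
the CT-derived value is not standardised.

## Synthetic cohort

The generator emulates the structure of a single-centre ischemia-suspected
cohort: ~46% of evaluable vessels ischemic (FFR ≤ 0.80), FFR strata
weighted 22:25:44:12 across the bands ≤ 0.70 / 0.70–0.80 / 0.80–0.90 /
> 0.90, ~82% LAD vs 18% LCX, lesion locations 57/37/6% proximal/middle/
distal, 23% of vessels with calcium score ≥ 400, QCA severities confined
to the 30–90% inclusion window, and voxel spacing 0.625×0.625×1.25 mm.

* **Geometry.** A left-coronary template (left main → LAD with a diagonal,
  LCX with an obtuse marginal) with jittered lengths, directions and leaf
  radii; parent radii are propagated upward by Murray's law
  (r_p³ = Σ r_c³), so every bifurcation satisfies it exactly.
* **Myocardium mask.** The union of spherical shells (3–12 mm) around the
  outlet terminal nodes — the perfusion bed of the left coronary system —
  cut by a plane so the proximal/right-coronary side is absent (the thin
  right-ventricular wall defeats automated contouring, so RCA territories
  are excluded by design). The cut is relaxed automatically if it would
  strip an outlet of its entire Voronoi cell.
* **Ground-truth hemodynamics.** Hyperemic microvascular resistance is
  coupled to perfusion through `MBF = M0·g(FFR)` with the piecewise-linear
  attenuation g(f) = 1 above 0.8 and f/0.8 below — the simplest monotone
  coupling by which ischemia reduces hyperemic flow. Each patient's state
  is the fixed point of: territory resistances from flows → network solve
  → outlet FFRs → flows (damped iteration, tolerance 10⁻¹¹). The
  noise-free MBF map therefore encodes exactly the flows the analysis
  stage re-derives, which makes parameter recovery well-posed and is why
  the noise-free recovery experiment closes to ~10⁻¹⁰ FFR units.
* **Severity inversion.** The percent-diameter stenosis of each evaluable
  vessel is found by Brent root-finding so that the fixed-point vessel FFR
  hits a target drawn from the band mixture above; prevalence and strata
  thus arise from the hemodynamics rather than being painted on. Severity
  is clamped to the configured range (default 30–90%). A consequence: the
  synthetic QCA distribution concentrates where the geometry's FFR–severity
  curve is steep (≈ 55–90%), so QCA-stratum sizes are *not* matched to a
  clinical severity histogram.
* **Noise.** Voxel MBF noise N(0, 0.2 mL·min⁻¹·mL⁻¹) truncated at zero by
  clipping; pressure-wire measurement noise N(0, 0.01) clipped to (0, 1];
  patient-level normal MBF M0 ~ N(2.0, 0.25) mL·min⁻¹·mL⁻¹ (hyperemic).
  The MBF magnitudes are synthetic choices — plausible hyperemic values —
  not measurements.
* **Seeding.** One `SeedSequence([cohort_seed, patient_index])` per
  patient, stream-split into geometry / truth / map-noise / measurement
  generators; identical config + seed reproduces every output byte for
  byte (the run manifest hashes verify this).

**What passing tests do and do not show.** The generator omits scanner
noise and beam hardening, motion, segmentation error, partial-volume
effects, collateral flow and microvascular disease — precisely the factors
that separate CTP-FFR from invasive FFR in patients. Green recovery tests
therefore certify that the pipeline implements its own model
self-consistently (territory bookkeeping, unit conversions, solver
correctness), not that the method attains any particular clinical
accuracy; the published contingency analysis is reproduced from the
printed stratum counts, which is an arithmetic check of the statistics
layer, not a re-analysis of images.

## Diagnostic statistics

Positivity is value ≤ 0.80 for both tests (the boundary is positive;
0.75–0.80 carries a gray-zone flag). Confidence intervals are exact
Clopper–Pearson throughout — reproducible and valid at small counts; the
target table's sensitivity/specificity/accuracy intervals are consistent
with this choice (its PPV/NPV intervals evidently used a different
predictive-value method, which is not replicated). AUC uses the
Mann–Whitney statistic with half credit for ties, oriented so that a lower
FFR estimate is more diseased; the paired DeLong comparison uses
structural components with midranks. McNemar is exact-binomial below 25
discordant pairs and continuity-corrected χ² above; accuracy comparisons
across strata use χ² (Fisher's exact for sparse 2×2). Pearson intervals
use the Fisher z transform. Bland–Altman limits are mean ± 1.96·SD
(ddof = 1). All tests are two-sided at α = 0.05. Per-patient aggregation
(worst-vessel rule) and a logical AND/OR combiner for multiple index
tests are provided but secondary; no claim is made that the combiner
matches any published multi-test column, whose combination rule is
unspecified.

The null-calibration Monte Carlos (n = 60, 500 replicates) use
permuted-label designs: for DeLong, two correlated score vectors with the
labels permuted per replicate; for McNemar, two equally accurate reads
(error rate 0.13, matching the observed diagnostic accuracy) exchanged
within pairs. The DeLong test calibrates to ≈ 0.05. The McNemar rule is
intrinsically conservative: with ~14 expected discordant pairs the exact
test's attainable size oscillates between ~0.01 and ~0.05, and its true
level under this design is ≈ 0.026–0.031, so measured rates can fall
slightly below 0.03 at some seeds. This is a property of the exact test,
not a calibration defect.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| cohort size | 50 patients | ~55 evaluable vessels |
| voxel spacing | 0.625×0.625×1.25 mm | ~20–30k masked voxels/patient |
| solver step | 1 mm | exact integrals make results step-insensitive |
| severity search | Brent, xtol 0.01% diameter | coarse 4 mm step during search |
| Newton | relax 0.7, ≤ 200 iterations | typical 15–25 |
| FFR readout | 20 mm distal | configurable |

## Known limitations

Steady flow only (no pulsatility or wave effects); rigid walls; Newtonian
rheology; no retrograde or collateral flow; single left-coronary template
(no anatomical variants, no RCA); the quadratic stenosis loss is an
empirical fit, least reliable for long, eccentric or serial lesions; the
MBF–FFR coupling of the generator is a modelling convenience, not
physiology fitted to data; per-voxel MBF noise is i.i.d. Gaussian, far
cleaner than scanner reality.
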