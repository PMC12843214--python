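# Methods

## Model overview

`alveomech` solves small-strain plane-strain elasticity on a 2-D
buccolingual cross-section of a single maxillary incisor in its alveolar
housing.  The coordinate frame puts the origin at the cervical line on the
root axis, +x buccal, +y coronal; units are mm–N–MPa, with unit out-of-plane
thickness.  The cross-section is a deliberate desk-scale stand-in for a
patient-specific 3-D model: its purpose is to reproduce the *qualitative*
mechanics of transverse loading protocols — displacement sign patterns,
orderings, and the spatial regime (compression vs tension) of PDL loading —
not absolute displacement or stress magnitudes.  All µm values it prints are
per-unit-thickness quantities of an idealized section and should never be
compared numerically against patient-model outputs.

## Geometry

The section comprises six regions: the tooth (crown rectangle over a
parabolically tapered root), a periodontal-ligament (PDL) band of uniform
thickness wrapping the root to a flat cap under the (truncated) apex,
cancellous bone, buccal and palatal cortical plates of independent
thickness, and an optional corticotomy band.  Root half-width follows
`w(y) = w_c (1 − (1 − τ) (y/L)²)` with `τ` the apical/cervical width ratio.

Defaults (all single config keys, chosen once as a plausible incisor and a
mechanically faithful housing):

| parameter | default | note |
|---|---|---|
| root_length | 13 mm | incisor root |
| crown_height | 5 mm | bracket height above the cervical line |
| root_cervical_width | 6.5 mm | buccolingual |
| root_apical_taper | 0.6 | truncated (rounded) apex; also sets the apical support area |
| pdl_thickness | 0.2 mm | uniform band |
| buccal / palatal cortical thickness | 0.4 / 1.2 mm | thin buccal phenotype |
| cancellous_buccolingual_extent | 3.5 mm | per side, between PDL and plate |
| corticotomy_band_width | 0.2 mm | inner (cancellous-facing) part of the buccal plate |
| basal margin (module constant) | 18 mm | bone column below the apex cap |
| anchor depth (module constant) | 8 mm | mini-implant node line below the crest |

Two of these deserve justification because the qualitative targets depend on
them.  (1) The **basal margin** represents the elastic give of the
surrounding jaw: the fixed boundary is the *inferior (basal) edge* of the
domain only, so the whole dentoalveolar segment can deform elastically over
this column.  That bodily "carry" is what makes the anchored protocol
translate the apex buccally; fixing the lateral outer plate surfaces instead
(the obvious alternative far-field choice) forbids any plate deflection and
makes corticotomy and skeletal anchorage mechanically inert, so it was
rejected.  (2) The **cancellous extent** sets the bending stiffness of the
ridge relative to the PDL: a very narrow ridge sways with the tooth and
smears the marginal stress concentration; at 3.5 mm per side the
conventional-loading compression peak sits robustly in the cervical third of
the buccal PDL, as expected for this loading.

The corticotomy is a material band, not a free slit: the cancellous-facing
part of the buccal plate, from the crest apically by `corticotomy_depth`
(default 3 mm), with stiffness knocked down by 10⁻³ (non-zero to keep the
stiffness matrix regular).  The band width must be smaller than the plate
thickness so the mesh stays conforming and the band stays inside the plate.

## Meshing

The mesher is structured (transfinite): horizontal layers and per-region
column bands whose x-stations follow the sampled root-flank polyline, so
every region boundary is exactly a mesh polyline.  Consequences that the
tests rely on: per-region element areas sum to the outline polygon areas to
machine precision; the mesh is conforming by construction; identical inputs
give bitwise-identical nodes; and swapping the two plate thicknesses mirrors
the node set (and the triangulation — diagonal orientation flips across the
root axis) exactly.  Element size is bounded by `h_pdl` (default 0.1 mm) in
the PDL band and by `h_far` (default 0.5 mm) elsewhere; root-band columns
are additionally capped at 1.8·`h_pdl` so the one-layer PDL cap under the
apex also meets the PDL size bound.  The default production mesh has ≈24 000
constant-strain triangles (≈25 000 dof); one linear solve takes well under a
second on one CPU.

## Materials

Plane-strain isotropic linear elasticity per region; mm–N–MPa internally,
GPa accepted at the config boundary.  Defaults: tooth 18 GPa, cancellous
1 GPa, cortical bone the *study variable* (12.5 or 27.5 GPa — the
density-dependent property varied across runs), PDL 0.68 MPa with ν = 0.45
(a conventional literature-style ligament stiffness).  Poisson ratios of the
hard tissues are 0.3.

The PDL can instead follow a one-term compressible Ogden law,
`W = (2µ/α²) Σ (λ̄ᵢ^α − 3) + K/2 (J − 1)²` with `λ̄ᵢ = J^{−1/3} λᵢ`, defaults
µ = 0.2 MPa, α = 2, K = 100 MPa (near-incompressibility contract
K ≥ 100 µ).  This normalization linearizes to shear modulus µ; the
small-strain Young modulus is `9Kµ/(3K+µ) ≈ 3µ`, verified numerically by a
uniaxial-stress root-finding oracle.  The nonlinear path is solved by
incremental-load total-Lagrangian Newton iteration on the PDL elements (all
other regions stay linear), with the element tangent approximated by forward
differences of the exact internal force; the convergence flag is honest and
non-convergence returns diagnostics rather than raising.  The linear PDL is
the baseline for every scenario result; the Ogden path is an optional
nonlinear variant.  Note that at ν_eq ≈ 0.499 displacement-based
constant-strain triangles stiffen volumetrically, so the Ogden variant is
systematically stiffer than the 0.68 MPa linear default — both paths agree
to 2 % when the linear model is set to the consistent linearization.

## Load protocols

All three protocols carry the same net transverse force (default 1 N,
buccal) so they stay comparable:

* CONVENTIONAL: the full force at the bracket node (buccal crown surface at
  crown height); no corticotomy.  No moments are applied anywhere (no active
  torque expression).
* CORTICOTOMY: same force, with the softened band present (depth 3 mm).
* BPS: corticotomy plus skeletal anchorage; `anchor_force_fraction`
  (default 0.7) of the force is shared equally by the ANCHOR nodes — the
  buccal-plate node line at 8 mm below the crest — and the rest goes to the
  bracket.

The anchor placement is a considered design choice: placing the anchorage at
the corticotomy-band mid-height (1.5 mm below the crest) was tried first and
rejected, because a crest-adjacent push concentrates bone displacement
cervically and cannot carry the root apex buccally — the protocol then still
classifies as tipping, contrary to the behaviour the force system is
designed to produce.  At mid-root depth (where mini-implants are inserted
clinically) the anchored pull carries the segment bodily, producing
translation, the deep shift of peak compression, and the continuous buccal
tensile band.

## Readouts

**Displacement pattern.**  Crown and apex tracking nodes are the mesh nodes
nearest the bracket point and the apex on the root axis.  The pattern rule
is sign concordance only: same-sign buccolingual displacements (both above a
0.01 µm tie tolerance, the numerical noise floor) classify as
translation-dominant, anything else as tipping-dominant.  No magnitude-ratio
threshold is used — a 10:1 crown/apex ratio with equal signs is still
translation by this rule.

**PDL stress profile.**  At 60 arc positions per side (0 = crest,
1 = apex, mid-sample positions), the normal stress `n·σ·n` is evaluated with
`n` the outward root-surface normal and `σ` the (element-constant) stress of
the nearest PDL element by centroid.  Negative is compression.  The root arc
is partitioned into equal cervical/middle/apical thirds.  The peak
compression location is the most negative sample's (side, third).  The
buccal tensile band flag requires the longest contiguous tensile run to
cover ≥ 0.5 of the buccal arc (the coverage threshold is a parameter; the
flag is monotone in it).  The "marginal buccal mean stress" is the mean over
the buccal cervical third, the quantitative shadow of marginal off-loading.

## Measurement analytics and reliability statistics

Measurement tables are CSVs (`segment,pre_mm,post_mm`; U+2212 minus
accepted and normalized) of paired pre/post linear measurements: alveolar
ridge width (bucco-palatal distance between outer cortical plates at
mid-root level) and buccal plate thickness (perpendicular root-surface to
buccal cortex distance).  Changes are always recomputed as `post − pre`,
reported at 2 decimals (half-up, matching clinical table precision) with
full precision retained; sign counts use the reported value, so a change
rounding to 0.00 counts as zero.  Three fixture tables are shipped and
guarded by checksum tests; a dedicated test verifies that every recomputed
change equals the printed change column to 0.01 mm.

Dahlberg error is `sqrt(Σ dᵢ² / 2n)` over duplicate readings.  The ICC is
the two-way random-effects, absolute-agreement, single-measurement
coefficient ICC(A,1), computed from the two-way ANOVA decomposition
(`(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`, k = 2); the variant
choice is isolated behind one function.  The implementation is cross-checked
against pingouin's ICC(A,1) in the test suite.

## Synthetic data

The generator covers the two inputs the pipeline needs without any
downloads.  *Phenotype sampling*: uniform draws of buccal cortical thickness
and PDL thickness within a named class; the thin class spans 0.18–1.11 mm of
buccal cortical thickness (the clinically observed pre-treatment spread) —
every draw in that range builds a valid geometry.  *Measurement studies*:
true site values ~ Normal(mean, sd) truncated at 0 (physical lengths),
treatment effect ~ Normal added to form the post value, duplicates = true
value + independent examiner noise per reading.  Under this model the
Dahlberg error estimates the examiner noise sd and the ICC estimates
σ_b²/(σ_b² + σ_e²), which the tests verify at n = 1000–2000 with fixed
seeds.  What the generator does *not* emulate: segment-to-segment anatomical
correlation, examiner drift/bias between readings, and registration error —
so passing recovery tests validates the statistics, not the robustness of
clinical acquisition.  All randomness flows from an explicit integer seed
through `numpy.random.default_rng`; there is no hidden global state.

## Numerical choices

Constant-strain triangles with a direct sparse factorization (fixed
"natural" column ordering) make every linear result bitwise reproducible.
Stresses are reported element-constant, without nodal smoothing.
Verification oracles: patch test exact to 1e-12; cantilever tip deflection
within 2 % of the Euler–Bernoulli + shear closed form at 0.1 mm mesh (on a
crossed-diagonal mesh, which is markedly less stiff in bending than a
two-triangle split); global equilibrium residual below 1e-8 N; mirrored
phenotype + mirrored load reproduces the mirrored field below 1e-9 mm; crown
displacement changes by < 2 % from the default mesh to half size.  Newton
tolerance is 1e-8 relative residual; degenerate inputs (inverted elements,
missing constraints, empty node sets, zero-area regions) raise typed errors
naming the offending stage or region.

## Known limitations

* The 2-D plane-strain idealization preserves sign patterns and orderings
  but not magnitudes; µm values are per-unit-thickness and incomparable to
  3-D patient models.
* The purely elastic effect of corticotomy alone is small here (≈0.1–0.2 %
  more crown displacement): the PDL dominates the socket's series
  compliance, so softening part of the plate barely changes it.  The
  ordering (corticotomy > conventional) is deterministic and
  refinement-stable, but the large displacement gains reported clinically
  for corticotomy arise from biology (regional acceleratory phenomenon) and
  from 3-D structural release that a cross-section cannot capture.
* Tipping also produces a genuine apical compression zone on the palatal
  side; in this geometry it is ~10–16 % weaker than the marginal buccal peak
  under conventional loading.  With materially different defaults the two
  can rival each other.
* No bone remodeling, viscoelasticity, anisotropy, density-field mapping, or
  multi-tooth interaction; boundary conditions idealize the far field as a
  rigid basal support.
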