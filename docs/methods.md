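# Methods

This note documents the models, conventions and numerical choices behind
`hippomorph`, and what the synthetic cohort does and does not emulate.

## Mesh model and geometry

All analyses operate on closed, orientable, corresponded triangle meshes:
every surface in a cohort shares one template topology (identical vertex
count and face list, tracked by a `topology_id` hash), so vertex-wise
statistics are meaningful. Enclosed volume is the divergence-theorem
signed-tetrahedron sum ∑ det(v₀,v₁,v₂)/6 over faces, exact for polyhedra and
translation invariant for closed surfaces; the absolute value removes the
global orientation sign. Vertex normals are area-weighted averages of
incident face normals, flipped outward when the winding convention points
inward (centroid test). Degenerate (zero-area) faces are skipped with a
warning rather than rejected, since extreme synthetic deformation can
collapse a triangle. On a refining icosphere the volume error decreases
monotonically (0.2% at subdivision level 4) and normals converge to radial;
at finite resolution area-weighted normals are tilted up to ~0.01 rad, which
is irrelevant at the 0.1 mm/year scale of the slope analyses.

On-disk format is legacy-VTK ASCII polydata (points, triangle polygons,
optional named per-vertex `SCALARS`), written with 17 significant digits so
read-back reproduces float64 exactly; ascii PLY is supported read-only. The
original study's template had 13,222 vertices over both hippocampi; the
package's icosphere-based templates have 10·4^L+2 vertices per hemisphere
(1,284 total at the default level 3, 5,124 at level 4). Every analysis is
per-vertex and resolution-agnostic, so the working resolution trades only
Monte-Carlo smoothness against runtime; the acceptance script and tests use
level 3.

## Synthetic cohort

The generator emulates a three-group longitudinal design — healthy controls
(CON, n=51), olanzapine-treated (OLZ, n=67) and haloperidol-treated (HAL,
n=67) first-episode patients — scanned at weeks 0/12/24/52/104 with
group-specific retention (controls are scheduled only at weeks 0/12/52).
Retention is independent per visit; week 0 is always present.

**Template.** A bent, tapered ellipsoid ("banana") per hemisphere, half-axes
≈ (19.5, 7.6, 5.65) mm chosen so the control left volume is ≈ 2,530 mm³;
the right mesh is the mirrored left, and subjects' right surfaces carry an
additional linear scale of 1.06 (≈ 19% volume asymmetry, right > left).
Vertices are labeled by longitudinal thirds (head/body/tail) and a lateral
half so deformation fields can target anatomy.

**Baseline shape.** Subject vertices are
(template + (d_g(i) + b_s(i))·n_i)·size_s, where d_g is the group mean
deformation (patients: up to −0.45 mm over a smoothed head∪lateral weight,
giving ≈ 12% volume reduction), b_s are smooth zero-mean per-hemisphere
subject fields (SD 0.25 mm), and size_s ~ N(1, 0.04) reproduces the ≈ 300 mm³
between-subject volume SD. Smooth fields are white vertex noise put through
k=10 rounds of half-neighbor averaging on the mesh graph, then centered and
rescaled, so fields are spatially coherent but individually variable.

**Longitudinal drift.** The displacement of vertex i at week t along the
subject's outward baseline normal is (s_g(i) + m_s + f_s(i))·t/52 + ε, with

- s_g the group mean slope field: mean −0.011 / −0.022 / −0.066 mm/year for
  CON/OLZ/HAL with spatial SD 0.057 / 0.057 / 0.077 — all groups share one
  smooth spatial pattern (weighted toward the head and lateral zones) whose
  amplitude and offset are group-specific. Group contrasts are therefore a
  near-uniform level shift plus a small amplitude difference, not a fixed
  anatomical signature;
- m_s ~ N(0, 0.057/0.057/0.077) a subject-level slope offset, which makes the
  SD of subject-mean slopes match the configured group SDs;
- f_s smooth per-hemisphere subject fields (SD 0.12/0.12/0.20 mm/year; HAL
  patchiest) carrying the *individually variable* strongly-contracting
  regions;
- ε i.i.d. per-visit measurement noise of 0.10 mm, which with the control
  visit schedule yields a within-subject vertex-slope scatter of
  ≈ 0.19 mm/year — the value implied by the reference percentages (≈ 52%
  negative, ≈ 36% below −0.068) under near-normality.

This split is the design's central scientific statement: treatments differ
in how much of the surface contracts strongly (level + amplitude + subject
variance), while the location of strong contraction varies across
individuals. Consequently subject-level percentage statistics separate the
groups, but per-vertex group contrasts stay small — the dissociation the
vertex-wise FDR analysis is meant to exhibit. Covariates (sex proportions,
total gray matter volume, gamma-distributed illness duration) are drawn at
the group means/SDs of the emulated study.

The generator does **not** emulate realistic hippocampal anatomy beyond the
zone labels, scanner/site effects, registration error structure (noise is
i.i.d. along normals), correlated dropout, or any clinical response
process. Passing tests therefore show that the *pipeline* is unbiased and
calibrated under a plausible generative model — not that real data satisfy
that model.

Determinism: one `SeedSequence` per cohort, spawned per subject; identical
seeds give byte-identical outputs. The group truth fields come from a fixed
internal seed so the "true" effect is constant across replicate cohorts.

## Statistics

- **Least-squares slopes** are closed-form OLS; slopes are undefined (and the
  subject excluded, with a warning) without two distinct visit weeks. Volume
  slopes are reported in mm³/week; vertex slopes in mm/year (exactly 52
  weeks/year).
- **Mann–Whitney U** uses midranks; p-values are exact by enumeration (a
  count-distribution recurrence) when both n ≤ 8 with no ties, otherwise a
  normal approximation with tie and continuity corrections. The two-sided
  exact p is 2·min(P(U≤u), P(U≥u)) capped at 1. The approximation is within
  ~0.011 of exact at n=8 (worst near mid-range p). The vertex-wise variant
  applies the same policy per vertex.
- **BH-FDR** is the step-up rule; rejected = {p ≤ p₍k*₎},
  k* = max{k : p₍k₎ ≤ kq/m}.
- **Mixed-design ANOVA (group × hemisphere)** uses the exact two-level
  reduction: group from a one-way ANOVA on subject means, hemisphere and
  interaction from the within-subject differences (intercept test with
  unweighted group means — type-III style for unbalanced groups — and a
  one-way ANOVA on the differences). It matches `pingouin.mixed_anova` to
  six significant digits in tests.
- **ANCOVA** is the extra-sum-of-squares F for the group factor after the
  covariates in a least-squares GLM; rank deficiency is reported with the
  offending column named.
- **Wilks' Λ MANOVA** computes Λ = det(W)/det(W+B) via slogdet with Rao's F
  approximation (exact at p=1 and k=2); a singular within-scatter raises an
  error instructing component truncation, and `shape_manova` pre-truncates to
  n − k − 1 components.
- **Mixed model for volumes** is a REML random-intercept linear model
  (statsmodels MixedLM) with categorical week, group and their interaction;
  interaction/week dummy columns for empty design cells are dropped by a
  greedy left-to-right rank filter (main effects win when a week is observed
  in one group only). Time and group×time are Wald F tests on the fixed
  effects with residual denominator df. Volumes constant within every subject
  short-circuit to p=1 (the REML fit is degenerate there). Null simulations
  put its interaction type-I error at 0.05 ± 0.01.
- **Post hocs** are Fisher's-LSD pooled-t comparisons (the pooled
  within-group variance of the preceding ANOVA), Bonferroni available by
  flag; two-sided p-values everywhere.

## Thresholds for "large-magnitude" slopes

The thresholds are the control mean ± 1 SD of a control slope distribution,
with three implemented readings: `subject_means` (moments of per-subject
mean slopes — the default), `pooled_vertices` (moments of all control vertex
slopes pooled) and `group_mean_map` (moments across vertices of the control
mean map). The default was chosen because it is the only reading that is
simultaneously consistent with a control mean slope of −0.011, an SD of
0.057, thresholds of −0.068/+0.047, *and* ~36% of vertices below the lower
threshold: pooled vertex slopes necessarily have several-fold larger SD than
subject means (within-subject scatter adds in), so a pooled 1-SD cut would
leave only ~16% below. The method used is always recorded in the output
table.

## Pipeline conventions

q = 0.05 for all FDR masks; exported slope surfaces clamp the display field
to ±0.1 mm/year (raw values kept in a second field); CSV floats use `%.10g`
so reruns are byte-identical; the manifest stores SHA-256 checksums of every
output. Left and right hemispheres are concatenated left-then-right for
combined-vertex quantities (CDFs, mean maps, vertex-wise tests); Table-style
percentage summaries are reported per hemisphere. Baseline displacement maps
project on *template* normals (cross-sectional contrast); longitudinal slope
maps project on the *subject baseline* normals (within-subject change);
both conventions are fixed and documented rather than configurable guesses.

## Problem sizes used by tests and the acceptance script

Unit and property tests run at icosphere level 2 (162 vertices/hemisphere)
with 5–20 subjects per group; study-scale checks (recovery of configured
slope means, percentage ANOVA power, CDF dominance, vertex-wise sparsity)
use level 3 with the full 51/67/67 design, 20 replicate cohorts in the test
suite and 10 in the acceptance script. Null calibrations use 2,000
replicates per test (1,000 for the mixed model) and 50 (20 in the script)
null cohorts for the FDR fraction. These sizes make the whole suite and the
script each complete in a few minutes on one CPU while leaving Monte-Carlo
margins well inside the asserted tolerances.

## Known limitations

The mixed model's Wald denominator df is a plain residual count, not a
Satterthwaite approximation — adequate at these cluster counts but
anticonservative for very few subjects. The exact Mann–Whitney path caps at
n=8 per group for speed in 10³–10⁴-vertex sweeps. The generator's noise is
i.i.d. along normals, so spatially correlated registration error — which
would widen vertex-wise nulls on real data — is not represented. Volume
slope distributions are approximately normal by construction; the heavy
tails real cohorts show (SDs several times the means) are only partly
reproduced via the subject slope offsets.
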