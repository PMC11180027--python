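# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Maze coding

A trial is a time-ordered, non-overlapping event sequence on an eight-arm
radial maze with baited arms {1, 2, 4, 7} and a 300 s duration. Entry
labels are assigned online from the per-trial visit history with the
precedence: unbaited & first visit → RME; unbaited & revisit → HME;
baited & revisit → WME; baited & first visit → PE if the pellet was eaten,
else PO. Hybrid errors count toward both the working and the reference
tallies, so `total_entries = PE+PO+WME+RME+HME`, `WME_total = WME+HME`,
`RME_total = RME+HME` hold for every trial (property-tested).

Two conventions required a decision:

- A revisit to a baited arm whose pellet was previously omitted is scored
  WME regardless of the pellet state — the re-entry is the operative
  working-memory event and every entry carries exactly one primary label.
  `MazeConfig(revisit_always_wme=False)` switches to scoring such a
  revisit PE when the pellet is then eaten.
- Nose pokes and stretch-attend postures are events performed from the
  atrium, not arm entries, and never generate memory labels.

Trials shorter than 300 s are scored; the realised duration is recorded.
Every measure is also normalised per arm entry, because total activity
varies widely between rats; normalised values are undefined (flagged) for
trials without entries.

## Phenotype classification

The classification variable is daily normalised TICA (s per entry). For
each treatment arm, the day-matched sham group provides mean and sample
SD (n−1 denominator; the population/sample choice is not standardised in
this literature, and sample SD is the conservative default); the
threshold is mean + 3·SD. Exceedance is strict (a value exactly at
threshold does not count). A rat is *affected* with ≥ 3 exceedance days
in each of days 1–6 and 7–12; a third window (13–18) is reported for
weekly counts but does not enter the primary call. Days with fewer than
two sham values carry no threshold and are skipped; a rat with fewer than
three evaluable days in either primary window gets an indeterminate call.

Classification runs on raw daily values. The 3×IQR outlier rule (values
above the group × day × measure cell mean + 3·IQR set missing) applies
only to the binned group-level analyses: removing high values before
thresholding would bias the criterion against detection. After
classification, group analyses relabel vehicle-treated nerve-injured rats
into *affected* / *unaffected*, giving the five behavioural groups used
by the ANOVA battery; indeterminate rats are dropped with a warning.

The criterion's specificity is checked by direct simulation
(`null_false_affected_rate`): with i.i.d. normal rats and per-day
thresholds re-estimated from nine shams, the false-affected rate over
10,000 rats is far below 0.5 % — requiring three 3-SD exceedances in each
of two windows compounds an already small per-day probability.

`expected_null_count` projects an observed affected count onto another
group at the same proportion, rounding halves away from zero.

## Synthetic behaviour

No generative model for maze behaviour exists in this literature, so the
generator uses the simplest over-dispersed positive families that match
foraging structure: negative-binomial entry counts (mean 16, dispersion
8) and log-normal dwell times (atrium median 6 s, σ_log 0.35; arm time
median 6 s; end-of-arm dwell median 3 s), with a per-rat log-normal trait
(σ 0.12) carrying between-animal variability. Arm choice mixes a revisit
rate (0.25), an unbaited-choice rate (0.45) and a pellet-omission
probability (0.10). Grooming/rearing/climbing are Poisson-count events
with log-normal durations. Events are laid consecutively and truncated at
the 300 s budget, so duration conservation holds by construction.

The latent affected phenotype (prevalence 0.22 in the vehicle CCI group,
0 elsewhere) multiplies atrium dwell, end-of-arm dwell and the SAP rate
by a factor tapering linearly from 6 at day 1 to 1 at day 21, mirroring a
phenotype that peaks early and wanes in the third week. These effect
sizes make daily exceedance near-certain in the two classification
windows, which is what the parameter-recovery checks assume. One optional
"non-forager" sham rat (never enters an arm) exercises the exclusion
path.

The generator emulates the statistical structure of the endpoints, not
their biology: there are no learning curves, no within-day event
autocorrelation beyond the trait, and sensory/motor effects are
independent of the latent phenotype. Passing recovery tests therefore
demonstrates the correctness of the analysis chain, not the realism of
any biological effect size.

Sensory tables draw five aesthesiometer replicates per paw per test day,
clipped to (0, 50] g (ramp ceiling), with nerve-injured groups dropping
ipsilaterally post-surgery (12 g vehicle, 22 g under treatment, 35 g
baseline) and the contralateral paw stable; rotarod latencies average
three trials clipped to (0, 180] s. Test days default to a pre-surgery
baseline (day 0) plus five post-surgery days.

## Imaging quantification

The macro chain is: per-channel maximum projection over z → rolling-ball
background subtraction (default radius 50 px, the common macro default;
output clipped at 0) → iterative-intermeans auto-threshold of the mask
channel → optional AND with a DAPI mask → median target intensity over
mask-true pixels (even counts average the central pair). Projection
precedes background subtraction, following the order in which the steps
are usually scripted. Empty masks yield flagged undefined results rather
than zeros, mirroring manual quality-control exclusion. Bilateral
comparisons report 100 × contralateral / ipsilateral medians.

The threshold iterates t ← (mean below t + mean above t)/2 on a 256-bin
histogram over the observed intensity range until the update falls below
half a bin width; pixels strictly above t are foreground, so ties go to
background. The rule is equivariant under positive affine intensity maps
(tested) and agrees with the IsoData thresholds computed independently by
scikit-image to within a few bin widths. Constant planes have no
threshold and return an empty mask with a warning.

A caveat on rolling-ball behaviour: the ball reproduces any surface whose
curvature stays below the ball curvature, so smooth ramps are removed
entirely; only features sharper than the ball (spots, cells) survive
subtraction. The large-radius limit approaches plain minimum subtraction
for such features, not for tilted backgrounds.

## Morphometry

Cells are 8-connected components above a minimum area (default 50 px²),
cropped with a 1-px margin. Box sizes form a base-2 power series from
2 px up to a quarter of the longer bounding-box side (at least two
scales). Twelve grid positions are used: the origin-anchored grid plus
eleven uniform-random integer offsets drawn from a seeded generator.

The primary fractal dimension is the slope of the **minimal cover**: at
each scale the smallest box count over the twelve grid positions enters a
single least-squares fit of ln N on ln ε. Averaging per-offset slopes
instead is also computed and reported (`dimension_offset_mean`, with the
full per-offset list) but is known to be biased low for space-filling
silhouettes, because misaligned grids split boundary pixels into extra
partial boxes at coarse scales (a filled 256² square then measures
D ≈ 1.89 rather than 2). The minimal cover approaches the true covering
number and reproduces the analytic dimensions of the test fixtures —
line 1.0, filled square 2.0, Sierpinski triangle log 3 / log 2 —
essentially exactly.

Lacunarity is (σ/μ)² of the pixel masses of occupied boxes, averaged over
scales and grid positions (one of several conventions; the variant is
recorded in the result metadata). Shape metrics: area is the foreground
pixel count; the default perimeter is the weighted 8-connected
boundary-chain length (scikit-image's `regionprops.perimeter`), with the
sub-pixel traced contour polygon and the Crofton estimate as options —
the conventions differ systematically on angular shapes, which shifts
circularity 4πA/P²; radius is the smallest enclosing circle of the
foreground pixels; density is area over convex-hull area. Note that
density does not penalise straight elongated shapes (a line is its own
hull); it separates arborised silhouettes from compact blobs.

Region summaries are field-wise means over all analysed cells and are
flagged invalid below 20 cells.

The synthetic ramified cells hold their radial reach fixed while branch
depth controls how finely the arbor subdivides (branching ratio 2, length
decay 0.7, constant 1-px branch thickness). Mean box-counting dimension
then increases strictly with depth (tested at depths 1/3/5 with 30 cells
each), and cells order as line < ramified < filled blob. With a per-level
thickness taper this monotonicity breaks — thick primaries dominate the
small-scale counts — which is why constant thickness is the default.

## Statistics

The battery wraps established implementations: mixed (split-plot) ANOVA
via pingouin (cross-checked against hand-computed sums of squares on a
balanced design), Shapiro-Wilk, Friedman, Wilcoxon, Pearson and linear
regression via scipy. Holm's step-down adjustment is implemented directly
(p_adj at rank i is the running max of (m−j+1)·p_j, capped at 1) and
cross-checked against statsmodels. The Greenhouse-Geisser correction
applies to within and interaction terms when Mauchly's test rejects
sphericity (`gg_correct="auto"`; `True` forces it), multiplying both
degrees of freedom by ε ∈ [1/(levels−1), 1] and producing the
non-integer dfs typical of repeated-measures reports. The nonparametric
branch (Friedman + Holm-corrected Wilcoxon post hocs) is routed when the
Shapiro-Wilk gate fails at α = 0.05.

A priori power uses the noncentral F distribution with λ = f²·k·n,
df₁ = k−1, df₂ = k(n−1); for f = 0.8, five groups, α = 0.05 and target
power 0.8 the smallest per-group n is 5. The empirical type-I rate of the
group test (`mixed_anova_type1_error`, 200 null replicates of a balanced
3 × 8 × 3 design) sits at the nominal α within Monte-Carlo error.

## Pipeline

`run_pipeline` chains simulate → code-trials → classify → quantify →
morphometry → stats → report into a run directory. A single global seed
fans out to per-stage seeds via SHA-256 of `"{seed}:{stage}"` (kept below
2³¹), so stages can be rerun in isolation; the manifest records the seed
fan-out, a hash of the canonical YAML configuration, package version and
stage timings, and reruns are byte-identical. Stage failures leave
partial outputs plus a `FAILED_<stage>` marker and exit non-zero.
Configuration files are schema-checked; unknown keys are rejected.

## Problem sizes

The shipped checks use: 200 nerve-injured rats (plus 9/7 shams) over 12
days for classifier recovery; 10,000 simulated rats for null specificity;
256-px fixtures and depth-7 Sierpinski rasters for the box-counting
oracles; 30 cells per branch depth for the monotonicity sweep; and 200
null replicates for the ANOVA type-I calibration. These sizes give
Monte-Carlo error comfortably below the asserted tolerances while keeping
a full run fast on a single CPU.

## Known limitations

- The behavioural generator's effect sizes are free parameters, not
  estimates — no distributional data exist to fit them to.
- Weekly evaluation windows beyond the two defining windows, and the
  routing rule between parametric and nonparametric branches, are
  reconstructions of under-specified conventions; both are configurable.
- Box-counting results depend on the grid convention; the audit fields
  exist precisely so the per-offset behaviour can be inspected.
- The imaging stage models quantification only: no bleed-through,
  illumination fields, or atlas registration.
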