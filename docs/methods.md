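# Methods

This note documents the models behind `pcstereo`, the defaults and why
they are what they are, and what the passing tests do and do not establish
about real tissue.

## Virtual tissue

A cerebellar region is a rectangular reference solid (the "contour" a
stereologist would draw, including white matter and interstitial space)
containing a set of *folia*: tubes of radius R swept along polyline
centerlines.  PC somata are placed on each folium's monolayer surface
(radius R − offset) as a Poisson process with surface density σ, displaced
radially by Normal(0, jitter), with an optional hard-core constraint
(random sequential adsorption; minimum separation = mean soma diameter)
that redraws conflicting candidates in bounded rounds.  Soma diameters are
lognormal (mean 25 µm, SD 4 µm, clipped to 0.4–1.8× the mean) — a modeling
choice at human PC scale, configurable.

Geometry is analytic: tube volume is the Pappus value πR²L (exact for a
straight tube and to second order in bend angle for gentle bends; the
point-in-solid test trims the sausage flat at its end planes so the two
agree), and monolayer area is 2π(R − offset)L.  Region volume is the box
volume by default (`volume_mode="bounding_box"`), because the density a
disector assay estimates is cells per *contoured region volume*, frames
being placed wherever the region shows in a section — not per volume of
cortical tissue proper.  `volume_mode="folia"` gives the union-of-tubes
volume for closed-form examples.

The density reference is therefore heterogeneous inside: somata live only
on monolayer shells.  That is precisely the situation the optical disector
is meant to handle, and the phantom's job is to exercise it.

### Calibrated default regions

The published design figures pin each region's sampled geometry: with
pitch p, mean frame count F and S sections the lateral box side is
W = p·sqrt(F/S) − frame side, the axial extent is 1.2·S mm − 0.2 mm, and
the true density is 450/(F × 1.47 × 10⁻³ mm³).  Folia are laid out as
serpentine rows (row pitch ≥ 2R + clearance) in staggered layers:

* rows run **diagonally** (27°) to the counting grid, so monolayer bands
  sweep through all grid phases instead of beating against the frame
  lattice;
* layers are staggered in z by a golden-ratio fraction of the layer
  pitch, so no commensurability with the 1.2 mm section period survives;
* a z undulation (amplitude 400 µm) with a phase shared within each
  region smears the monolayer across the sectioning axis while keeping
  inter-folium clearances constant.

Folium radii are 450 µm (300 µm in lobule X) with the monolayer 150 µm
(120 µm) deep and radial jitter of 60 µm (40 µm).  These values were
chosen so that the per-frame clustering of counted somata — cells
concentrate where a monolayer shell runs tangent to the disector window —
stays moderate; with thick folia and a thin monolayer the replicate
scatter of the density estimate is several times the Gundersen CE, which
assumes Poisson within-section noise.  With the defaults the CE is within
a factor ≲ 1.7 of the true replicate CV (exact for lobules IV–VI), and the
mean CE is ≈ 0.05 with ~415–445 cells counted per region, matching the
design criterion (< 0.07) and the reported mean (0.053).

## Sectioning, degradation, sampling, counting

Sections are contiguous 200 µm slabs with a uniform random start, of which
every 6th is retained; a soma belongs to the slab containing its *leading
edge* (the minimum-z point of its sphere, the first to come into focus
when focusing downward) — the unique counting event.  Degradation removes
whole sections at the configured loss fraction and erodes each section's
footprint by the fray depth, deleting the rim's area and somata together,
so density remains estimable (simulated bias < 5% at 10% loss + 50 µm
fray).

Frames (side 140 µm) sit at the low-corner of each grid cell whose frame
would overlap the region's cross-section with positive area.  The counting
rule: a soma scores in a frame iff its maximal XY profile disk intersects
the closed frame square, does not touch the forbidden line, and its
leading edge lies in (z_top + guard, z_top + guard + h].  The forbidden
line is the classical one — left edge with its infinite upward extension,
bottom edge, and the downward extension through the bottom-right corner.
We initially implemented the variant with downward/leftward extensions and
found, via the brute-force tiling test, a configuration (a profile disk
straddling a frame's top-left corner region without containing the
corner) that it counts twice; the classical extensions make the
exhaustive-tiling identity exact, which is the property the whole
unbiasedness argument rests on.

### Edge effects

The estimator sums *full* box volumes also for frames that straddle the
region boundary, so E[density] is biased low by roughly
(4·side/W + thickness/Z) for a W×W×Z box — about 3–7% for the calibrated
regions (visible in the worked example), and the same in a real assay with
these frame sizes and contours.  The unbiasedness *validation* therefore
uses a larger box with a finer design (40 µm frames at 800 µm pitch, 20 mm
box) where the edge term is ≪ 1%, and verifies the 2% band there.  What
passes: the counting rule, the volume bookkeeping, and the SURS design are
unbiased.  What does not follow: absence of edge bias for small regions —
that is a real property of the method, reproduced rather than hidden.

## Estimation

Density, CE (m = 1), Cavalieri volumes (Σ area × thickness × period, with
slab-mean areas so the estimator is exactly unbiased under the random
series start), and the volume-weighted composite Σ V_r D_r / Σ V_r with
regions missing an estimate excluded from both sums.  Per-section counts
enter the CE in anatomical order; log densities (natural log) are carried
alongside raw ones for the statistics.

## Cohort simulation

Per-case regional log densities follow

    log D[c, r] = log µ_r + 1[autism]·log a_r + 1[male, r ≠ X]·log g
                  + β·age + 1[r = X]·(γ·log(BW/1450 g)
                                      + 1[autism male]·log m_X)
                  + u_c + e[c, r]

with u_c ~ N(0, 0.10²), e correlated across regions (crus I–crus II 0.52,
0.30 elsewhere; SD 0.12), and measurement noise as mean-one lognormal with
CV 0.053 (the assay's mean CE) in the fast-surrogate mode.  Demographics
(ages, brain weights) are drawn from diagnosis × sex cell normals fitted
to the packaged clinical table; mental-retardation and epilepsy flags at
38%, regression at 3/8, among autism cases.

**Raw-contrast parameterization.**  Effects are specified as the raw
cohort contrasts they should produce (crus I ratio 0.802, crus II 0.783,
lobules IV–VI 0.95, male 0.79, lobule X autism-M/F 0.685 and
autism-M/control-M 0.74, overall composite 0.89).  Because age and brain
weight are confounded with sex and diagnosis in the demographic cells, the
model coefficients are obtained by inverting the analytic expectation of
each contrast under the cell normals (`derive_model`); with the default
table this gives a_crusI = 0.796, g = 0.816, γ = −0.268, m_X = 0.752.  A
planted 19.8% is then *recovered* as a raw 19.8% (the recovery tests
compare Monte-Carlo means with the same analytic expectations; the
residual ratio-of-means bias is < 0.5 percentage points at n = 8 per
group).

**Lobule X mediation.**  The two lobule X male contrasts cannot both run
through brain weight: the log-BW gaps in the fitted cells (autism M–F
0.259, autism M–control M 0.109) have the wrong proportion for the
printed contrast pair, whatever γ.  The default therefore combines a
negative brain-weight coupling (γ = −0.268: heavier brains, lower
density — volume dilution) with a direct autism-male term m_X = 0.752; a
`lobx_mediation="full"` switch forces everything through brain weight and
then reproduces only the M/F contrast.  A corollary: the within-autism
lobule X density/brain-weight correlation comes out near −0.4, weaker
than the −0.67 reported from real tissue; the planted contrasts take
precedence.

**Composite volume weights.**  A volume-weighted composite that is 11%
lower in autism is arithmetically impossible if crus I & II (deficits
~20%) dominate the weights and every region is lower.  The nominal
regional volumes (13,900 / 2,830 / 2,100 / 190 mm³ for IV–VI / crus I /
crus II / lobule X) are therefore calibrated so that *all* printed
contrasts hold simultaneously — lobules IV–VI carry most of the weight.
These cohort-level weights are deliberately distinct from the phantom
volumes (which are pinned by the frame counts and pitches); the package
keeps assay geometry and cohort statistics consistent with their
respective published figures rather than forcing a single geometry to
satisfy both.

**ADI-R.**  The eye-contact item (Q50, ordinal 0–3, higher = more
impaired) is generated by thresholding a latent variable equal to the
negative standardized lobule X log density plus N(0, 0.75) noise at fixed
quartile cutpoints; one autism case per cohort lacks usable scores.  The
latent noise was calibrated once (Monte Carlo, 400 cohorts) so the mean
Spearman correlation with measured lobule X density across the 7 complete
autism cases is −0.75; the crus I–crus II residual correlation 0.52 was
calibrated the same way to give a mean sample correlation of 0.832.
Domain totals are generated as noisy sums unrelated to density.

## Statistics

* **Levene gate**: center = mean (the classic statistic, as in common
  commercial software); pooled t when Levene p ≥ α, Welch otherwise.
  Percent differences are on raw densities with the larger-mean group as
  reference.
* **Factorial model**: y = Xβ + case intercept + ε with observation
  weights ∝ regional volume, fitted by maximum likelihood (per-case 4×4
  covariance blocks, profiled GLS β; Nelder-Mead on the two log
  variances).  Sum-to-zero coding, Type III Wald F per term, denominator
  df by the between/within containment rule (between-case terms: cases −
  between-parameters; within terms: observations − cases − within-
  parameters).  The unweighted fit is cross-checked against an
  independent mixed-model implementation in the tests.  Volume weighting
  concentrates information in the largest region and costs power — the
  planted-effect power checks use the unweighted variant.
* **FDR**: Benjamini–Hochberg step-up.  On the published four regional
  p-values (0.512, 0.039, 0.032, 0.173) the step-up rule flags the two
  crus regions at q = 0.10 and nothing at q = 0.05 (0.032 > 0.05/4); the
  report wrappers therefore default to q = 0.10, the rate at which the
  published flag pattern is a fixed point of the rule.
* **Spearman**: mid-rank rho; exact permutation p for n ≤ 8 (5,040
  permutations at n = 7), t approximation above; percentile bootstrap CI
  (1,000 replicates), widened minimally to contain the point estimate
  under heavy ties.
* **Observed power**: P(F′(df₁, df₂, λ) > F_crit).  Two noncentrality
  conventions are exposed: `cohen` (λ = f²N, the textbook definition —
  power 0.264 at f = 0.36, N = 16) and `spss` (λ = f²(df_err + df_hyp +
  1) — power 0.237 ≈ 0.24 for the same pair, which is how observed-power
  values printed by that software are internally consistent).  Both are
  verified against a 20,000-replicate ANOVA simulation at the implied
  noncentrality.

## Problem sizes and determinism

Phantoms are built once per session in the tests (≈ 2–7 s each; the
largest holds ≈ 2.2 million somata); replicate assays take 10–200 ms.
The acceptance script uses 50 assay replicates per region and 200
simulated cohorts.  Every stochastic stage takes a seed or Generator;
identical seeds give identical phantoms, samples, cohorts, and output
files.

## Limitations

* Folium geometry is a packing of serpentine tubes, not an anatomical
  cerebellum; cross-folium hard-core interactions are not enforced (layer
  clearances make them geometrically impossible at the defaults).
* Optical physics is not modelled: the 75 µm usable depth is taken as
  given; no lost-caps correction beyond the guard volume, no shrinkage
  correction back to fresh tissue.
* The cohort generator plants multiplicative effects; it does not model
  epilepsy/MR effects on density (reported absent) and generates ADI-R
  domain totals unlinked to density.
* Passing recovery tests show the pipeline recovers what it plants at
  n = 16 noise levels — not that the planted structure is true of brains.
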