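# Methods

`adipomorph` implements the quantitative pipeline of a 2×2 mouse study
design (genotype Ctrl/KO × treatment vehicle/β3-adrenergic agonist) on brown
adipose tissue (BAT): lipid-droplet morphometry from histology, fatty-acid
composition indices, comparative-ΔCt qPCR quantification, glucose-tolerance
AUC, and the group-comparison statistics that tie them together.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic validation does and does not establish.

## Multi-scale droplet segmentation and fusion

BAT sections contain droplets spanning more than an order of magnitude in
diameter — dense multilocular droplets of a few μm next to unilocular
droplets of tens of μm.  A single detector tuned to one size class misses or
mangles the other, so the pipeline runs one detector per *inference scale*
(defaults: a small scale at 2 μm / 8 px and a large scale at 13.68 μm /
54.9 px, at the 0.249 μm/px extraction resolution) and merges the per-scale
instance label maps.

**Working representation.** Raw H&E tiles show droplets as bright unstained
vacuoles.  RGB is collapsed with BT.709 luminance weights (0.2125, 0.7154,
0.0721) — a documented, configurable choice — and inverted
(`out = max_intensity − gray`), making droplets the dark phase.  No contrast
normalization is applied.

**Detectors.** Trained segmentation models plug in through the
`DetectorContract` (callable `(image, scale) → LabelMap`, validated for
shape and non-negative integer ids on load); training them is out of scope.
The bundled `reference_detect` is a classical stand-in so the pipeline runs
without model weights: Gaussian smoothing with σ = nominal_diameter_px/8,
global Otsu threshold keeping the droplet-polarity side, hole filling,
distance-transform peak seeding with minimum separation
nominal_diameter_px/2, and watershed splitting.  Otsu is offset-invariant,
so uniform intensity shifts do not change the output.  It is a stand-in,
not a reproduction of the trained models.

**Bandwidth filter.** Each scale's labels are filtered on equivalent
diameter with a closed interval (ties kept).  The intervals are free
parameters; the defaults — small [1, 8] μm, large [6, 120] μm — overlap in
the 6–8 μm band on purpose so that fusion arbitrates it.  The filter acts on
diameter, not area, consistent with the equivalent-diameter readout.
Border-touching labels are kept by default (`exclude_border_labels` flips
this).

**Fusion rule.** Scales are added successively in ascending nominal
diameter; within a scale, labels are visited by ascending id.  A candidate
label is accepted iff strictly less than 10% (configurable) of its area is
already occupied in the fused map — a label with *exactly* 10% occupancy is
rejected.  Accepted labels claim only currently-free pixels, so
smaller-scale geometry is never overwritten; the provenance table records
original vs accepted areas per label, making the alternative (overwrite)
semantics auditable.  Occupancy is computed against all labels accepted so
far, which coincides with "occupied by smaller scales" whenever per-scale
inputs are internally disjoint (always true for label maps).  Correctness is
checked against an independent brute-force pixel-set implementation of the
same rule on randomized instances.

**Morphometry.** Areas are pixel counts × pixel_size².  The equivalent
diameter is d = 2·√(A/π).  Per image we report droplet count, the
arithmetic (not area-weighted) mean diameter over droplets, and the fraction
of droplets per diameter class; default class edges (2, 5, 10, 20, 50 μm,
open-ended above) are free choices.  Group values are unweighted means over
images, so each section (mouse) is one point regardless of droplet count —
matching how small-n histology panels are analyzed.

## Fatty-acid indices

Input is a long table of per-sample species quantities for the TG and PL
fractions, quantified against a C19:0 internal standard (glyceryl
trinonadecanoate).  Quantities are assumed molar-comparable.  Species codes
are normalized to `C<carbons>:<bonds>n-<position>`; unknown codes pass
through with a warning.

- mol%(s) = 100·q(s)/Σ q(s′) over non-standard species (sums to 100 by
  construction);
- lipogenic index = C16:0/C18:2n-6 (endogenously synthesized vs dietary FA);
- palmitoleate/linoleate = C16:1n-7/C18:2n-6;
- SCD1 ratio = C16:1n-7/C16:0 (Δ9-desaturation activity proxy);
- ELOVL6 ratio = C18:0/C16:0 — the enzyme's canonical product/substrate
  pair.  The literature sometimes uses C18:1n-7/C16:1n-7 instead; that
  definition is available via `elovl6_definition` and the choice is flagged
  here because no single convention is universal;
- total FA vs C19 = Σ(non-standard)/q(C19:0), a per-sample relative content;
- TG/PL ratio = total FA in TG / total FA in PL.

Ratios are computed on quantities; mol% would give identical values because
the normalization cancels.  Missing species or zero denominators produce
NaN with a warning — never imputed values.  Indices are computed per sample
and averaged per group afterwards.

## ΔCt quantification, mtDNA and GTT

Replicate Ct values are averaged on the Ct scale (standard comparative-ΔCt
practice; averaging RQ instead would bias by Jensen's inequality), then
ΔCt = Ct_target − Ct_housekeeping (36B4 for mRNA) and RQ = 2^−ΔCt.  An
optional calibrator group rescales to fold change (the calibrator's mean is
exactly 1).  Relative mitochondrial DNA content uses Cox1 (mitochondrial)
vs Ppia (nuclear): the sign convention 2^(Ct_Ppia − Ct_Cox1) is chosen so
that more mitochondrial template yields a larger value, matching the
direction in which a mitochondrial-loss phenotype reads as a decrease.

GTT AUC is the trapezoidal area over the full 0–120 min sampling range
(total AUC, no baseline subtraction); incremental AUC above the t=0 value
is available via `incremental=True`.

## Statistics routing

Per response: Shapiro–Wilk per group at α = 0.05 on raw values (no
transformations).  If every group is compatible with normality and the full
2×2 design is present: two-way ANOVA (type-II sums of squares by default,
appropriate for near-balanced designs; configurable) plus planned pairwise
comparisons — genotype within each treatment and treatment within each
genotype (family size m = 4) — as pooled-MSE t-tests with residual df,
Šídák-adjusted (p_adj = 1 − (1−p)^m).  Exactly two normal groups: unpaired
two-tailed t-test.  Any group non-normal, too small to test (n < 3), or an
incomplete design: Mann–Whitney per planned pair, Šídák-adjusted over the
family.  Fisher's LSD (unadjusted pooled t-tests) is available as the
alternate post hoc.  The family is the planned simple-effect set because
those are the contrasts such studies actually report; it is configurable in
the sense that callers can subset the pairwise table.

Calibration, measured by simulation in the test suite: under a global null
(2×2, n = 6/group, 1000 datasets) the family-wise rate of any significant
adjusted comparison stays within α plus binomial slack.  For power we
simulate a 3-within-cell-SD shift confined to the KO×CL cell of a
desaturation-ratio response.  "Detected" means the report flags the
interaction term (ANOVA route) or a significant adjusted planned contrast
involving the perturbed cell — the simple effects that constitute the
interaction.  This definition matters: per-group Shapiro at α = 0.05 sends
≈ 1 − 0.95⁴ ≈ 19% of perfectly normal datasets down the nonparametric
branch, which has no interaction term, so an ANOVA-term-only definition
caps power near 81% regardless of effect size.  Under the combined
definition the measured power is ≥ 90/100 with a wide margin.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated.

**Images.** Non-overlapping discs (rejection-sampled centers, minimum gap
3 px, bounded at 10,000 retries per droplet, then a placement error) with
droplet interior brighter than background and a darker 1-px rim, plus
Gaussian noise, 8-bit.  Droplet diameters are truncated log-normal; the
location parameter is the median (geometric mean) of the untruncated
distribution.  Defaults per section: 24 small droplets (median 3 μm, σ=0.25,
truncated [1.5, 6]) and 6 large (median 25 μm, σ=0.15, truncated [12, 40])
at 512×512 px and 0.249 μm/px — an 80/20 multilocular/unilocular mix.  The
tissues themselves report no size-distribution parameters, so these are the
package's own documented choices.  Truth tables record sampled diameters,
rasterized areas and measured equivalent diameters; rasterization keeps the
two within one pixel size.

**Detections.** An error model emits per-scale label maps from truth:
per-size-class miss rates (defaults encode the clean contract — each scale
sees only its own class, exactly), nearest-neighbour merging, fragmentation
of large droplets into k fragments strictly inside the footprint at the
small scale, and ±jitter dilation/erosion that never collides with other
labels.

**Tables.** FA compositions are Dirichlet draws on the mol% simplex
(concentration parameter, default 2000, ≈1–13% relative noise depending on
species abundance; `None` = noise off), so mol% sums to 100 by
construction; group effects are species multipliers applied to the mean
vector and renormalized, with expected values exposed in closed form
(`expected_mol_percent`).  Default effects emulate the knockout-under-
agonist phenotype directionally (palmitate ×1.3, palmitoleate ×2,
stearate ×0.7, arachidonate ×0.7, total FA ×1.5); magnitudes are free
choices since the study reports per-panel plots, not tabulated means.  Ct
tables are base + group shift + N(0, sd) per replicate.  GTT series are a
mean excursion curve over the 0/15/30/60/90/120 min scheme plus noise,
clipped at 30 mg/dL.

**What the generator does not emulate** — and hence what passing tests do
not show: tissue texture, staining variability, touching/overlapping real
droplets, non-circular droplet sections, whole-slide geometry, qPCR
efficiency differences, and compositional covariance structure between FA
species beyond the simplex constraint.  Clean-detection tests validate the
fusion/measurement arithmetic, not segmentation accuracy on real H&E; the
reference-detector tests validate the classical stand-in only on the disc
photometry above.

## Problem sizes and tolerances

Validation runs at desk scale: 100 randomized 32×32 instances for the
fusion oracle, 200 rasterized discs (2–40 μm) for diameter recovery at a
two-pixel-size tolerance, 8 sections for end-to-end morphometry recovery
(5% on mean diameter, ±0.05 on class fractions), 1000 simulated datasets
for type-I calibration and 100 for power.  Index identities are asserted to
1e-12, mol% sums to 1e-9.  These sizes keep the whole suite under a minute
apart from the statistics simulations.

## Known limitations

- The fusion rule's clipping semantics ("claim free pixels only") is one of
  two defensible readings of additive merging; the provenance table carries
  both areas so the overwrite variant can be assessed in sensitivity
  analyses.
- `reference_detect` under-segments droplet pairs closer than about half a
  nominal diameter and is not intended for quantitative use on real tissue.
- The ELOVL6 ratio definition is a convention choice (see above).
- Statistics assume independent samples; repeated-measures or mixed designs
  are out of scope.
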