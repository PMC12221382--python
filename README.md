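# adipomorph

Quantitative pipeline for brown-adipose-tissue (BAT) studies with a 2×2
genotype × treatment design: multi-scale lipid-droplet morphometry from
histology, fatty-acid composition indices, comparative-ΔCt qPCR
quantification, glucose-tolerance AUC, and the group statistics that tie
the readouts together.  A synthetic-data generator provides ground-truth
images and tables so every stage is testable without animal data.

## The problem

BAT "whitening" — the shift from many small multilocular lipid droplets
toward few large unilocular ones — is a morphological signature of
impaired thermogenic function, and changes in de novo lipogenesis (DNL)
leave fingerprints in the tissue's fatty-acid profile.  Quantifying both
requires (i) segmenting droplets whose diameters span more than an order of
magnitude, and (ii) reducing composition and qPCR tables to interpretable
indices with appropriate small-n statistics.

## The core methods

**Multi-scale segmentation fusion.**  One detector per inference scale
(defaults 2 μm/8 px and 13.68 μm/54.9 px at 0.249 μm/px) produces instance
label maps, each filtered by a per-scale equivalent-diameter bandwidth.
Scales are merged by adding them in increasing order: a label is accepted
iff strictly less than 10% of its area is already occupied by previously
accepted labels,

&nbsp;&nbsp;accept L ⇔ |{p ∈ L : fused(p) ≠ 0}| / |L| < 0.10,

and accepted labels claim only free pixels, so smaller-scale geometry is
preserved.  Fused label areas A convert to equivalent diameters
d = 2·√(A/π); summaries report per-image mean diameter and diameter-class
fractions, aggregated image-first per group.

**Lipid indices** from species quantities q(s) (C19:0 internal standard
excluded from totals): mol% = 100·q(s)/Σq, lipogenic index C16:0/C18:2n-6,
palmitoleate/linoleate C16:1n-7/C18:2n-6, SCD1 ratio C16:1n-7/C16:0,
ELOVL6 ratio C18:0/C16:0, total FA vs C19, and the per-sample TG/PL total
ratio.

**Expression & physiology.**  Comparative ΔCt: RQ = 2^−(Ct_target −
Ct_housekeeping) with replicates averaged on the Ct scale; mitochondrial
DNA content 2^(Ct_Ppia − Ct_Cox1); trapezoidal GTT AUC over 0–120 min.

**Statistics routing.**  Shapiro–Wilk per group; all normal and full 2×2 →
two-way ANOVA with Šídák-adjusted planned simple-effect contrasts
(p_adj = 1 − (1−p)^m, m = 4); two normal groups → unpaired t-test; any
non-normal or untestable group → Mann–Whitney per planned pair.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import adipomorph as am

# 1) a synthetic BAT section with known ground truth
spec = am.ImageSpec(seed=42)                 # 24 small (~3 um) + 6 large (~25 um)
image, truth, truth_table = am.generate_bat_image(spec)
print(f"truth droplets: {truth.n_labels} "
      f"(mean diameter {truth_table['diameter_um'].mean():.2f} um)")

# 2) detect at both scales, bandwidth-filter, fuse
fused = am.segment_droplets(image)
print(f"fused droplets: {fused.n_labels}")

# 3) morphometry
droplets = am.measure(fused, image_id="section-1", group="Ctrl:NaCl")
summary = am.summarize(droplets)
print(summary.per_image[["droplet_count", "mean_diameter_um",
                         "frac (2, 5]", "frac (20, 50]"]].round(3).to_string(index=False))

# 4) lipid indices from a generated composition table (n = 6 per group)
groups = [("Ctrl", "NaCl", 6), ("Ctrl", "CL", 6), ("KO", "NaCl", 6), ("KO", "CL", 6)]
fa = am.generate_fa_tables(am.FAGroupParams(groups=groups, seed=42))
tg = am.compute_indices(fa).query("fraction == 'TG'")
print(tg.groupby("group")[["lipogenic_index", "scd1_ratio"]].mean().round(3))

# 5) statistics routing on the SCD1 ratio
design = am.Design(tg.rename(columns={"scd1_ratio": "response"})[
    ["sample", "genotype", "treatment", "response"]])
report = am.route_and_test(design)
print(report.routing)
print(report.pairwise[["comparison", "p_adjusted", "significant"]].round(4).to_string(index=False))
```

prints

```
truth droplets: 30 (mean diameter 7.57 um)
fused droplets: 30
 droplet_count  mean_diameter_um  frac (2, 5]  frac (20, 50]
            30              7.21        0.667            0.2
           lipogenic_index  scd1_ratio
group
Ctrl:CL              1.243       0.125
Ctrl:NaCl            1.214       0.123
KO:CL                1.620       0.193
KO:NaCl              1.223       0.118
two-way ANOVA + Sidak
       comparison  p_adjusted  significant
  Ctrl vs KO | CL      0.0000         True
Ctrl vs KO | NaCl      0.9843        False
CL vs NaCl | Ctrl      0.9996        False
  CL vs NaCl | KO      0.0000         True
```

The reference detector recovers all 30 ground-truth droplets and their
mean diameter to within a few percent (rasterization and boundary smoothing
account for the 7.21 vs 7.57 μm difference).  The generated fatty-acid
tables carry a knockout-under-agonist effect (doubled palmitoleate, raised
palmitate); the indices recover it and the routing flags exactly the two
planned contrasts involving the perturbed KO:CL group.

A command-line interface mirrors the library:
`adipomorph synth|convert|detect|fuse|measure|lipids|qpcr|gtt|stats --help`.

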