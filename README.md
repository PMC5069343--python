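# bsmap — statistical parametric mapping of bodily sensation drawings

`bsmap` analyzes **bodily sensation maps (BSMs)**: drawings in which
participants mark where on a 2D body template (front and back views,
natively 1024×1024) they felt a sensation — for example the needling
sensations elicited by acupuncture versus tactile control stimulation at
the HT7, PC6, ST36 and SP10 points. The toolkit is aimed at
psychophysics and acupuncture researchers who want group-level
topographic inference on such drawings, together with factorial analysis
of the accompanying 13-item sensation questionnaire (each item scored
0–3).

## The statistics

Given per-subject, per-session drawings `X_s` (non-negative intensity
matrices on a shared body mask):

1. **Normalization.** Each session is rescaled to the unit range,
   `X_s ← X_s / max(X_s)` over in-mask pixels (unmarked pixels are 0).
2. **Baseline correction** (optional). The subject's no-stimulation
   baseline drawing is subtracted, `D_s = X_s − B_s`, removing
   non-specific sensations such as the bilateral palm pattern that
   appears whenever subjects attend to their body.
3. **Pixel-wise random effects.** At every in-mask pixel,
   `t = m / (s/√n)` with df = n−1 (the paired test against baseline is
   the one-sample test on differences). Zero-variance pixels are marked
   invalid and excluded. For display, t is converted to the
   standard-normal deviate with the same two-sided tail probability,
   `Z = sign(t)·Φ⁻¹(1 − p/2)`.
4. **Cluster-extent correction.** Thresholding ~10⁵ pixels at p < 0.05
   would be meaningless without multiple-comparison control. Following
   the AlphaSim approach, `bsmap` simulates (default 10,000 iterations)
   smooth Gaussian null fields on the same mask, thresholds each exactly
   like the data, and records the largest connected suprathreshold
   component per iteration. The extent threshold `k` is the smallest
   size such that `P(max cluster > k) ≤ α` (clusters must *strictly*
   exceed `k`). Only clusters larger than `k` are reported, controlling
   the family-wise error across the whole body at `α = 0.05`.
5. **Questionnaire ANOVA.** Per item, a two-way fixed-effects ANOVA
   crosses stimulus type (2 levels) with location (4 levels), with
   Bonferroni correction over the m = 13 items.

Because raw subject drawings from sensation-mapping studies are rarely
shared, the package ships a first-class synthetic-study generator with
known ground truth (baseline palm blobs, local stimulus-site blobs,
line-like propagating effects along a limb), so every statistical
guarantee is testable end to end.

## Worked example

```python
import bsmap

template = bsmap.load_template("humanoid-64")
design = bsmap.default_study_design(template, n_subjects=25)
dataset, truth = bsmap.generate_study(template, design, seed=7)

# baseline-corrected group map for needling at ST36
diffs = bsmap.as_stack(bsmap.baseline_differences(dataset, "acupuncture", "ST36"))
stat = bsmap.one_sample_tmap(diffs, template)

corrector = bsmap.ClusterExtentCorrection(
    template=template, n_iterations=10_000, voxel_p=0.05,
    corrected_alpha=0.05, fwhm_px=8.0, seed=7).fit()
clusters = corrector.transform(stat)

print(f"extent threshold: >{corrector.extent_threshold_} px "
      f"(achieved null rate {corrector.achieved_alpha_:.4f})")
for _, row in clusters.to_dataframe().iterrows():
    if row["surviving"]:
        regions = bsmap.region_report(template, clusters.cluster_mask(row["id"]))
        print(f"cluster {row['id']}: {row['size']} px, peak Z={row['peak_z']:.2f} "
              f"at ({row['peak_row']},{row['peak_col']}) [{row['view']}], "
              "regions: " + ", ".join(f"{n} {f:.0%}" for n, f in regions[:2]))
truth_mask = truth.mask_for(("acupuncture", "ST36"))
coverage = (clusters.surviving_mask() & truth_mask).sum() / truth_mask.sum()
print(f"planted-support coverage: {coverage:.0%}")
```

prints

```
extent threshold: >54 px (achieved null rate 0.0478)
cluster 1: 77 px, peak Z=9.52 at (47,19) [front], regions: left_leg_front 100%
planted-support coverage: 98%
```

Read: on this 64×64 template, a real cluster must exceed 54 pixels to be
reported at a corrected α of 0.05; the surviving 77-pixel cluster
(peak Z = 9.52) sits entirely on the front left leg, where the effect
was planted, and covers 98% of the planted support. The estimators
follow scikit-learn conventions (`fit`, fitted `*_` attributes,
`get_params`/`set_params`), and every operation is also available as a
plain function (`one_sample_tmap`, `simulate_null_max_clusters`,
`cluster_threshold`, `two_way_anova`, ...).

The same pipeline is scriptable from the shell:

```bash
bsmap simulate --template humanoid-64 --out study/ --seed 7
bsmap run --config analysis.yaml        # preprocess -> map -> correct -> render
bsmap anova --questionnaire study/questionnaire.csv --out-dir anova/
```

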