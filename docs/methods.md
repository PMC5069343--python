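# Methods

## Spatial domain and conventions

All drawings live on one canvas holding the front and back body views
side by side. Coordinates are 0-based `(row, col)`, origin top-left,
row-major, shared by every module. The silhouette mask is derived from a
raster template by treating any nonzero pixel as inside the body, which
tolerates anti-aliased edges. The two views are *separate connected
domains*: pixel adjacency across the panel gap is a layout artifact, not
anatomy, so connected components are computed per view and no cluster
may span views.

The built-in templates (`humanoid-N`, `rectangle-N`, `default-1024`) are
deterministic synthetic silhouettes. The humanoid style is a stick
figure with head, torso (chest/abdomen), two arms with hands and two
legs per view, plus a minimal disjoint region atlas named by the
subject's anatomical side (image-left is the subject's right on the
front view). It is an approximation built for validation and reporting;
it does not claim to match any particular drawing app's silhouette
pixel-for-pixel.

## Preprocessing

**Normalization** divides each session's drawing by its in-mask maximum.
The unmarked background is 0, so the result spans [0, 1] with maximum
exactly 1; the operation is idempotent and invariant to positive
rescaling, which is what lets it absorb each subject's idiosyncratic
"marking gain". An all-zero drawing (subject marked nothing) passes
through unchanged with a `RuntimeWarning`: rescaling it is undefined and
dropping it silently would corrupt paired designs.

**Baseline subtraction** keeps the signed difference. Truncating
negatives would discard information about sensations present at rest but
absent under stimulation; one-sided selection is deferred to the
thresholding stage, where positive-only cluster extraction is the
default for "sensation present" maps.

**Smoothing** (`smooth_map`) uses a Gaussian kernel with
σ = FWHM / (2√(2 ln 2)), computed on the full canvas with reflection at
the canvas edges and re-masked afterwards. Reflection avoids dimming
inside the body near the silhouette boundary. Real drawings are not
smoothed by default; smoothing exists primarily for the null-field
simulation.

## Pixel-wise statistics

The group model is a random-effects one-sample t-test per in-mask pixel
(`t = m/(s/√n)`, df = n − 1); the paired test against baseline is by
definition the one-sample test on within-subject differences. Pixels
with zero sample variance (typically: nobody marked them) are flagged
invalid and excluded from thresholding rather than set to t = 0 — 0/0 is
undefined, and excluding degenerate pixels matches neuroimaging
practice. p values are two-sided; sidedness of the original map
threshold is genuinely ambiguous in this literature, so the package pairs
a two-sided per-pixel threshold with positive-only cluster extraction by
default, both configurable (`MCConfig.two_sided`, `positive_only`). The
null simulation always mirrors whatever rule is applied to the data.

The display transform is `Z = sign(t)·Φ⁻¹(1 − p_two/2)`, computed in log
space (`t.logsf` + `ndtri_exp`) so that |t| up to the float range does
not underflow; t = 0 maps to Z = 0 exactly, and |Z| ≤ |t| for df ≥ 2.

## Monte-Carlo cluster-extent correction

Re-implemented from first principles (no AFNI dependency): each
iteration draws an iid standard-normal field on the canvas, smooths it
with the configured FWHM, re-standardizes the in-mask values to zero
mean and unit variance, applies the per-pixel threshold rule, labels
components per view (8-connectivity by default — the permissive,
conventional 2D choice; 4 available) and records the maximum cluster
size. The extent threshold is the smallest integer k with
P(max > k) ≤ α, and survival requires size *strictly greater* than k.
Iterations use independent child streams spawned from one seed
(`numpy.random.SeedSequence.spawn`), so the null distribution is
bit-reproducible and parallelizable by iteration.

The simulation needs a smoothness input that real studies rarely report.
`estimate_fwhm` recovers it from mean-removed subject maps by the
variance-of-differences method: Gaussian-kernel smoothing of white noise
gives a field autocorrelation ρ(d) = exp(−d²/4s²) (the kernel convolved
with itself), so the lag-1 autocorrelation inverts to the kernel scale.
The pipeline uses the estimate by default; white residuals give FWHM 0.

On the native 1024×1024 two-view canvas this procedure is the 2D
analogue of the cluster-size calibration used in whole-body sensation
mapping studies (which report extent cutoffs on the order of 10³ pixels
at per-pixel p < 0.05); the exact cutoff depends on the mask area and
field smoothness, so the package always derives it from its own
simulation rather than reusing any published number.

### Degenerate inputs and tie-breaks

Cluster labels are ordered by decreasing size, ties broken by the
top-left-most pixel in row-major scan order, making tables and label
matrices deterministic. An all-zero null (no iteration produced a
cluster) yields threshold 0 with its achieved rate reported. Peak
locations take the first maximum of |Z| within the cluster in scan
order.

## Questionnaire ANOVA

Per item, a classical fixed-effects two-way ANOVA with interaction
(stimulus type × location) on the cell observations, computed via OLS
with type-II sums of squares — identical to the textbook decomposition
on balanced data, which the test suite verifies against an independent
sums-of-squares oracle to 1e−8. The design is actually within-subject,
so a repeated-measures variant (subject as blocking factor) is available
behind `repeated_measures=True`, but the fixed-effects analysis is the
default because it is the stated method for this instrument. A table
with zero total variance is reported as degenerate (F undefined) rather
than F = 0. Scores are validated to 0..3; non-integer values are
accepted with a warning. Bonferroni correction uses the family of
m = 13 items.

## Synthetic studies

The generator emulates the structure of a sensation-mapping experiment:
25 subjects, one baseline plus eight stimulation sessions (2 stimulus
types × 4 locations), non-specific bilateral palm blobs at baseline that
recur in every session, a local blob at the stimulated site, and remote
effects for needling conditions (a constant-width line kernel along the
limb for HT7/PC6/ST36 — the "propagating sensation" geometry — and a
referred chest blob for SP10).

Default conditions, chosen once as a plausible rendering of how subjects
mark drawings, and used unchanged by all tests:

| parameter | default | rationale |
|---|---|---|
| marked-region amplitude | 1.0 | drawings are near full scale where marked |
| pixel noise | truncated Gaussian, sd 0.1 | light speckle; truncation keeps maps non-negative with a genuine zero background |
| marking gain | lognormal, σ = 0.3 per subject | idiosyncratic vigor; absorbed by unit-range normalization |
| local effect prevalence | 1.0 | everyone feels the stimulus site |
| remote/propagating prevalence | 0.5 | propagating sensations are reported by a fraction of subjects (historical reports range ~20–80%) |
| baseline palm prevalence | 0.9 | palms appear in nearly all baseline drawings |
| per-subject jitter | 1 px | anatomical variability in drawing placement |

Baseline effects are *realized once per subject* (inclusion and jitter
drawn from the subject's stream) and reused across that subject's
sessions; session noise is independent. This is what makes baseline
subtraction able to cancel them — re-jittering per session would leave
dipole residuals. Ground-truth masks are the nominal (unjittered)
effect supports: the half-maximum disc for blobs, the full constant-width
ribbon for lines. Questionnaire scores are Binomial(3, mean/3) per
cell, so cell means in [0, 3] are directly parameterizable; the default
cell means reproduce the published group means of the instrument.

What the generator does **not** model: reporting and recall biases,
stroke-level drawing dynamics, spatially correlated "scribble" noise,
inter-subject anatomical registration error beyond translation jitter,
and any physiological meridian mechanism. Passing tests therefore show
that the statistical machinery is correct under the stated noise model,
not that real drawings satisfy that model.

## Validation scale and guarantees

Error-control experiments run on a 64×64 single-view mask with n = 25
subjects: the extent threshold is derived from 10,000 null-field
iterations at fwhm 8 px, the family-wise error is measured on 1,000
simulated null studies, and planted-effect recovery (blob σ = 6 px,
amplitude 1.0 against noise sd 0.1 — a per-pixel standardized effect
well above 1 across the half-max support) is measured over 100
replicates requiring a surviving cluster covering ≥ 50% of the true
support. These sizes keep the whole validation reproducible on a single
CPU in minutes while leaving Monte-Carlo error well inside the asserted
slack (binomial SE bounds are used everywhere a rate is asserted).
Note that the null studies use unsmoothed noise drawings while the
extent threshold is calibrated on fwhm-8 fields; the threshold is
therefore conservative for those maps and the measured family-wise error
sits near zero, comfortably under the nominal 0.05.

## Known limitations

* Normalization by the in-mask maximum makes a session's scale depend on
  its single brightest pixel; drawings dominated by one extreme stroke
  compress everything else.
* The extent threshold assumes stationary smoothness; real drawings may
  be smoother along limbs than across them.
* The fixed-effects ANOVA ignores the within-subject correlation of the
  repeated sessions (use `repeated_measures=True` to block on subject).
* Conversion of colored multi-channel drawings to intensity is out of
  scope: inputs must already be single-channel.
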