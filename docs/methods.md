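# Methods

`nanoring` quantifies transsynaptic nanocolumn rings — the arrangement, at
*Drosophila* neuromuscular-junction synapses, of presynaptic scaffold (Brp)
clusters and postsynaptic glutamate-receptor (GluR) clusters on opposed
circles of ~210–250 nm diameter — in two-channel super-resolution (STED-like)
images, and the receptor/scaffold intensity time-course at confocal
resolution. Because raw images of this kind are rarely shareable, the
package pairs every estimator with a synthetic scene generator that renders
the same architecture with full latent ground truth, so each quantity the
pipeline reports can be checked by parameter recovery.

## Generative model

A scene is a field of synapse sites on a jittered grid (900 nm spacing,
so neighbouring synapses never interact with a ±300 nm line profile).
Per presynaptic ring:

- ring diameter ~ Normal(212 nm, 20 nm); the 20 nm population spread is a
  free parameter (only standard errors, not spreads, are typically
  reported for such measurements);
- cluster count ~ round(Normal(4.7, 1.0)) truncated at 1 — count
  histograms of this kind are well described by Gaussians;
- cluster angles: equispaced with wrapped-Gaussian jitter (SD 15°).
  Uniform angular placement was rejected because it frequently merges
  clusters below the 40 nm resolution, contradicting the discrete maxima
  seen in such images;
- cluster intensity: `intensity_scale_pre` (default 1500 expected photons)
  times a mean-one log-normal factor (SD 0.3) for the heterogeneous
  within-ring intensity distribution; the spread value is a model choice,
  not a measured quantity.

With probability `p_ring_opposed` = 0.84 the ring is opposed by a
postsynaptic ring (nominal diameter ~ Normal(244 nm, 20 nm)); additional
unopposed postsynaptic rings are added so that they make up 22% of all
postsynaptic rings. Each presynaptic cluster has, with probability
`aligned_fraction_pre` = 0.77, an aligned receptor partner displaced by an
isotropic Gaussian jitter of 11.2 nm per axis — derived from the measured
14 nm mean lateral nearest-neighbor offset, since the length of an
isotropic Gaussian offset is Rayleigh with mean σ·√(π/2). Remaining
on-ring receptor clusters are unaligned: placed on the nominal
postsynaptic circle, self-avoiding (≥48 nm from other receptor clusters)
and — by the definition of "unaligned" — more than 50 nm from every
presynaptic cluster. Ambient receptor clusters (45% of all receptor
clusters) emulate the perisynaptic receptor pool: they sit in an annular
halo 75–300 nm outside a postsynaptic ring's rim, never within ±75 nm of
any ring's rim (a receptor cluster on the rim would be an on-ring cluster).

Rendering integrates an isotropic Gaussian PSF (FWHM 40 nm for STED-like,
250 nm for confocal-like scenes) exactly over pixels (error-function
formula), adds uniform background (2 expected photons/pixel), and draws
per-pixel Poisson counts, emulating photon-counting detection. One root
seed is split into geometry and photon-noise substreams so geometry can be
held fixed while noise varies.

### An emergent limitation: the apparent receptor-ring diameter

The model cannot simultaneously realize three measured numbers: a 212 nm
presynaptic interpeak diameter, a 244 nm postsynaptic interpeak diameter,
and a 14 nm mean aligned-cluster offset. Aligned receptor clusters are
jittered copies of presynaptic positions (radius ≈ 106 nm); the blurred
radial intensity of the receptor channel is then a mixture of that
component with the unaligned component farther out, and its peak — what an
interpeak measurement reads — cannot be pushed beyond ≈ 112–116 nm radius
for any placement of the unaligned clusters
(`nanoring.unaligned_cluster_radius` documents the saturation analysis).
The same tension is present in the measurements themselves: a 16 nm radial
gap between the two apparent radii exceeds the 14 nm mean offset between
aligned cluster pairs, so the apparent receptor-ring diameter must be an
emergent property of the full receptor distribution rather than the radius
of the aligned maxima. We keep the jitter rule (it reproduces the
nearest-neighbor statistics exactly) and accept that the recovered
apparent postsynaptic diameter on synthetic scenes is ≈ 228 nm, about 6%
below the nominal 244 nm parameter.

## Ring detection

Candidates come from an annular matched filter: for each diameter on a
grid (140–320 nm, step 10 nm) the image is correlated with four unit-sum
Gaussian half-annulus kernels (PSF-matched cross-section, two orthogonal
splits) and a unit-sum interior-hole disk; the score is the minimum
half-annulus response minus the hole response. The score is zero on flat
background and filled disks, and near zero for isolated blobs, which light
up only part of the annulus. Local maxima of the best-scale score map
above threshold — a fraction (default 0.3) of the 99.9th-percentile score,
plus a robust-sigma noise floor — become candidate anchors. The
fractional threshold makes the detection set invariant under global
intensity scaling; the noise floor keeps structure-free images empty.

Rings are then extracted greedily from the image's bright-spot map
(local maxima above a scale-free relative threshold, which recover the
cluster positions): each anchor is fitted (coarse radius scan, Kåsa
circle refit), validated — at least 3 spots within ±30 nm of the rim, no
angular gap above 150° (220° when more than 3 spots support the rim, since
a ring may carry a genuine unpartnered sector), and an empty interior —
and ranked by Gaussian-weighted radial support minus a penalty for nearby
spots the circle leaves unexplained. The best-ranked candidate is
accepted, claims the spots of its synaptic neighbourhood (interior, rim,
and perisynaptic field out to rim + 280 nm — receptor fields extend a few
hundred nm), nearby candidates are re-ranked against the remaining free
spots, and the process repeats ("matching pursuit"). Accepted centers get
a final concentric two-radius polish: receptor rings hold aligned and
unaligned clusters at two concentric radii, and fitting a single circle to
both displaces the center, while a common-center two-radius fit does not.

Detected rings are classified by their radial profile: ring-like requires
the peak-normalized intensity at the center to be at most 0.8 and an
off-center maximum on both signed sides; everything else is non-ring-like
(NRL). Performance on wild-type synthetic scenes: presynaptic recall
≈ 0.96 with no false positives and ~3 nm center error; postsynaptic recall
≈ 0.92 with ~7% false positives — the 45% ambient receptor fraction
produces chance constellations of 3–5 spots on a common circle that no
single-channel image-level criterion we found fully separates from genuine
rings. This detection floor propagates into the cross-channel pairing
fraction (≈ 0.75 measured vs 0.84 generated) and the unopposed-ring
fraction (≈ 30% vs 22% generated); both are reported as measured.

## Line profiles, clusters, alignment

Line profiles average 36 evenly spaced full-diameter lines (bilinear
sampling, 5° spacing — enough to cover cluster bumps of ~9° angular SD)
into one signed-distance profile on a ±300 nm grid at pixel resolution,
normalized to its own maximum. Normalization is per ring, before any
averaging. The interpeak distance refines each side's maximum with a
3-point parabola (20 nm sampling would otherwise quantize diameters) and
is computed per ring and then averaged; the periphery readout is the value
at exactly |300| nm. On noiseless single rings the interpeak distance
matches the analytic maximum of the PSF-convolved ring to within 2 nm
(the blurred rim peak sits ~1.5 nm inside the true radius).

Cluster detection lightly smooths the image (Gaussian, SD one pixel),
collects local maxima in the annulus rim ± 60 nm, keeps maxima whose
height relative to the annulus's 5th–100th percentile range exceeds 0.2
(robust to the background pedestal, and scale-free), enforces a 40 nm
minimum separation (the optical resolution — closer maxima are
unresolvable by construction) by keeping the brighter of any pair, and
refines positions with separable parabolas. Cross-channel alignment uses
greedy mutual-nearest matching in increasing distance order (uncapped);
a presynaptic cluster is aligned iff matched within 40 nm — the
resolution bound, exposed as a parameter. Pooled matched distances are
histogrammed (4 nm bins) and fitted with a Gaussian, following the
field's convention, although the underlying law is Rayleigh; both the
fitted mean and the raw mean are reported. Rings with an empty cluster
set contribute missing (not zero) fractions and are excluded from means.
An independent angular route samples the intensity along the ring
circumference, counts angular peaks, and matches them across channels
within the 40 nm arc equivalent.

## Confocal quantification and statistics

Puncta are segmented by per-image Otsu threshold (a fixed-threshold mode
exists for settings-matched comparisons), connected components, and a
0.05 µm² minimum area; each punctum carries its mean intensity and area in
physical units. `relative_change` reports 100·(treated/control − 1) of
mean punctum intensity and refuses to compare groups whose
acquisition-settings flags differ, encoding the caveat that magnitudes are
not comparable across time points acquired with different settings.
Distributions are compared with the two-sample Kolmogorov–Smirnov test;
group designs use Mann–Whitney (two groups) or Kruskal–Wallis with Dunn's
Bonferroni-adjusted pairwise comparisons, switching to Welch/ANOVA + Tukey
when every group passes the D'Agostino–Pearson normality screen. The
quantal-content helper is the plain EPSP/mEPSP amplitude ratio.

Condition presets scale the generator's photon budgets by the reported
confocal intensity changes (e.g. −8%/+23% at 5 min of receptor blockade)
and, where measured, carry condition-specific cluster means and diameters.
The 5-minute preset changes only intensities, so its confocal recovery
isolates the segmentation + normalization path.

## Problem sizes and tolerances

Recovery analyses use 200-ring fields at 10 nm pixels (≈ 1500² px),
three seeds — large enough that binomial error on the recovered fractions
is a few percent, small enough that the full panel runs in minutes on one
CPU. Ring search spans 140–320 nm diameters; sub-pixel refinements are
clipped to ±0.5 sample. Degenerate inputs (empty fields, constant images,
empty cluster sets) return empty results or explicit missing values, never
errors, except where a contract is violated (unnormalized profiles,
non-ring-like rings passed to annulus operations).

## What passing recovery does and does not show

The generator emulates in-plane rings, Gaussian optics, Poisson counting
and a stylized ambient pool; it does not model deconvolution artifacts,
chromatic aberration, tilted/perpendicular synapses (tilt is rendered but
not analyzed), 3D structure, or spatially correlated backgrounds. Recovery
on these scenes therefore validates the estimators' correctness and
calibration under the stated architecture, not their behaviour on every
property of real micrographs.
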