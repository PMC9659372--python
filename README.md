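# nanoring

Quantification of **transsynaptic nanocolumn rings** in two-channel
super-resolution images of synapses.

At the *Drosophila* neuromuscular junction, the presynaptic active-zone
scaffold Bruchpilot (Brp) and the postsynaptic glutamate receptors (GluR)
each resolve, at STED resolution (<40 nm), into rings of discrete protein
clusters ~210–250 nm in diameter. Most Brp clusters are opposed, across
the synaptic cleft, by a GluR cluster a few tens of nanometres away —
transsynaptic *nanocolumns* arranged on a ring. `nanoring` implements the
image analysis this architecture calls for:

- **ring detection** in a single channel (annular matched filter +
  cluster-support ring extraction) and cross-channel **ring pairing** by
  the ≤40 nm center rule;
- **radial line-profile analysis** anchored at ring centers: normalized
  average profiles, interpeak-distance diameters (the distance between the
  two rim peaks), center/periphery intensity, ring-like vs non-ring-like
  (NRL) classification, cross-channel peak offset;
- **within-ring cluster analysis**: sub-pixel local-maxima detection in
  the ring annulus, cluster-count histograms with Gaussian fits, lateral
  nearest-neighbor distances and aligned-cluster fractions, plus an
  independent circumference (angular) profile route;
- **confocal-level quantification** for plasticity time-courses: punctum
  segmentation, mean intensity/area, normalization to time-matched
  controls, Kolmogorov–Smirnov and nonparametric group statistics;
- a **synthetic scene generator** (STED-like and confocal-like, 16-bit
  TIFF, Poisson photon statistics) with named condition presets and full
  latent ground truth, so every estimator is validated by parameter
  recovery.

## Worked example

```python
import numpy as np
import nanoring as nr

preset = nr.make_preset("wild_type")          # measured architecture as defaults
truth = nr.sample_ground_truth(preset, n_rings=50, seed=1)
img_pre, img_post = nr.render_scene(truth, preset, seed=1)

pre_rings = nr.detect_rings(img_pre)
post_rings = nr.detect_rings(img_post)

diameters = [nr.interpeak_distance(r.profile) for r in pre_rings
             if r.profile_class == "ring_like"]
counts = [nr.detect_clusters(img_pre, r).n for r in pre_rings
          if r.profile_class == "ring_like"]
pairing = nr.pair_rings(pre_rings, post_rings)

alignments = []
for i, j, _ in pairing.pairs:
    a = nr.detect_clusters(img_pre, pre_rings[i])
    b = nr.detect_clusters(img_post, post_rings[j])
    if a.n and b.n:
        alignments.append(nr.nn_alignment(a, b))
pooled = nr.pool_alignments(alignments)
```

Output for this scene:

```
detected 49 presynaptic and 53 postsynaptic rings
mean presynaptic interpeak diameter: 207.5 nm
mean clusters per presynaptic ring: 4.71
paired pre-ring fraction: 0.71
aligned cluster fraction: 75%
NN-distance Gaussian-fit mean: 12.9 nm
```

The generator placed 50 presynaptic rings of nominal diameter 212 nm with
4.7 clusters each; 84% carry an opposed receptor ring, 77% of presynaptic
clusters an aligned receptor partner at a Rayleigh(11.2 nm) offset
(mean 14 nm). The pipeline recovers diameters, counts, alignment fraction
and nearest-neighbor distance from the rendered images; the paired
fraction reads lower than the generated 0.84 because detection of
receptor rings against the dense ambient-receptor background is imperfect
(see `docs/methods.md` for the error budget).

## Command line

```bash
nanoring simulate --preset wild_type --n-rings 200 --seed 1 --out scene/
nanoring all --preset wild_type --n-rings 200 --seed 1 --out run/
nanoring detect --pre pre.tif --post post.tif --out run/
nanoring report --run-dir run/
nanoring confocal --treated tx.tif --control ctrl.tif --channel post
```

`nanoring all` writes TIFFs, ground truth, per-ring CSVs (detections,
profiles, clusters, pairings, alignment), summary JSON, a manifest with
the config hash and seeds, and report figures. Re-running an archived
config reproduces all outputs bit-for-bit.

## Condition presets

`wild_type` carries the measured wild-type architecture (diameters
212/244 nm, 4.7/6.0 clusters per ring, 77% aligned, pairing probability
0.84, 22% unopposed receptor rings, 45% ambient receptor spots).
`phtx_5min`, `phtx_15min`, `phtx_30min` encode the receptor-blockade
homeostatic time-course (channel-specific intensity changes; the 30-min
preset also carries its measured cluster means and diameters);
`GluRIIA_OE`, `GluRIIB_null`, and `neto109` encode the receptor-subunit
and auxiliary-subunit perturbations. `make_preset(name, **overrides)`
validates every field.

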