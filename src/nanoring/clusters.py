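"""Local-maxima (cluster) detection within ring annuli and alignment statistics.

Within each detected ring the image is lightly smoothed and local intensity
maxima are collected in the annulus around the ring radius; maxima must
clear a prominence threshold relative to the annulus's 5th–100th intensity
percentile range (robust to the background pedestal) and be separated by at
least the optical resolution (default 40 nm — closer maxima are
unresolvable by construction).  Cross-channel cluster alignment is scored
by greedy mutual-nearest matching; a presynaptic cluster counts as aligned
when matched within the threshold.  An independent readout samples the
intensity along the ring circumference and matches angular peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .io import ImageChannel
from .matching import greedy_mutual_match
from .rings import RingDetection


@dataclass
class ClusterSet:
    """Sub-pixel local maxima within one ring's annulus."""

    ring_id: int
    channel: str
    x_nm: np.ndarray
    y_nm: np.ndarray
    intensity: np.ndarray
    annulus_inner_nm: float
    annulus_outer_nm: float

    @property
    def n(self) -> int:
        return len(self.x_nm)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm])


@dataclass
class AlignmentResult:
    """Cross-channel cluster matching for one paired ring.

    ``aligned_fraction`` is None (missing, not 0) when the presynaptic set
    is empty.
    """

    ring_id: int
    pairs: list[tuple[int, int, float]]
    distances_nm: np.ndarray
    n_pre: int
    n_post: int
    n_aligned: int
    aligned_fraction: float | None


@dataclass
class GaussianFit:
    mean: float
    sd: float
    ok: bool


@dataclass
class CountHistogram:
    """Cluster-count histogram with Gaussian fit and raw moments."""

    counts: np.ndarray           # per-ring counts
    bin_centers: np.ndarray
    density: np.ndarray
    raw_mean: float
    raw_sem: float
    n_rings: int
    fit: GaussianFit | None


def _gauss(x, a, mu, sd):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def fit_gaussian(bin_centers: np.ndarray, density: np.ndarray) -> GaussianFit:
    """Least-squares Gaussian fit to a histogram; falls back to moments."""
    x = np.asarray(bin_centers, float)
    y = np.asarray(density, float)
    w = y.sum()
    mu0 = float((x * y).sum() / w) if w > 0 else float(x.mean())
    sd0 = float(np.sqrt(max(((x - mu0) ** 2 * y).sum() / w, 1e-12))) if w > 0 else 1.0
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=[y.max(), mu0, max(sd0, 1e-3)],
                            maxfev=5000)
        return GaussianFit(mean=float(popt[1]), sd=abs(float(popt[2])), ok=True)
    except (RuntimeError, ValueError):
        return GaussianFit(mean=mu0, sd=sd0, ok=False)


def detect_clusters(
    image: ImageChannel,
    ring: RingDetection,
    annulus_halfwidth_nm: float = 60.0,
    min_sep_nm: float = 40.0,
    prominence: float = 0.2,
) -> ClusterSet:
    """Detect local intensity maxima within a ring's annulus.

    Raises ValueError if the ring is classified non-ring-like (the annulus
    is undefined without a valid diameter).
    """
    if ring.profile_class != "ring_like":
        raise ValueError(f"ring {ring.ring_id} is not ring-like; annulus undefined")
    px = image.pixel_size_nm
    r_in = max(ring.diameter_nm / 2.0 - annulus_halfwidth_nm, 0.0)
    r_out = ring.diameter_nm / 2.0 + annulus_halfwidth_nm

    # local crop around the ring
    row_c, col_c = image.to_px(ring.x_nm, ring.y_nm)
    pad = int(np.ceil(r_out / px)) + 3
    i0 = max(int(round(row_c)) - pad, 0)
    j0 = max(int(round(col_c)) - pad, 0)
    i1 = min(int(round(row_c)) + pad + 1, image.data.shape[0])
    j1 = min(int(round(col_c)) + pad + 1, image.data.shape[1])
    crop = gaussian_filter(np.asarray(image.data[i0:i1, j0:j1], float), sigma=1.0)

    ii, jj = np.mgrid[i0:i1, j0:j1]
    xs = (jj + 0.5) * px
    ys = (ii + 0.5) * px
    rr = np.hypot(xs - ring.x_nm, ys - ring.y_nm)
    mask = (rr >= r_in) & (rr <= r_out)
    empty = ClusterSet(ring.ring_id, image.channel, np.empty(0), np.empty(0),
                       np.empty(0), r_in, r_out)
    if mask.sum() < 9:
        return empty

    vals = crop[mask]
    lo = float(np.percentile(vals, 5))
    hi = float(vals.max())
    if hi <= lo:
        return empty
    level = lo + prominence * (hi - lo)

    # strict-ish local maxima on the crop, restricted to the annulus
    from scipy.ndimage import maximum_filter

    is_max = (crop == maximum_filter(crop, size=3)) & mask & (crop >= level)
    is_max[0, :] = is_max[-1, :] = is_max[:, 0] = is_max[:, -1] = False
    mi, mj = np.nonzero(is_max)
    if mi.size == 0:
        return empty
    order = np.lexsort((mj, mi, -crop[mi, mj]))
    mi, mj = mi[order], mj[order]

    # enforce minimum separation, keeping the brighter of any violating pair
    min_sep_px = min_sep_nm / px
    kept: list[int] = []
    for k in range(len(mi)):
        if all((mi[k] - mi[m]) ** 2 + (mj[k] - mj[m]) ** 2 >= min_sep_px**2
               for m in kept):
            kept.append(k)

    xs_out, ys_out, amps = [], [], []
    for k in kept:
        i, j = int(mi[k]), int(mj[k])
        di, dj = _sub(crop, i, j)
        # crop indices are local; shift by the crop origin (i0, j0)
        xs_out.append((j0 + j + dj + 0.5) * px)
        ys_out.append((i0 + i + di + 0.5) * px)
        amps.append(float(crop[i, j]))
    return ClusterSet(ring.ring_id, image.channel, np.asarray(xs_out),
                      np.asarray(ys_out), np.asarray(amps), r_in, r_out)


def _sub(crop: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Separable 3-point parabolic sub-pixel offset at (i, j)."""
    def off(a, b, c):
        den = a - 2 * b + c
        return 0.0 if den >= 0 else float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))

    di = off(crop[i - 1, j], crop[i, j], crop[i + 1, j]) if 0 < i < crop.shape[0] - 1 else 0.0
    dj = off(crop[i, j - 1], crop[i, j], crop[i, j + 1]) if 0 < j < crop.shape[1] - 1 else 0.0
    return di, dj


def count_histogram(cluster_sets: list[ClusterSet], min_rings_for_fit: int = 10
                    ) -> CountHistogram:
    """Histogram of clusters per ring with a least-squares Gaussian fit.

    With fewer than ``min_rings_for_fit`` rings the fit is skipped and only
    the raw mean ± SEM reported.
    """
    counts = np.array([cs.n for cs in cluster_sets], float)
    if counts.size == 0:
        raise ValueError("no cluster sets")
    lo, hi = int(counts.min()), int(counts.max())
    centers = np.arange(lo, hi + 1, dtype=float)
    density = np.array([(counts == c).mean() for c in centers])
    raw_mean = float(counts.mean())
    raw_sem = float(counts.std(ddof=1) / np.sqrt(counts.size)) if counts.size > 1 else 0.0
    fit = fit_gaussian(centers, density) if counts.size >= min_rings_for_fit and \
        len(centers) >= 3 else None
    return CountHistogram(counts=counts, bin_centers=centers, density=density,
                          raw_mean=raw_mean, raw_sem=raw_sem,
                          n_rings=counts.size, fit=fit)


def nn_alignment(
    pre: ClusterSet,
    post: ClusterSet,
    align_threshold_nm: float = 40.0,
) -> AlignmentResult:
    """Match pre and post clusters of one paired ring and score alignment.

    Greedy mutual-nearest matching in increasing distance order (uncapped);
    all matched distances are recorded, and a presynaptic cluster counts as
    aligned iff its match lies within ``align_threshold_nm``.
    """
    pairs = greedy_mutual_match(pre.xy, post.xy)
    dists = np.array([d for _, _, d in pairs])
    n_aligned = int((dists <= align_threshold_nm).sum()) if dists.size else 0
    frac = n_aligned / pre.n if pre.n > 0 else None
    return AlignmentResult(ring_id=pre.ring_id, pairs=pairs, distances_nm=dists,
                           n_pre=pre.n, n_post=post.n, n_aligned=n_aligned,
                           aligned_fraction=frac)


@dataclass
class PooledAlignment:
    """Alignment statistics pooled over rings."""

    distances_nm: np.ndarray
    mean_aligned_fraction: float
    n_rings: int
    nn_fit: GaussianFit
    raw_mean_nm: float


def pool_alignments(results: list[AlignmentResult],
                    bin_width_nm: float = 4.0) -> PooledAlignment:
    """Pool per-ring matches; Gaussian-fit the NN-distance histogram.

    Rings with missing aligned fraction (empty presynaptic set) are
    excluded from the fraction mean, per the missing-not-zero convention.
    """
    dists = np.concatenate([r.distances_nm for r in results]) if results else np.empty(0)
    fracs = [r.aligned_fraction for r in results if r.aligned_fraction is not None]
    if dists.size == 0:
        raise ValueError("no matched cluster pairs to pool")
    edges = np.arange(0.0, dists.max() + bin_width_nm, bin_width_nm)
    if len(edges) < 4:
        edges = np.arange(0.0, dists.max() + 4 * bin_width_nm, bin_width_nm)
    hist, _ = np.histogram(dists, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fit = fit_gaussian(centers, hist)
    return PooledAlignment(distances_nm=dists,
                           mean_aligned_fraction=float(np.mean(fracs)) if fracs else float("nan"),
                           n_rings=len(results), nn_fit=fit,
                           raw_mean_nm=float(dists.mean()))


# ---------------------------------------------------------------------------
# Circumference (angular) profile
# ---------------------------------------------------------------------------

def circumference_profile(
    image: ImageChannel,
    ring: RingDetection,
    n_samples: int = 360,
    radius_nm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear intensity along the ring circle; returns (angles_deg, values)."""
    if ring.profile_class != "ring_like":
        raise ValueError(f"ring {ring.ring_id} is not ring-like")
    from scipy.ndimage import map_coordinates

    r = ring.diameter_nm / 2.0 if radius_nm is None else radius_nm
    ang = np.arange(n_samples) * (2 * np.pi / n_samples)
    xs = ring.x_nm + r * np.cos(ang)
    ys = ring.y_nm + r * np.sin(ang)
    px = image.pixel_size_nm
    vals = map_coordinates(np.asarray(image.data, float),
                           [ys / px - 0.5, xs / px - 0.5], order=1, mode="nearest")
    return np.rad2deg(ang), vals


def angular_peaks(
    angles_deg: np.ndarray,
    values: np.ndarray,
    radius_nm: float,
    min_sep_nm: float = 40.0,
    prominence: float = 0.2,
) -> np.ndarray:
    """Angular positions (deg) of circumference-profile peaks.

    Peaks are local maxima on the circular profile above the prominence
    level (relative to the 5th–100th percentile range), separated by at
    least the arc equivalent of ``min_sep_nm``.
    """
    v = np.asarray(values, float)
    n = v.size
    lo = float(np.percentile(v, 5))
    hi = float(v.max())
    if hi <= lo:
        return np.empty(0)
    level = lo + prominence * (hi - lo)
    is_max = (v >= np.roll(v, 1)) & (v > np.roll(v, -1)) & (v >= level)
    idx = np.nonzero(is_max)[0]
    if idx.size == 0:
        return np.empty(0)
    idx = idx[np.argsort(-v[idx], kind="stable")]
    min_sep_deg = np.rad2deg(min_sep_nm / radius_nm)
    step = 360.0 / n
    kept: list[int] = []
    for i in idx:
        ai = i * step
        ok = all(min(abs(ai - k * step), 360.0 - abs(ai - k * step)) >= min_sep_deg
                 for k in kept)
        if ok:
            kept.append(int(i))
    return np.sort(np.array(kept) * step)


def angular_aligned_fraction(
    pre_peaks_deg: np.ndarray,
    post_peaks_deg: np.ndarray,
    radius_nm: float,
    tol_nm: float = 40.0,
) -> float | None:
    """Fraction of presynaptic angular peaks with a postsynaptic peak within
    the arc equivalent of ``tol_nm``; None when there are no pre peaks."""
    if len(pre_peaks_deg) == 0:
        return None
    if len(post_peaks_deg) == 0:
        return 0.0
    tol_deg = np.rad2deg(tol_nm / radius_nm)
    post = np.asarray(post_peaks_deg, float)
    n_hit = 0
    for a in pre_peaks_deg:
        d = np.abs(post - a)
        d = np.minimum(d, 360.0 - d)
        if d.min() <= tol_deg:
            n_hit += 1
    return n_hit / len(pre_peaks_deg)
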