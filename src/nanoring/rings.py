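"""Automated ring detection, profile classification, and cross-channel pairing.

Detection combines an annular matched filter with cluster-support ring
extraction.  For each candidate diameter d the image is correlated with
ring-shaped kernels (Gaussian annulus of radius d/2, cross-section matched
to the PSF, split into half-annuli) and a disk-shaped hole kernel, all
normalized to unit sum; the score is the minimum half-annulus response
minus the hole response — zero on flat background and filled disks and
negligible for isolated non-annular blobs.  Local maxima of the best-scale
score map above threshold anchor ring candidates, which are then fitted,
validated and ranked on the image's bright-spot map and extracted greedily
with spot ownership (matching pursuit); see the helpers below.

The detection threshold is a fraction of the field's robust (99.9th
percentile) score so the detection set is invariant under global intensity
scaling; an additional noise floor (a multiple of the score map's robust
sigma) keeps structure-free images detection-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import ImageChannel
from .matching import greedy_mutual_match
from .profiles import GeometryError, LineProfile, extract_profile

#: score-map noise floor, in robust sigmas of the score map
NOISE_FLOOR_SIGMA = 8.0


@dataclass
class RingDetection:
    """One detected annular structure."""

    ring_id: int
    channel: str
    x_nm: float
    y_nm: float
    diameter_nm: float
    score: float
    profile_class: str = "NRL"  # "ring_like" or "NRL"
    profile: LineProfile | None = None


@dataclass
class RingPairing:
    """Cross-channel pairing of detected rings by the center-distance rule."""

    pairs: list[tuple[int, int, float]]  # (pre index, post index, distance nm)
    unopposed_pre: list[int]
    unopposed_post: list[int]

    @property
    def paired_pre_fraction(self) -> float:
        n = len(self.pairs) + len(self.unopposed_pre)
        return len(self.pairs) / n if n else float("nan")

    @property
    def unopposed_post_fraction(self) -> float:
        n = len(self.pairs) + len(self.unopposed_post)
        return len(self.unopposed_post) / n if n else float("nan")


def classify_profile(profile: LineProfile, center_max_fraction: float = 0.8) -> str:
    """Classify a peak-normalized profile as ``"ring_like"`` or ``"NRL"``.

    Ring-like requires the normalized intensity at 0 nm to be at most
    ``center_max_fraction`` and an off-center maximum on both signed sides
    (the side maximum must not sit immediately next to the center, as it
    does for a filled disk).
    """
    if not profile.is_normalized(atol=1e-6):
        raise ValueError("profile must be peak-normalized (max = 1)")
    d, y = profile.distances_nm, profile.intensities
    zero = len(d) // 2
    if y[zero] > center_max_fraction:
        return "NRL"
    left, right = y[:zero][::-1], y[zero + 1:]  # both ordered outward from center
    for side in (left, right):
        if len(side) < 3 or int(np.argmax(side)) < 1:
            return "NRL"
    return "ring_like"


def _ring_kernels(d_px: float, sigma_px: float, radius_px: int) -> list[np.ndarray]:
    """Half-annulus and hole-disk kernels for one candidate diameter.

    Returns [left, right, top, bottom, hole]: four unit-sum Gaussian
    half-annuli (two orthogonal splits) and a unit-sum disk strictly inside
    the rim.  The ring score is min(half responses) - hole response, so a
    single off-center blob (which lights up only part of the annulus)
    cannot masquerade as a ring, while a genuine ring with clusters all
    around the circumference responds in every half.
    """
    ax = np.arange(-radius_px, radius_px + 1)
    yy, xx = ax[:, None], ax[None, :]
    rr = np.hypot(yy, xx)
    ann = np.exp(-((rr - d_px / 2.0) ** 2) / (2.0 * sigma_px**2))
    halves = []
    for m in (xx <= 0, xx >= 0, yy <= 0, yy >= 0):
        h = ann * m
        halves.append(h / h.sum())
    hole_r = max(d_px / 2.0 - 2.0 * sigma_px, 1.0)
    hole = (rr <= hole_r).astype(float)
    halves.append(hole / hole.sum())
    return halves


def _quadratic_subpixel(score: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Sub-pixel offset of a score-map local maximum (separable parabola)."""
    def off(a, b, c):
        den = a - 2 * b + c
        if den >= 0:
            return 0.0
        return float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))

    di = off(score[i - 1, j], score[i, j], score[i + 1, j]) if 0 < i < score.shape[0] - 1 else 0.0
    dj = off(score[i, j - 1], score[i, j], score[i, j + 1]) if 0 < j < score.shape[1] - 1 else 0.0
    return di, dj


def _rim_radius(
    data: np.ndarray,
    px: float,
    x_nm: float,
    y_nm: float,
    r_min: float,
    r_max: float,
    n_angles: int = 24,
) -> float:
    """Rim radius: argmax of the orientation-averaged radial intensity."""
    from scipy.ndimage import map_coordinates

    rs = np.arange(0.0, r_max + 2 * px, px)
    th = np.arange(n_angles) * (2 * np.pi / n_angles)
    xs = x_nm + rs[None, :] * np.cos(th)[:, None]
    ys = y_nm + rs[None, :] * np.sin(th)[:, None]
    prof = map_coordinates(data, [ys.ravel() / px - 0.5, xs.ravel() / px - 0.5],
                           order=1, mode="nearest").reshape(n_angles, rs.size).mean(0)
    lo = int(np.searchsorted(rs, r_min))
    i = lo + int(np.argmax(prof[lo:]))
    r = rs[i]
    if 0 < i < rs.size - 1:
        a, b, c = prof[i - 1], prof[i], prof[i + 1]
        den = a - 2 * b + c
        if den < 0:
            r += float(np.clip(0.5 * (a - c) / den, -0.5, 0.5)) * px
    return float(min(max(r, r_min), r_max))


def _refine_center(
    data: np.ndarray,
    px: float,
    x_nm: float,
    y_nm: float,
    radius_nm: float,
    sigma_px: float,
    window_px: int = 3,
) -> tuple[float, float]:
    """Refine a ring center by maximizing the annulus-matched response
    over a small pixel window, with quadratic sub-pixel interpolation."""
    r_px = radius_nm / px
    half = int(np.ceil(r_px + 3 * sigma_px))
    i0 = int(round(y_nm / px - 0.5))
    j0 = int(round(x_nm / px - 0.5))
    pad = half + window_px
    if (i0 - pad < 0 or j0 - pad < 0
            or i0 + pad + 1 > data.shape[0] or j0 + pad + 1 > data.shape[1]):
        return x_nm, y_nm
    patch = data[i0 - pad:i0 + pad + 1, j0 - pad:j0 + pad + 1]
    ax = np.arange(-half, half + 1)
    rr = np.hypot(ax[:, None], ax[None, :])
    ann = np.exp(-((rr - r_px) ** 2) / (2.0 * sigma_px**2))
    ann /= ann.sum()
    resp = fftconvolve(patch, ann[::-1, ::-1], mode="valid")
    k = int(np.argmax(resp))
    i, j = divmod(k, resp.shape[1])
    di, dj = _quadratic_subpixel(resp, i, j) if (0 < i < resp.shape[0] - 1
                                                 and 0 < j < resp.shape[1] - 1) else (0.0, 0.0)
    return ((j0 - window_px + j + dj + 0.5) * px,
            (i0 - window_px + i + di + 0.5) * px)


def _circle_refit(
    spots: np.ndarray,
    x_nm: float,
    y_nm: float,
    radius_nm: float,
    r_min: float,
    r_max: float,
    band_nm: float = 30.0,
    iters: int = 3,
) -> tuple[float, float, float]:
    """Refine (center, radius) by algebraic (Kåsa) circle fit on rim spots.

    Iterates fit -> inlier reselection; falls back to the input when fewer
    than three rim spots support the circle.
    """
    x, y, r = x_nm, y_nm, radius_nm
    for _ in range(iters):
        rr = np.hypot(spots[:, 0] - x, spots[:, 1] - y)
        sel = spots[np.abs(rr - r) <= band_nm]
        if len(sel) < 3:
            break
        a = np.column_stack([2 * sel[:, 0], 2 * sel[:, 1], np.ones(len(sel))])
        b = sel[:, 0] ** 2 + sel[:, 1] ** 2
        try:
            sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        except np.linalg.LinAlgError:
            break
        cx, cy = float(sol[0]), float(sol[1])
        r2 = sol[2] + cx**2 + cy**2
        if r2 <= 0:
            break
        rn = float(np.sqrt(r2))
        if not r_min <= rn <= r_max:
            break
        x, y, r = cx, cy, rn
    return x, y, r


def _concentric_refit(
    sel: np.ndarray,
    x_nm: float,
    y_nm: float,
    iters: int = 12,
) -> tuple[float, float]:
    """Center of concentric sub-circles through the given rim spots.

    Ring clusters sit on up to two concentric circles (an aligned inner
    and an unaligned outer sub-population); fitting one circle to both
    displaces the center, while a common-center two-radius fit stays on
    the ring axis.  Alternates radius-group assignment (best 1D split)
    with a gradient step on the shared center.
    """
    if len(sel) < 4:
        return x_nm, y_nm
    cx, cy = x_nm, y_nm
    for _ in range(iters):
        dx = sel[:, 0] - cx
        dy = sel[:, 1] - cy
        rr = np.hypot(dx, dy)
        if np.any(rr < 1e-9):
            break
        order = np.argsort(rr)
        rs = rr[order]
        # best split of sorted radii into <=2 groups (min within-group SSE)
        best_sse, best_split = np.inf, 0
        for split in range(len(rs) + 1):
            lo, hi = rs[:split], rs[split:]
            sse = (np.var(lo) * len(lo) if len(lo) else 0.0) + \
                  (np.var(hi) * len(hi) if len(hi) else 0.0)
            if sse < best_sse:
                best_sse, best_split = sse, split
        rho = np.empty_like(rr)
        lo_idx = order[:best_split]
        hi_idx = order[best_split:]
        if len(lo_idx):
            rho[lo_idx] = rr[lo_idx].mean()
        if len(hi_idx):
            rho[hi_idx] = rr[hi_idx].mean()
        ux, uy = dx / rr, dy / rr
        step_x = float(np.mean((rr - rho) * ux))
        step_y = float(np.mean((rr - rho) * uy))
        cx += step_x
        cy += step_y
        if abs(step_x) < 0.05 and abs(step_y) < 0.05:
            break
    return cx, cy


def _spot_map(data: np.ndarray, px: float, rel_threshold: float = 0.15
              ) -> np.ndarray:
    """Sub-cluster spot positions (nm): bright local maxima of the image.

    Threshold is relative to the robust intensity range (median to 99.9th
    percentile of the lightly smoothed image), so the spot set is invariant
    under global intensity scaling.
    """
    from scipy.ndimage import gaussian_filter, maximum_filter

    sm = gaussian_filter(data, 1.0)
    med = float(np.median(sm))
    hi = float(np.percentile(sm, 99.9))
    if hi <= med:
        return np.empty((0, 2))
    level = med + rel_threshold * (hi - med)
    is_max = (sm == maximum_filter(sm, size=3)) & (sm >= level)
    is_max[0, :] = is_max[-1, :] = is_max[:, 0] = is_max[:, -1] = False
    mi, mj = np.nonzero(is_max)
    return np.column_stack([(mj + 0.5) * px, (mi + 0.5) * px])


def _validate_ring(
    spots: np.ndarray,
    x_nm: float,
    y_nm: float,
    radius_nm: float,
    band_nm: float = 30.0,
    min_peaks: int = 3,
    max_gap_deg: float = 150.0,
) -> tuple[bool, tuple]:
    """Candidate validation and rank by cluster support.

    A genuine ring is composed of at least ``min_peaks`` clusters at a
    common radius, spread around the circumference; the candidate must
    have that many spots within ``band_nm`` of its rim, with angular-gap
    limits.  The rank is (weighted support, -max_gap), where support sums
    a Gaussian weight of each rim spot's radial residual (sigma 18 nm):
    the true center of a ring collects all of its clusters on a tight rim,
    while an off-center or wrong-radius ghost collects fewer spots at
    looser radii, so the true center out-ranks any ghost net built from a
    cluster subset plus stray spots.

    Returns (passes, rank).
    """
    if len(spots) == 0:
        return False, (0.0, -360.0)
    dx = spots[:, 0] - x_nm
    dy = spots[:, 1] - y_nm
    rr = np.hypot(dx, dy)
    resid = rr - radius_nm
    on_rim = np.abs(resid) <= band_nm
    n = int(on_rim.sum())
    # weighted rim support, penalized by unexplained nearby spots: a ghost
    # circle leaves the parent ring's remaining clusters stranded in its
    # neighborhood, while the true center accounts for all of them
    unexplained = int(((rr <= radius_nm + 60.0) & ~on_rim).sum())
    support = float(np.exp(-(resid[on_rim] / 18.0) ** 2 / 2.0).sum()) - unexplained
    # a ring has a hole: a bright cluster well inside the rim means this
    # circle is not the rim of an annular structure
    if np.any(rr < radius_nm - 60.0):
        return False, (support, -360.0)
    if n < min_peaks:
        return False, (support, -360.0)
    ang = np.sort(np.degrees(np.arctan2(dy[on_rim], dx[on_rim])) % 360.0)
    gaps = np.diff(np.append(ang, ang[0] + 360.0))
    max_gap = float(gaps.max())
    rank = (support, -max_gap)
    # a ring with >= min_peaks + 1 clusters may carry a genuine hole (an
    # unpartnered sector); minimal 3-spot support must be well spread
    ok = max_gap <= (max_gap_deg if n == min_peaks else max_gap_deg + 70.0)
    return ok, rank


def detect_rings(
    image: ImageChannel,
    d_min_nm: float = 140.0,
    d_max_nm: float = 320.0,
    score_threshold: float = 0.3,
    psf_fwhm_nm: float = 40.0,
    d_step_nm: float = 10.0,
    classify: bool = True,
    profile_max_r_nm: float = 300.0,
) -> list[RingDetection]:
    """Detect annular structures in one channel.

    Parameters
    ----------
    d_min_nm, d_max_nm
        Diameter search range (grid step ``d_step_nm``).
    score_threshold
        Detection threshold as a fraction of the 99.9th percentile of the
        score map (intensity-scale-free).
    classify
        If True, each detection's radial profile is extracted (where it
        fits inside the image) and classified ring-like vs NRL.

    Returns detections sorted by descending score; empty or structure-free
    images yield an empty list.
    """
    if not d_min_nm < d_max_nm:
        raise ValueError(f"d_min_nm ({d_min_nm}) must be < d_max_nm ({d_max_nm})")
    px = image.pixel_size_nm
    if px > d_min_nm / 4.0:
        raise ValueError(
            f"pixel size {px} nm too coarse for d_min {d_min_nm} nm (need <= d_min/4)"
        )
    data = np.asarray(image.data, float)
    if data.size == 0 or np.ptp(data) == 0:
        return []

    sigma_px = (psf_fwhm_nm / 2.35482) / px
    diameters = np.arange(d_min_nm, d_max_nm + 0.5 * d_step_nm, d_step_nm)
    radius_px = int(np.ceil(d_max_nm / 2.0 / px + 3 * sigma_px))

    best = np.full(data.shape, -np.inf)
    for d in diameters:
        kernels = _ring_kernels(d / px, sigma_px, radius_px)
        resp = [fftconvolve(data, kern, mode="same") for kern in kernels]
        s = np.minimum.reduce(resp[:4]) - resp[4]
        np.maximum(best, s, out=best)

    pos = best[best > 0]
    if pos.size == 0:
        return []
    robust_max = float(np.percentile(best, 99.9))
    med = float(np.median(best))
    mad_sigma = 1.4826 * float(np.median(np.abs(best - med)))
    thr = max(score_threshold * robust_max, med + NOISE_FLOOR_SIGMA * mad_sigma)

    # local maxima of the best-scale score map
    from scipy.ndimage import maximum_filter

    local = (best == maximum_filter(best, size=3)) & (best >= thr)
    # exclude a one-pixel border (no sub-pixel refinement there)
    local[0, :] = local[-1, :] = local[:, 0] = local[:, -1] = False
    ii, jj = np.nonzero(local)
    if ii.size == 0:
        return []
    order = np.lexsort((jj, ii, -best[ii, jj]))
    ii, jj = ii[order], jj[order]

    # per-candidate image-driven refinement: rim radius from the radial
    # mean profile, center from a local annulus correlation, then ring
    # topology validation — before suppression, so that an off-center
    # ghost (which fails validation) cannot suppress the genuine center
    spots = _spot_map(data, px)
    r_grid = np.arange(d_min_nm / 2.0, d_max_nm / 2.0 + 1.0, 5.0)

    # candidate centers: each score-map anchor contributes its raw position
    # and an intensity-refined one (on lopsided rings either may be closer
    # to the true center)
    centers = []
    for k in range(len(ii)):
        i, j = int(ii[k]), int(jj[k])
        di, dj = _quadratic_subpixel(best, i, j)
        x_nm, y_nm = image.to_nm(i + di, j + dj)
        sc = float(best[i, j])
        r0 = _rim_radius(data, px, x_nm, y_nm, d_min_nm / 2.0, d_max_nm / 2.0)
        xr, yr = _refine_center(data, px, x_nm, y_nm, r0, sigma_px)
        centers.append((x_nm, y_nm, sc))
        if np.hypot(xr - x_nm, yr - y_nm) > 1.0:
            centers.append((xr, yr, sc))

    def best_config(cx, cy, free_mask):
        """Best validated (rank, radius, center) at a candidate position.

        The coarse radius scan finds the supporting cluster set; a Kåsa
        circle refit on those spots then removes the candidate's residual
        center error before the final ranking, so a near-center candidate
        scores the full support of its ring.
        """
        sub = spots[free_mask] if len(spots) else spots
        out = None
        for r_try in r_grid:
            ok, rank = _validate_ring(sub, cx, cy, r_try)
            if ok and (out is None or rank > out[0]):
                out = (rank, r_try, cx, cy)
        if out is not None and len(sub) >= 3:
            fx, fy, fr = _circle_refit(sub, out[2], out[3], out[1],
                                       d_min_nm / 2.0, d_max_nm / 2.0)
            ok, rank = _validate_ring(sub, fx, fy, fr)
            if ok and rank > out[0]:
                out = (rank, fr, fx, fy)
        return out

    # greedy ring extraction with re-evaluation (matching pursuit): accept
    # the globally best-supported ring, let it claim the spots of its
    # synaptic neighborhood (interior, rim, perisynaptic field), re-rank
    # nearby candidates against the remaining free spots, repeat.  Ghost
    # configurations that borrowed a true ring's clusters lose their
    # support as soon as the true ring is accepted.
    claimed = np.zeros(len(spots), bool)
    free = ~claimed
    state = [[best_config(cx, cy, free), cx, cy, sc] for cx, cy, sc in centers]
    alive = [s[0] is not None for s in state]
    accepted: list[tuple[float, float, float, float]] = []
    claim_extra_nm = 280.0
    while True:
        k_best, rank_best = -1, None
        for k, s in enumerate(state):
            if alive[k] and s[0] is not None and (rank_best is None or s[0][0] > rank_best):
                k_best, rank_best = k, s[0][0]
        if k_best < 0:
            break
        (_rank, r_acc, cx, cy), _ax, _ay, sc = state[k_best]
        accepted.append((cx, cy, 2.0 * r_acc, sc))
        alive[k_best] = False
        if len(spots):
            rr = np.hypot(spots[:, 0] - cx, spots[:, 1] - cy)
            claimed |= rr <= r_acc + claim_extra_nm
            free = ~claimed
        reach = r_acc + claim_extra_nm + d_max_nm / 2.0 + 40.0
        for k, s in enumerate(state):
            if not alive[k]:
                continue
            dist = np.hypot(s[1] - cx, s[2] - cy)
            # suppression: too close to an accepted ring to be another one
            if dist < d_min_nm / 2.0 or dist < r_acc + d_min_nm / 2.0:
                alive[k] = False
                continue
            if dist <= reach:
                s[0] = best_config(s[1], s[2], free)
                if s[0] is None:
                    alive[k] = False

    detections: list[RingDetection] = []
    for x_nm, y_nm, dnm, sc in sorted(accepted, key=lambda a: -a[3]):
        if len(spots) >= 4:
            rr = np.hypot(spots[:, 0] - x_nm, spots[:, 1] - y_nm)
            sel = spots[np.abs(rr - dnm / 2.0) <= 45.0]
            x_nm, y_nm = _concentric_refit(sel, x_nm, y_nm)
        det = RingDetection(ring_id=len(detections), channel=image.channel,
                            x_nm=x_nm, y_nm=y_nm, diameter_nm=dnm, score=sc)
        if classify:
            try:
                prof = extract_profile(image, (x_nm, y_nm), max_r_nm=profile_max_r_nm,
                                       ring_id=det.ring_id)
                det.profile = prof
                det.profile_class = classify_profile(prof)
            except GeometryError:
                det.profile_class = "NRL"
        detections.append(det)
    return detections


def pair_rings(
    pre: list[RingDetection],
    post: list[RingDetection],
    max_dist_nm: float = 40.0,
) -> RingPairing:
    """Pair pre- and postsynaptic rings whose centers lie within 40 nm.

    Greedy mutual-nearest-neighbor matching in increasing distance order;
    each ring appears in at most one pair, remaining rings are unopposed.
    """
    a = np.array([[r.x_nm, r.y_nm] for r in pre], float).reshape(-1, 2)
    b = np.array([[r.x_nm, r.y_nm] for r in post], float).reshape(-1, 2)
    pairs = greedy_mutual_match(a, b, max_dist=max_dist_nm)
    paired_a = {i for i, _, _ in pairs}
    paired_b = {j for _, j, _ in pairs}
    return RingPairing(
        pairs=pairs,
        unopposed_pre=[i for i in range(len(pre)) if i not in paired_a],
        unopposed_post=[j for j in range(len(post)) if j not in paired_b],
    )
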