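"""Synthetic two-channel STED/confocal scene generator with latent ground truth.

The generative model realizes the transsynaptic nanocolumn-ring architecture:
each synapse is a presynaptic (Brp-like) ring of discrete clusters on a
circle, opposed with probability ``p_ring_opposed`` by a postsynaptic
(GluR-like) ring.  Each presynaptic cluster has, with probability
``aligned_fraction_pre``, an aligned postsynaptic partner displaced by a
small isotropic lateral jitter; the remaining postsynaptic on-ring clusters
are unaligned, and a further ``ambient_spot_fraction`` of postsynaptic
clusters lie off-ring entirely.  Clusters are rendered as Gaussian PSF spots
(photons integrated exactly over pixels) on a diffuse background, and
photon-counting detection is emulated with per-pixel Poisson draws.

Apparent vs nominal postsynaptic diameter
-----------------------------------------
Aligned postsynaptic clusters necessarily sit near the presynaptic radius
(they are jittered copies of presynaptic positions, which is what makes
the lateral nearest-neighbor distance ~14 nm); unaligned on-ring clusters
sit on the nominal postsynaptic circle.  The *apparent* postsynaptic
diameter — the peak of the blurred radial intensity, what a line-profile
interpeak measurement reads — is therefore a compromise between the two
radii and falls short of ``ring_diameter_post_nm``; see
:func:`unaligned_cluster_radius` for the analysis showing no unaligned
placement can remove this shortfall while the jitter rule holds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erf

from .io import ImageChannel
from .presets import ScenePreset

# Field layout: synapse sites on a jittered square grid.  Spacing leaves
# room for a 300 nm line-profile radius around every ring plus slack.
SITE_SPACING_NM = 900.0
SITE_JITTER_NM = 80.0
FIELD_MARGIN_NM = 150.0
# Minimum separation between same-channel clusters of one ring (clusters
# closer than the optical resolution would be one cluster).
MIN_CLUSTER_SEP_NM = 48.0
# Half-width of the annular band around each postsynaptic ring from which
# ambient (off-ring, by definition) spots are excluded, and the radial
# width of the perisynaptic halo in which they are placed.
AMBIENT_EXCLUSION_NM = 75.0
AMBIENT_HALO_WIDTH_NM = 225.0
# An unaligned postsynaptic cluster must not itself satisfy the 40 nm
# alignment criterion against any presynaptic cluster (definitional
# consistency; small margin for localization noise).
UNALIGNED_MIN_PRE_DIST_NM = 50.0

RING_COLUMNS = [
    "ring_id", "x_nm", "y_nm", "has_pre", "has_post", "opposed",
    "diameter_pre_nm", "diameter_post_nm", "tilt_deg",
]
CLUSTER_COLUMNS = [
    "cluster_id", "ring_id", "channel", "x_nm", "y_nm", "intensity",
    "partner_id",
]


@dataclass
class GroundTruth:
    """Exact latent geometry of one rendered scene.

    ``rings`` has one row per synapse site (columns ``RING_COLUMNS``);
    ``clusters`` one row per fluorophore cluster (columns
    ``CLUSTER_COLUMNS``; ``ring_id`` is -1 for ambient spots, ``partner_id``
    -1 where no transsynaptic partner exists).
    """

    rings: pd.DataFrame
    clusters: pd.DataFrame
    field_width_nm: float
    field_height_nm: float
    preset_name: str = ""

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def clusters_of(self, ring_id: int, channel: str) -> pd.DataFrame:
        c = self.clusters
        return c[(c.ring_id == ring_id) & (c.channel == channel)]

    def validate(self) -> None:
        """Check structural invariants; raise AssertionError on violation."""
        c = self.clusters
        linked = c[c.partner_id >= 0]
        by_id = c.set_index("cluster_id")
        for cid, pid in zip(linked.cluster_id, linked.partner_id):
            assert by_id.loc[pid, "partner_id"] == cid, "partner links not symmetric"
        assert linked.partner_id.is_unique, "partner links not one-to-one"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "preset_name": self.preset_name,
            "field_width_nm": self.field_width_nm,
            "field_height_nm": self.field_height_nm,
            "rings": self.rings.to_dict(orient="list"),
            "clusters": self.clusters.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        rings = pd.DataFrame(d["rings"], columns=RING_COLUMNS)
        clusters = pd.DataFrame(d["clusters"], columns=CLUSTER_COLUMNS)
        return cls(rings, clusters, d["field_width_nm"], d["field_height_nm"],
                   d["preset_name"])


def _empty_truth(preset: ScenePreset) -> GroundTruth:
    side = 2 * FIELD_MARGIN_NM + SITE_SPACING_NM
    return GroundTruth(
        rings=pd.DataFrame(columns=RING_COLUMNS),
        clusters=pd.DataFrame(columns=CLUSTER_COLUMNS),
        field_width_nm=side,
        field_height_nm=side,
        preset_name=preset.name,
    )


def unaligned_cluster_radius(preset: ScenePreset) -> float:
    """Analysis tool: unaligned-cluster radius that would best match the
    apparent postsynaptic diameter (not used by the sampler, which places
    unaligned clusters on the nominal circle).

    Solves (by grid search) for the radius r_u bringing the maximum of the
    angular-average radial intensity — the mixture of aligned clusters
    (Gaussian at the presynaptic radius, width = sqrt(jitter^2 +
    psf_sigma^2)) and unaligned clusters (Gaussian at r_u, width =
    psf_sigma), weighted by expected counts and diluted by the 1/r
    circumference factor — as close as possible to the apparent
    postsynaptic radius.  The solve can saturate: when the aligned
    component dominates, the merged peak cannot be pushed arbitrarily far
    out, and the closest achievable radius is returned.
    """
    target = preset.ring_diameter_post_nm / 2.0
    mu_a = preset.ring_diameter_pre_nm / 2.0
    w_a = preset.aligned_fraction_pre * preset.clusters_per_ring_pre
    w_u = preset.clusters_per_ring_post - w_a
    if w_u <= 0 or w_a <= 0:
        return target
    s = preset.psf_sigma_nm
    s_a = math.hypot(preset.alignment_jitter_sd_nm, s)

    r = np.arange(max(mu_a - 3 * s_a, 1.0), target + 4 * s + 50.0, 0.1)
    candidates = np.arange(max(target - 20.0, mu_a), target + 45.0, 0.25)
    best_ru, best_err = target, np.inf
    for ru in candidates:
        f = ((w_a / s_a) * np.exp(-((r - mu_a) ** 2) / (2 * s_a**2))
             + (w_u / s) * np.exp(-((r - ru) ** 2) / (2 * s**2))) / r
        peak = r[np.argmax(f)]
        err = abs(peak - target)
        if err < best_err - 1e-12:
            best_err, best_ru = err, ru
    return float(best_ru)


def _ring_cluster_angles(rng: np.random.Generator, n: int, jitter_deg: float) -> np.ndarray:
    """Approximately equispaced angles with wrapped-Gaussian jitter."""
    base = rng.uniform(0, 2 * np.pi)
    ang = base + np.arange(n) * (2 * np.pi / n)
    ang = ang + rng.normal(0.0, np.deg2rad(jitter_deg), size=n)
    return np.mod(ang, 2 * np.pi)


def _truncated_isotropic_jitter(rng: np.random.Generator, sd: float,
                                max_norm_sd: float = 3.0) -> tuple[float, float]:
    """Isotropic 2D Gaussian offset, rejected beyond max_norm_sd * sd."""
    if sd <= 0:
        return 0.0, 0.0
    for _ in range(100):
        dx, dy = rng.normal(0.0, sd, size=2)
        if math.hypot(dx, dy) <= max_norm_sd * sd:
            return float(dx), float(dy)
    return 0.0, 0.0


def _count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Rounded Gaussian cluster count, truncated at 1."""
    return max(1, int(round(rng.normal(mean, sd))))


def sample_ground_truth(
    preset: ScenePreset,
    n_rings: int,
    seed: int,
    field_shape_nm: tuple[float, float] | None = None,
) -> GroundTruth:
    """Draw the latent geometry of a scene with ``n_rings`` presynaptic rings.

    All randomness flows from ``seed`` (geometry substream; photon noise in
    :func:`render_scene` uses an independent substream of the same root so
    geometry can be held fixed while noise varies).

    Parameters
    ----------
    field_shape_nm : (height_nm, width_nm), optional
        Explicit field size.  Raises ``ValueError`` if the synapse sites
        plus margins do not fit.
    """
    if n_rings < 0:
        raise ValueError("n_rings must be >= 0")
    if n_rings == 0:
        return _empty_truth(preset)

    rng = np.random.default_rng([int(seed), 0x6E67])  # geometry substream

    # --- synapse sites ---------------------------------------------------
    opposed = rng.random(n_rings) < preset.p_ring_opposed
    n_opposed = int(opposed.sum())
    p_u = preset.p_post_ring_unopposed
    n_unopposed_post = int(round(n_opposed * p_u / (1.0 - p_u))) if p_u < 1 else 0
    n_sites = n_rings + n_unopposed_post

    ncols = int(math.ceil(math.sqrt(n_sites)))
    nrows = int(math.ceil(n_sites / ncols))
    width = 2 * FIELD_MARGIN_NM + ncols * SITE_SPACING_NM
    height = 2 * FIELD_MARGIN_NM + nrows * SITE_SPACING_NM
    if field_shape_nm is not None:
        req_h, req_w = height, width
        height, width = float(field_shape_nm[0]), float(field_shape_nm[1])
        if height < req_h or width < req_w:
            raise ValueError(
                f"field {height:.0f}x{width:.0f} nm too small for {n_sites} "
                f"sites (need >= {req_h:.0f}x{req_w:.0f} nm)"
            )
    idx = np.arange(n_sites)
    gx = FIELD_MARGIN_NM + ((idx % ncols) + 0.5) * SITE_SPACING_NM
    gy = FIELD_MARGIN_NM + ((idx // ncols) + 0.5) * SITE_SPACING_NM
    gx = gx + rng.uniform(-SITE_JITTER_NM, SITE_JITTER_NM, n_sites)
    gy = gy + rng.uniform(-SITE_JITTER_NM, SITE_JITTER_NM, n_sites)

    # Unaligned on-ring clusters sit on the nominal postsynaptic circle.
    # Aligned clusters are jittered copies of presynaptic positions, so the
    # apparent (profile-peak) post diameter is an emergent compromise that
    # falls short of the nominal parameter; see unaligned_cluster_radius
    # for the saturation analysis.
    r_u_offset = 0.0
    log_sd = preset.cluster_intensity_lognorm_sd
    # mean-one multiplicative intensity heterogeneity
    def _amps(rng, n, scale):
        return scale * rng.lognormal(-0.5 * log_sd**2, log_sd, size=n)

    ring_rows: list[dict] = []
    cl_rows: list[dict] = []
    next_cid = 0

    def _add_cluster(ring_id, channel, x, y, intensity, partner=-1):
        nonlocal next_cid
        cl_rows.append(dict(cluster_id=next_cid, ring_id=ring_id, channel=channel,
                            x_nm=float(x), y_nm=float(y), intensity=float(intensity),
                            partner_id=int(partner)))
        next_cid += 1
        return next_cid - 1

    def _sample_post_ring(ring_id, cx, cy, d_post, pre_pts, pre_ids, pre_amp_ids):
        """Place postsynaptic clusters for one ring; returns nothing."""
        n_post = _count(rng, preset.clusters_per_ring_post, preset.cluster_count_sd)
        if len(pre_ids):
            n_aligned = int(rng.binomial(len(pre_ids), preset.aligned_fraction_pre))
            n_aligned = min(n_aligned, n_post)
        else:
            n_aligned = 0
        chosen = rng.choice(len(pre_ids), size=n_aligned, replace=False) if n_aligned else []
        placed: list[tuple[float, float]] = []
        amps = _amps(rng, n_post, preset.intensity_scale_post)
        k = 0
        for ci in chosen:
            px, py = pre_pts[ci]
            dx, dy = _truncated_isotropic_jitter(rng, preset.alignment_jitter_sd_nm)
            cid = _add_cluster(ring_id, "post", px + dx, py + dy, amps[k],
                               partner=pre_ids[ci])
            cl_rows[pre_amp_ids[ci]]["partner_id"] = cid
            placed.append((px + dx, py + dy))
            k += 1
        # unaligned on-ring clusters: latent radius consistent with the
        # apparent diameter; self-avoiding angular placement.  A cluster is
        # unaligned by definition, so it must also keep clear of every
        # presynaptic cluster by more than the alignment threshold.
        r_lat = d_post / 2.0 + (r_u_offset if n_aligned else 0.0)
        n_unal = n_post - n_aligned
        if n_unal > 0:
            for ang in _ring_cluster_angles(rng, n_unal, preset.angular_jitter_sd_deg):
                x = cx + r_lat * math.cos(ang)
                y = cy + r_lat * math.sin(ang)
                for _ in range(60):
                    if (all(math.hypot(x - qx, y - qy) >= MIN_CLUSTER_SEP_NM
                            for qx, qy in placed)
                            and all(math.hypot(x - qx, y - qy) >= UNALIGNED_MIN_PRE_DIST_NM
                                    for qx, qy in pre_pts)):
                        break
                    a = rng.uniform(0, 2 * np.pi)
                    x = cx + r_lat * math.cos(a)
                    y = cy + r_lat * math.sin(a)
                _add_cluster(ring_id, "post", x, y, amps[k])
                placed.append((x, y))
                k += 1

    # --- presynaptic rings (first n_rings sites) -------------------------
    for i in range(n_rings):
        d_pre = max(4 * preset.psf_fwhm_nm,
                    rng.normal(preset.ring_diameter_pre_nm, preset.diameter_sd_nm))
        d_post = max(4 * preset.psf_fwhm_nm,
                     rng.normal(preset.ring_diameter_post_nm, preset.diameter_sd_nm))
        is_opp = bool(opposed[i])
        ring_rows.append(dict(ring_id=i, x_nm=gx[i], y_nm=gy[i], has_pre=True,
                              has_post=is_opp, opposed=is_opp,
                              diameter_pre_nm=d_pre,
                              diameter_post_nm=d_post if is_opp else np.nan,
                              tilt_deg=preset.tilt_deg))
        n_pre = _count(rng, preset.clusters_per_ring_pre, preset.cluster_count_sd)
        angles = _ring_cluster_angles(rng, n_pre, preset.angular_jitter_sd_deg)
        amps = _amps(rng, n_pre, preset.intensity_scale_pre)
        pre_pts, pre_ids, pre_amp_ids = [], [], []
        for ang, a in zip(angles, amps):
            x = gx[i] + (d_pre / 2.0) * math.cos(ang)
            y = gy[i] + (d_pre / 2.0) * math.sin(ang)
            row_idx = next_cid
            cid = _add_cluster(i, "pre", x, y, a)
            pre_pts.append((x, y))
            pre_ids.append(cid)
            pre_amp_ids.append(row_idx)
        if is_opp:
            _sample_post_ring(i, gx[i], gy[i], d_post, pre_pts, pre_ids, pre_amp_ids)

    # --- unopposed postsynaptic rings ------------------------------------
    for j in range(n_unopposed_post):
        rid = n_rings + j
        d_post = max(4 * preset.psf_fwhm_nm,
                     rng.normal(preset.ring_diameter_post_nm, preset.diameter_sd_nm))
        ring_rows.append(dict(ring_id=rid, x_nm=gx[rid], y_nm=gy[rid], has_pre=False,
                              has_post=True, opposed=False,
                              diameter_pre_nm=np.nan, diameter_post_nm=d_post,
                              tilt_deg=preset.tilt_deg))
        _sample_post_ring(rid, gx[rid], gy[rid], d_post, [], [], [])

    # --- ambient (off-ring) postsynaptic spots ---------------------------
    # Perisynaptic receptor pool: each ambient spot sits in an annular halo
    # around a postsynaptic ring, outside the on-ring exclusion band of
    # every ring (off-ring by definition) but close enough to raise the
    # receptor-channel intensity at the ring periphery.
    n_onring_post = sum(1 for c in cl_rows if c["channel"] == "post")
    a = preset.ambient_spot_fraction
    n_ambient = int(round(n_onring_post * a / (1.0 - a))) if a < 1 else 0
    post_rings = [r for r in ring_rows if r["has_post"]]
    if n_ambient > 0 and post_rings:
        centers = np.array([[r["x_nm"], r["y_nm"]] for r in post_rings])
        radii = np.array([r["diameter_post_nm"] / 2.0 for r in post_rings])
        tree = cKDTree(centers)
        amps = _amps(rng, n_ambient, preset.intensity_scale_post)
        kept: list[tuple[float, float]] = []
        while len(kept) < n_ambient:
            m = max(2 * (n_ambient - len(kept)), 16)
            parent = rng.integers(0, len(post_rings), m)
            rad = radii[parent] + AMBIENT_EXCLUSION_NM + \
                rng.uniform(0.0, AMBIENT_HALO_WIDTH_NM, m)
            ang = rng.uniform(0.0, 2 * np.pi, m)
            cx = centers[parent, 0] + rad * np.cos(ang)
            cy = centers[parent, 1] + rad * np.sin(ang)
            inside = ((cx > FIELD_MARGIN_NM) & (cx < width - FIELD_MARGIN_NM)
                      & (cy > FIELD_MARGIN_NM) & (cy < height - FIELD_MARGIN_NM))
            dist, which = tree.query(np.column_stack([cx, cy]))
            ok = inside & (np.abs(dist - radii[which]) > AMBIENT_EXCLUSION_NM)
            for x, y in zip(cx[ok], cy[ok]):
                if len(kept) < n_ambient:
                    kept.append((float(x), float(y)))
        for (x, y), amp in zip(kept, amps):
            _add_cluster(-1, "post", x, y, amp)

    rings = pd.DataFrame(ring_rows, columns=RING_COLUMNS)
    clusters = pd.DataFrame(cl_rows, columns=CLUSTER_COLUMNS)
    return GroundTruth(rings, clusters, width, height, preset.name)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _splat_gaussians(shape: tuple[int, int], px: float,
                     xs: np.ndarray, ys: np.ndarray, amps: np.ndarray,
                     sigma_nm: float) -> np.ndarray:
    """Sum of 2D Gaussians integrated exactly over pixels (erf formula)."""
    img = np.zeros(shape, dtype=np.float64)
    if len(xs) == 0:
        return img
    s = sigma_nm
    half = int(math.ceil(5 * s / px)) + 1
    h, w = shape
    inv = 1.0 / (s * math.sqrt(2.0))
    for x, y, a in zip(xs, ys, amps):
        j0 = int(x // px)
        i0 = int(y // px)
        jlo, jhi = max(0, j0 - half), min(w, j0 + half + 1)
        ilo, ihi = max(0, i0 - half), min(h, i0 + half + 1)
        if jlo >= jhi or ilo >= ihi:
            continue
        ex = erf((np.arange(jlo, jhi + 1) * px - x) * inv)
        ey = erf((np.arange(ilo, ihi + 1) * px - y) * inv)
        img[ilo:ihi, jlo:jhi] += a * 0.25 * np.outer(np.diff(ey), np.diff(ex))
    return img


def render_expectation(
    truth: GroundTruth,
    preset: ScenePreset,
    psf_fwhm_nm: float | None = None,
    pixel_size_nm: float | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free expected photon images for both channels."""
    fwhm = preset.psf_fwhm_nm if psf_fwhm_nm is None else psf_fwhm_nm
    px = preset.pixel_size_nm if pixel_size_nm is None else pixel_size_nm
    sigma = fwhm / 2.35482
    shape = (int(math.ceil(truth.field_height_nm / px)),
             int(math.ceil(truth.field_width_nm / px)))
    out = {}
    for channel in ("pre", "post"):
        c = truth.clusters
        sel = c[c.channel == channel] if len(c) else c
        img = _splat_gaussians(shape, px,
                               np.asarray(sel.x_nm, float) if len(sel) else np.empty(0),
                               np.asarray(sel.y_nm, float) if len(sel) else np.empty(0),
                               np.asarray(sel.intensity, float) if len(sel) else np.empty(0),
                               sigma)
        out[channel] = img + preset.background_rate
    return out


def render_scene(
    truth: GroundTruth,
    preset: ScenePreset,
    seed: int,
    noise: bool = True,
) -> tuple[ImageChannel, ImageChannel]:
    """Render the STED-like two-channel scene (pre, post).

    Each cluster is an isotropic Gaussian of the preset's PSF FWHM with its
    ground-truth integrated intensity; diffuse background is added and,
    unless ``noise=False``, per-pixel values are Poisson-distributed photon
    counts (photon noise substream of ``seed``).
    """
    exp = render_expectation(truth, preset)
    rng = np.random.default_rng([int(seed), 0x7031])  # photon-noise substream
    chans = []
    for channel in ("pre", "post"):
        data = rng.poisson(exp[channel]).astype(np.float64) if noise else exp[channel]
        chans.append(ImageChannel(data=data, pixel_size_nm=preset.pixel_size_nm,
                                  channel=channel))
    return chans[0], chans[1]


def render_confocal(
    truth: GroundTruth,
    preset: ScenePreset,
    confocal_psf_fwhm_nm: float = 250.0,
    confocal_pixel_nm: float = 100.0,
    seed: int = 0,
    noise: bool = True,
) -> tuple[ImageChannel, ImageChannel]:
    """Render the same latent scene at confocal resolution.

    At ~250 nm FWHM every ring collapses to a single punctum.  Requires
    ``confocal_psf_fwhm_nm > preset.psf_fwhm_nm``.
    """
    if not confocal_psf_fwhm_nm > preset.psf_fwhm_nm:
        raise ValueError("confocal PSF must be wider than the STED PSF")
    exp = render_expectation(truth, preset, psf_fwhm_nm=confocal_psf_fwhm_nm,
                             pixel_size_nm=confocal_pixel_nm)
    rng = np.random.default_rng([int(seed), 0x7032])
    chans = []
    for channel in ("pre", "post"):
        data = rng.poisson(exp[channel]).astype(np.float64) if noise else exp[channel]
        chans.append(ImageChannel(data=data, pixel_size_nm=confocal_pixel_nm,
                                  channel=channel))
    return chans[0], chans[1]
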