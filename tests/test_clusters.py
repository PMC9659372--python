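"""Within-ring cluster detection, counting, and alignment statistics."""

import numpy as np
import pytest

import nanoring as nr
from conftest import single_ring_truth


def _ring_det(cx=700.0, cy=700.0, d=212.0, channel="pre"):
    return nr.RingDetection(ring_id=0, channel=channel, x_nm=cx, y_nm=cy,
                            diameter_nm=d, score=1.0, profile_class="ring_like")


@pytest.fixture(scope="module")
def five_cluster_image(wt_preset):
    truth = single_ring_truth(wt_preset, 700.0, 700.0, 212.0, n_clusters=5)
    img, _ = nr.render_scene(truth, wt_preset, seed=1, noise=False)
    return img, truth


def test_five_clusters_recovered_within_10nm(five_cluster_image):
    img, truth = five_cluster_image
    cs = nr.detect_clusters(img, _ring_det())
    assert cs.n == 5
    cl = truth.clusters
    for x, y in zip(cs.x_nm, cs.y_nm):
        d = np.hypot(cl.x_nm - x, cl.y_nm - y)
        assert d.min() <= 10.0


def test_all_maxima_inside_annulus(five_cluster_image):
    img, _ = five_cluster_image
    cs = nr.detect_clusters(img, _ring_det())
    rr = np.hypot(cs.x_nm - 700.0, cs.y_nm - 700.0)
    assert np.all(rr >= cs.annulus_inner_nm - 1e-6)
    assert np.all(rr <= cs.annulus_outer_nm + 1e-6)


def test_uniform_annulus_gives_no_maxima():
    img = nr.ImageChannel(np.full((150, 150), 9.0), pixel_size_nm=10.0)
    cs = nr.detect_clusters(img, _ring_det())
    assert cs.n == 0


def test_nrl_ring_rejected(five_cluster_image):
    img, _ = five_cluster_image
    det = _ring_det()
    det.profile_class = "NRL"
    with pytest.raises(ValueError):
        nr.detect_clusters(img, det)


def test_cluster_count_invariant_under_intensity_scaling(five_cluster_image):
    img, _ = five_cluster_image
    scaled = nr.ImageChannel(img.data * 11.0, pixel_size_nm=img.pixel_size_nm)
    assert nr.detect_clusters(scaled, _ring_det()).n == \
        nr.detect_clusters(img, _ring_det()).n


def test_count_histogram_hand_computed_moments():
    sets = [nr.ClusterSet(k, "pre", np.zeros(n), np.zeros(n), np.ones(n),
                          46.0, 166.0)
            for k, n in enumerate([4, 5, 5, 6])]
    h = nr.count_histogram(sets, min_rings_for_fit=10)
    assert h.raw_mean == pytest.approx(5.0)
    assert h.raw_sem == pytest.approx(np.sqrt(2 / 3) / 2)
    assert h.fit is None  # too few rings for a Gaussian fit


def test_count_histogram_degenerate_single_count():
    sets = [nr.ClusterSet(k, "pre", np.zeros(5), np.zeros(5), np.ones(5),
                          46.0, 166.0) for k in range(20)]
    h = nr.count_histogram(sets)
    assert h.raw_mean == 5.0
    assert h.raw_sem == 0.0


def test_count_histogram_gaussian_fit_recovers_counts():
    rng = np.random.default_rng(0)
    counts = np.clip(np.round(rng.normal(6.0, 1.0, 300)), 1, None).astype(int)
    sets = [nr.ClusterSet(k, "post", np.zeros(n), np.zeros(n), np.ones(n),
                          46.0, 166.0) for k, n in enumerate(counts)]
    h = nr.count_histogram(sets)
    assert h.fit is not None and h.fit.ok
    assert h.fit.mean == pytest.approx(6.0, abs=0.3)


def _cluster_set(xy, ring_id=0, channel="pre"):
    xy = np.asarray(xy, float).reshape(-1, 2)
    return nr.ClusterSet(ring_id, channel, xy[:, 0], xy[:, 1],
                         np.ones(len(xy)), 46.0, 166.0)


def test_nn_alignment_identity():
    pts = [(100.0, 100.0), (150.0, 180.0), (260.0, 90.0)]
    res = nr.nn_alignment(_cluster_set(pts), _cluster_set(pts, channel="post"))
    assert res.aligned_fraction == 1.0
    np.testing.assert_allclose(res.distances_nm, 0.0)


def test_nn_alignment_empty_pre_is_missing_not_zero():
    res = nr.nn_alignment(_cluster_set(np.empty((0, 2))),
                          _cluster_set([(0.0, 0.0)], channel="post"))
    assert res.aligned_fraction is None


def test_nn_alignment_distances_symmetric():
    rng = np.random.default_rng(3)
    a = rng.uniform(0, 400, (5, 2))
    b = rng.uniform(0, 400, (6, 2))
    fwd = nr.nn_alignment(_cluster_set(a), _cluster_set(b, channel="post"))
    rev = nr.nn_alignment(_cluster_set(b), _cluster_set(a, channel="post"))
    np.testing.assert_allclose(np.sort(fwd.distances_nm),
                               np.sort(rev.distances_nm))


def test_pooled_nn_follows_rayleigh_law():
    """Aligned offsets are isotropic Gaussian, so matched distances are
    Rayleigh(sigma); the Gaussian-fit mean of the pooled histogram must be
    within 10% of the analytic mean sigma*sqrt(pi/2)."""
    sigma = 11.2
    rng = np.random.default_rng(1)
    results = []
    for ring in range(120):
        pre = rng.uniform(200, 800, (5, 2))
        post = pre + rng.normal(0, sigma, pre.shape)
        results.append(nr.nn_alignment(_cluster_set(pre, ring),
                                       _cluster_set(post, ring, "post")))
    pooled = nr.pool_alignments(results)
    analytic = sigma * np.sqrt(np.pi / 2)
    assert pooled.nn_fit.mean == pytest.approx(analytic, rel=0.10)
    assert pooled.mean_aligned_fraction == pytest.approx(1.0, abs=0.02)


def test_zero_jitter_alignment_fraction_exact():
    """For jitter -> 0 the aligned fraction equals the generator's partner
    probability exactly."""
    p = nr.make_preset("wild_type", alignment_jitter_sd_nm=1e-6)
    truth = nr.sample_ground_truth(p, 60, seed=4)
    fracs = []
    for _, ring in truth.rings[truth.rings.opposed].iterrows():
        pre = truth.clusters_of(ring.ring_id, "pre")
        post = truth.clusters_of(ring.ring_id, "post")
        res = nr.nn_alignment(_cluster_set(np.c_[pre.x_nm, pre.y_nm]),
                              _cluster_set(np.c_[post.x_nm, post.y_nm],
                                           channel="post"))
        expected = (pre.partner_id >= 0).mean()
        assert res.aligned_fraction == pytest.approx(expected)
        fracs.append(res.aligned_fraction)
    assert len(fracs) > 20


# ---------------------------------------------------------------------------
# circumference profile
# ---------------------------------------------------------------------------

def test_circumference_profile_finds_five_bumps(five_cluster_image):
    img, truth = five_cluster_image
    ang, vals = nr.circumference_profile(img, _ring_det())
    peaks = nr.angular_peaks(ang, vals, radius_nm=106.0)
    assert len(peaks) == 5
    gaps = np.diff(np.append(np.sort(peaks), np.sort(peaks)[0] + 360.0))
    np.testing.assert_allclose(gaps, 72.0, atol=6.0)


def test_constant_annulus_no_angular_peaks():
    img = nr.ImageChannel(np.full((150, 150), 4.0), pixel_size_nm=10.0)
    ang, vals = nr.circumference_profile(img, _ring_det())
    assert len(nr.angular_peaks(ang, vals, radius_nm=106.0)) == 0


def test_angular_alignment_consistent_with_nn(five_cluster_image, wt_preset):
    """Cross-method referee: angular peak matching on an aligned synthetic
    pair agrees with coordinate matching."""
    img, truth = five_cluster_image
    ang, vals = nr.circumference_profile(img, _ring_det())
    pre_peaks = nr.angular_peaks(ang, vals, radius_nm=106.0)
    frac = nr.angular_aligned_fraction(pre_peaks, pre_peaks, radius_nm=106.0)
    assert frac == 1.0
    shifted = (pre_peaks + 180.0) % 360.0
    assert nr.angular_aligned_fraction(pre_peaks, shifted, 106.0) <= 0.4
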