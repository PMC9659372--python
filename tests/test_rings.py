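"""Ring detection, profile classification, and cross-channel pairing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanoring as nr
from conftest import single_ring_truth


@pytest.fixture(scope="module")
def noiseless_ring(wt_preset):
    truth = single_ring_truth(wt_preset, 700.0, 700.0, 212.0)
    img, _ = nr.render_scene(truth, wt_preset, seed=1, noise=False)
    return img


def _exhaustive_oracle(img, d_grid, step_nm=2.0, window=60.0,
                       center=(700.0, 700.0)):
    """Independent detector: brute-force (rim minus hole) contrast over a
    fine center grid and the diameter grid."""
    from scipy.ndimage import map_coordinates

    px = img.pixel_size_nm
    best = (-np.inf, None, None, None)
    ang = np.arange(64) * 2 * np.pi / 64
    for cx in np.arange(center[0] - window, center[0] + window + 1, step_nm):
        for cy in np.arange(center[1] - window, center[1] + window + 1, step_nm):
            for d in d_grid:
                r = d / 2.0
                xs = cx + r * np.cos(ang)
                ys = cy + r * np.sin(ang)
                rim = map_coordinates(img.data, [ys / px - 0.5, xs / px - 0.5],
                                      order=1).mean()
                xh = cx + r / 3 * np.cos(ang)
                yh = cy + r / 3 * np.sin(ang)
                hole = map_coordinates(img.data, [yh / px - 0.5, xh / px - 0.5],
                                       order=1).mean()
                score = rim - hole
                if score > best[0]:
                    best = (score, cx, cy, d)
    return best


def test_single_ring_detected_and_matches_exhaustive_oracle(noiseless_ring):
    dets = nr.detect_rings(noiseless_ring)
    assert len(dets) == 1
    det = dets[0]
    assert np.hypot(det.x_nm - 700.0, det.y_nm - 700.0) <= 10.0
    assert abs(det.diameter_nm - 212.0) <= 20.0
    _, ox, oy, od = _exhaustive_oracle(noiseless_ring,
                                       np.arange(140.0, 321.0, 10.0))
    assert np.hypot(det.x_nm - ox, det.y_nm - oy) <= 10.0
    assert abs(det.diameter_nm - od) <= 20.0


def test_pure_background_yields_no_detections(wt_preset):
    empty = nr.sample_ground_truth(wt_preset, 0, seed=2)
    img, _ = nr.render_scene(empty, wt_preset, seed=2)
    assert nr.detect_rings(img) == []


def test_constant_image_yields_no_detections():
    img = nr.ImageChannel(np.full((120, 120), 7.0), pixel_size_nm=10.0)
    assert nr.detect_rings(img) == []


def test_invalid_diameter_range_raises():
    img = nr.ImageChannel(np.zeros((64, 64)), pixel_size_nm=10.0)
    with pytest.raises(ValueError):
        nr.detect_rings(img, d_min_nm=300.0, d_max_nm=200.0)
    with pytest.raises(ValueError):
        nr.detect_rings(nr.ImageChannel(np.zeros((64, 64)), pixel_size_nm=50.0))


def test_detection_recall_on_wildtype_scene(small_scene, small_detections):
    """Detections match ground-truth centers at a 40 nm matching radius."""
    from scipy.spatial import cKDTree

    truth = small_scene["truth"]
    for chan, col in (("pre", "has_pre"), ("post", "has_post")):
        dets = small_detections[chan]
        tr = truth.rings[truth.rings[col]]
        tree = cKDTree(np.array([[d.x_nm, d.y_nm] for d in dets]))
        dist, _ = tree.query(np.c_[tr.x_nm, tr.y_nm])
        assert (dist < 40.0).mean() >= 0.8


def test_intensity_scaling_leaves_detection_set_invariant(noiseless_ring):
    base = nr.detect_rings(noiseless_ring)
    scaled_img = nr.ImageChannel(noiseless_ring.data * 7.5,
                                 pixel_size_nm=noiseless_ring.pixel_size_nm)
    scaled = nr.detect_rings(scaled_img)
    assert len(scaled) == len(base)
    for a, b in zip(base, scaled):
        assert np.hypot(a.x_nm - b.x_nm, a.y_nm - b.y_nm) < 1.0
        assert b.score == pytest.approx(7.5 * a.score, rel=1e-6)


def test_translation_equivariance_whole_pixels(noiseless_ring):
    shift = 5
    rolled = nr.ImageChannel(np.roll(noiseless_ring.data, shift, axis=1),
                             pixel_size_nm=noiseless_ring.pixel_size_nm)
    a = nr.detect_rings(noiseless_ring)[0]
    b = nr.detect_rings(rolled)[0]
    assert b.x_nm - a.x_nm == pytest.approx(shift * 10.0, abs=1.0)
    assert b.y_nm == pytest.approx(a.y_nm, abs=1.0)
    assert b.score == pytest.approx(a.score, rel=1e-6)


def test_rotation_equivariance_90deg(noiseless_ring):
    rot = nr.ImageChannel(np.rot90(noiseless_ring.data).copy(),
                          pixel_size_nm=noiseless_ring.pixel_size_nm)
    a = nr.detect_rings(noiseless_ring)[0]
    b = nr.detect_rings(rot)[0]
    h_nm = noiseless_ring.data.shape[1] * 10.0
    # rot90 maps (x, y) -> (y, W - x)
    assert b.x_nm == pytest.approx(a.y_nm, abs=2.0)
    assert b.y_nm == pytest.approx(h_nm - a.x_nm, abs=2.0)
    assert b.score == pytest.approx(a.score, rel=1e-6)
    assert b.diameter_nm == pytest.approx(a.diameter_nm, abs=2.0)


# ---------------------------------------------------------------------------
# profile classification
# ---------------------------------------------------------------------------

def _profile(values, step=20.0):
    n = len(values) // 2
    d = np.arange(-n, n + 1) * step
    return nr.LineProfile(distances_nm=d, intensities=np.asarray(values, float))


def test_filled_disk_profile_is_nrl():
    d = np.arange(-15, 16) * 20.0
    y = np.exp(-(d / 150.0) ** 2)
    assert nr.classify_profile(_profile(y)) == "NRL"


def test_two_peak_profile_with_center_dip_is_ring_like():
    d = np.arange(-15, 16) * 20.0
    y = np.exp(-((np.abs(d) - 106.0) / 40.0) ** 2)
    y[15] = 0.5
    prof = _profile(y / y.max())
    assert nr.classify_profile(prof) == "ring_like"


def test_flat_profile_is_nrl():
    assert nr.classify_profile(_profile(np.ones(31))) == "NRL"


def test_unnormalized_profile_rejected():
    with pytest.raises(ValueError):
        nr.classify_profile(_profile(np.full(31, 0.4)))


# ---------------------------------------------------------------------------
# ring pairing
# ---------------------------------------------------------------------------

def _dets(points, channel="pre"):
    return [nr.RingDetection(ring_id=k, channel=channel, x_nm=x, y_nm=y,
                             diameter_nm=212.0, score=1.0,
                             profile_class="ring_like")
            for k, (x, y) in enumerate(points)]


def test_identical_centers_all_paired_at_zero():
    pts = [(100.0, 100.0), (900.0, 150.0), (500.0, 800.0)]
    pairing = nr.pair_rings(_dets(pts), _dets(pts, "post"))
    assert len(pairing.pairs) == 3
    assert all(d == 0.0 for _, _, d in pairing.pairs)
    assert pairing.unopposed_pre == [] and pairing.unopposed_post == []


def test_two_pre_near_one_post_keeps_the_closer():
    pre = _dets([(100.0, 100.0), (130.0, 100.0)])
    post = _dets([(110.0, 100.0)], "post")
    pairing = nr.pair_rings(pre, post)
    assert pairing.pairs == [(0, 0, pytest.approx(10.0))]
    assert pairing.unopposed_pre == [1]


def test_pairing_symmetry(small_detections):
    fwd = nr.pair_rings(small_detections["pre"], small_detections["post"])
    rev = nr.pair_rings(small_detections["post"], small_detections["pre"])
    assert sorted((j, i) for i, j, _ in fwd.pairs) == \
        sorted((i, j) for i, j, _ in rev.pairs)
    assert fwd.unopposed_pre == rev.unopposed_post


def _optimal_assignment(a, b, max_dist):
    """Brute-force oracle: assignment minimizing total distance with the
    per-pair cap, maximizing the number of pairs first."""
    best = (0, 0.0, [])
    na, nb = len(a), len(b)
    for k in range(min(na, nb), -1, -1):
        found = None
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.permutations(range(nb), k):
                dist = [np.hypot(a[p][0] - b[q][0], a[p][1] - b[q][1])
                        for p, q in zip(ia, ib)]
                if max(dist, default=0.0) > max_dist:
                    continue
                tot = sum(dist)
                if found is None or tot < found[0]:
                    found = (tot, list(zip(ia, ib)))
        if found:
            return found[1]
    return []


def test_greedy_pairing_matches_bruteforce_on_small_fields(wt_preset):
    """On sparse fields (ring spacing >> threshold) greedy mutual-NN
    pairing equals the optimal assignment."""
    for seed in range(4):
        truth = nr.sample_ground_truth(wt_preset, 6, seed=seed)
        rings = truth.rings
        rng = np.random.default_rng(seed)
        pre_pts = [(r.x_nm + rng.normal(0, 8), r.y_nm + rng.normal(0, 8))
                   for _, r in rings[rings.has_pre].iterrows()]
        post_pts = [(r.x_nm + rng.normal(0, 8), r.y_nm + rng.normal(0, 8))
                    for _, r in rings[rings.has_post].iterrows()]
        pairing = nr.pair_rings(_dets(pre_pts), _dets(post_pts, "post"))
        oracle = _optimal_assignment(pre_pts, post_pts, 40.0)
        assert sorted((i, j) for i, j, _ in pairing.pairs) == sorted(oracle)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.tuples(st.floats(0, 1000), st.floats(0, 1000)),
                min_size=0, max_size=6),
       st.lists(st.tuples(st.floats(0, 1000), st.floats(0, 1000)),
                min_size=0, max_size=6))
def test_pairing_invariants(pre_pts, post_pts):
    pairing = nr.pair_rings(_dets(pre_pts), _dets(post_pts, "post"))
    used_pre = [i for i, _, _ in pairing.pairs]
    used_post = [j for _, j, _ in pairing.pairs]
    assert len(set(used_pre)) == len(used_pre)
    assert len(set(used_post)) == len(used_post)
    assert all(d <= 40.0 for _, _, d in pairing.pairs)
    assert len(pairing.pairs) + len(pairing.unopposed_pre) == len(pre_pts)
    assert len(pairing.pairs) + len(pairing.unopposed_post) == len(post_pts)
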