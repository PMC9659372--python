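"""Generator: ground-truth sampling, rendering physics, determinism."""

import numpy as np
import pytest
from scipy.stats import norm

import nanoring as nr


def test_zero_rings_gives_empty_truth(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 0, seed=1)
    assert truth.n_rings == 0
    assert len(truth.clusters) == 0


def test_sampling_is_deterministic(wt_preset):
    a = nr.sample_ground_truth(wt_preset, 10, seed=3)
    b = nr.sample_ground_truth(wt_preset, 10, seed=3)
    assert a.rings.equals(b.rings)
    assert a.clusters.equals(b.clusters)
    img_a, _ = nr.render_scene(a, wt_preset, seed=3)
    img_b, _ = nr.render_scene(b, wt_preset, seed=3)
    assert np.array_equal(img_a.data, img_b.data)


def test_geometry_fixed_while_noise_varies(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 5, seed=3)
    a, _ = nr.render_scene(truth, wt_preset, seed=3)
    b, _ = nr.render_scene(truth, wt_preset, seed=4)
    assert a.data.shape == b.data.shape
    assert not np.array_equal(a.data, b.data)


def test_partner_links_symmetric_one_to_one(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 40, seed=11)
    truth.validate()


def test_aligned_fraction_matches_preset(wt_preset):
    """Fraction of presynaptic clusters with a partner ~ Binomial(0.77)."""
    truth = nr.sample_ground_truth(wt_preset, 200, seed=5)
    opposed = set(truth.rings[truth.rings.opposed].ring_id)
    pre = truth.clusters[(truth.clusters.channel == "pre")
                         & truth.clusters.ring_id.isin(opposed)]
    frac = (pre.partner_id >= 0).mean()
    n = len(pre)
    ci = 1.96 * np.sqrt(0.77 * 0.23 / n)
    assert abs(frac - 0.77) < ci + 0.01


def test_degenerate_jitter_partners_coincide(wt_preset):
    p = nr.make_preset("wild_type", aligned_fraction_pre=1.0,
                       alignment_jitter_sd_nm=1e-9)
    truth = nr.sample_ground_truth(p, 10, seed=2)
    cl = truth.clusters.set_index("cluster_id")
    pre = cl[(cl.channel == "pre") & (cl.partner_id >= 0)]
    assert len(pre) > 0
    for cid, row in pre.iterrows():
        partner = cl.loc[row.partner_id]
        assert np.hypot(row.x_nm - partner.x_nm, row.y_nm - partner.y_nm) < 1e-6


def test_unaligned_on_ring_clusters_lie_on_their_circle(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 50, seed=9)
    rings = truth.rings.set_index("ring_id")
    cl = truth.clusters
    post = cl[(cl.channel == "post") & (cl.ring_id >= 0) & (cl.partner_id < 0)]
    for _, row in post.iterrows():
        ring = rings.loc[row.ring_id]
        r = np.hypot(row.x_nm - ring.x_nm, row.y_nm - ring.y_nm)
        assert abs(r - ring.diameter_post_nm / 2.0) \
            <= 3 * wt_preset.alignment_jitter_sd_nm


def test_photon_conservation_in_expectation(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 10, seed=4)
    pre, post = nr.render_scene(truth, wt_preset, seed=4)
    for chan, img in (("pre", pre), ("post", post)):
        cl = truth.clusters[truth.clusters.channel == chan]
        expected = cl.intensity.sum() + wt_preset.background_rate * img.data.size
        assert abs(img.data.sum() - expected) < 3 * np.sqrt(expected)


def test_background_only_image_is_poisson(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 0, seed=1)
    img, _ = nr.render_scene(truth, wt_preset, seed=1)
    b = wt_preset.background_rate
    n = img.data.size
    assert img.data.mean() == pytest.approx(b, abs=4 * np.sqrt(b / n))
    assert img.data.var() == pytest.approx(b, rel=0.05)


def test_single_cluster_mean_matches_pixel_integrated_gaussian(wt_preset):
    """Average of many Poisson renders vs the closed-form Gaussian
    integrated over pixels (written here independently via norm.cdf)."""
    import pandas as pd
    from nanoring.simulate import CLUSTER_COLUMNS, GroundTruth, RING_COLUMNS

    p = nr.make_preset("wild_type", background_rate=1e-9)
    x0, y0, amp = 325.0, 310.0, 2000.0
    clusters = pd.DataFrame([{"cluster_id": 0, "ring_id": -1, "channel": "pre",
                              "x_nm": x0, "y_nm": y0, "intensity": amp,
                              "partner_id": -1}], columns=CLUSTER_COLUMNS)
    truth = GroundTruth(rings=pd.DataFrame(columns=RING_COLUMNS),
                        clusters=clusters, field_width_nm=650.0,
                        field_height_nm=650.0)
    acc = None
    n_rep = 60
    for k in range(n_rep):
        img, _ = nr.render_scene(truth, p, seed=1000 + k)
        acc = img.data if acc is None else acc + img.data
    mean_img = acc / n_rep

    px = p.pixel_size_nm
    s = p.psf_fwhm_nm / 2.35482
    edges = np.arange(mean_img.shape[1] + 1) * px
    cx = np.diff(norm.cdf(edges, loc=x0, scale=s))
    cy = np.diff(norm.cdf(np.arange(mean_img.shape[0] + 1) * px, loc=y0, scale=s))
    oracle = amp * np.outer(cy, cx)
    peak = oracle.max()
    assert np.abs(mean_img - oracle).max() < 5 * np.sqrt(peak / n_rep) + 0.05 * peak


def test_translation_equivariance_of_expectation(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 4, seed=8)
    exp0 = nr.render_expectation(truth, wt_preset)["pre"]
    shift_px = 3
    shifted = truth.clusters.copy()
    shifted["x_nm"] = shifted.x_nm + shift_px * wt_preset.pixel_size_nm
    truth2 = nr.GroundTruth(truth.rings, shifted, truth.field_width_nm,
                            truth.field_height_nm, truth.preset_name)
    exp1 = nr.render_expectation(truth2, wt_preset)["pre"]
    np.testing.assert_allclose(exp1[:, shift_px:], exp0[:, :-shift_px],
                               rtol=0, atol=1e-9)


def test_confocal_collapses_each_ring_to_one_punctum(wt_preset):
    """At 250 nm FWHM the ring's clusters merge: exactly one local maximum
    remains within a ring radius of each synapse center."""
    from scipy.ndimage import gaussian_filter, maximum_filter

    truth = nr.sample_ground_truth(wt_preset, 9, seed=6)
    _, post = nr.render_confocal(truth, wt_preset, confocal_psf_fwhm_nm=250.0,
                                 confocal_pixel_nm=100.0, seed=6)
    sm = gaussian_filter(post.data, 1.0)
    level = wt_preset.background_rate + 5 * np.sqrt(wt_preset.background_rate)
    is_max = (sm == maximum_filter(sm, size=3)) & (sm > level)
    mi, mj = np.nonzero(is_max)
    mx, my = (mj + 0.5) * 100.0, (mi + 0.5) * 100.0
    for _, ring in truth.rings[truth.rings.has_post].iterrows():
        d = np.hypot(mx - ring.x_nm, my - ring.y_nm)
        # one merged punctum per synapse (its peak may shift toward
        # nearby perisynaptic receptor mass)
        assert (d < 250.0).sum() == 1


def test_confocal_requires_wider_psf(wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 1, seed=1)
    with pytest.raises(ValueError):
        nr.render_confocal(truth, wt_preset, confocal_psf_fwhm_nm=30.0, seed=1)


def test_confocal_intensity_ratio_tracks_preset_scale(wt_preset):
    """Photon-sum ratio between perturbation and control renders follows
    the presets' intensity-scale ratio."""
    p_tx = nr.make_preset("phtx_5min")
    t_wt = nr.sample_ground_truth(wt_preset, 30, seed=2)
    t_tx = nr.sample_ground_truth(p_tx, 30, seed=2)
    _, wt_post = nr.render_confocal(t_wt, wt_preset, seed=2)
    _, tx_post = nr.render_confocal(t_tx, p_tx, seed=2)
    bg = wt_preset.background_rate
    sum_wt = wt_post.data.sum() - bg * wt_post.data.size
    sum_tx = tx_post.data.sum() - bg * tx_post.data.size
    ratio = sum_tx / sum_wt
    assert ratio == pytest.approx(1.23, rel=0.06)


def test_explicit_field_too_small_raises(wt_preset):
    with pytest.raises(ValueError, match="too small"):
        nr.sample_ground_truth(wt_preset, 100, seed=1,
                               field_shape_nm=(2000.0, 2000.0))


def test_truth_json_roundtrip(tmp_path, wt_preset):
    truth = nr.sample_ground_truth(wt_preset, 6, seed=5)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = nr.GroundTruth.from_json(path)
    assert back.n_rings == truth.n_rings
    np.testing.assert_allclose(back.clusters.x_nm, truth.clusters.x_nm)
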