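"""Shared fixtures: synthetic scenes at unit-test and recovery scale."""

from __future__ import annotations

import numpy as np
import pytest

import nanoring as nr


@pytest.fixture(scope="session")
def wt_preset():
    return nr.make_preset("wild_type")


def single_ring_truth(preset, cx, cy, diameter, n_clusters=5, channel="pre",
                      field=1400.0):
    """Hand-built ground truth: one ring of equal-intensity clusters."""
    import pandas as pd

    from nanoring.simulate import CLUSTER_COLUMNS, RING_COLUMNS

    ang = np.arange(n_clusters) * 2 * np.pi / n_clusters + 0.3
    rows = [{"cluster_id": k, "ring_id": 0, "channel": channel,
             "x_nm": cx + diameter / 2 * np.cos(a),
             "y_nm": cy + diameter / 2 * np.sin(a),
             "intensity": preset.intensity_scale_pre, "partner_id": -1}
            for k, a in enumerate(ang)]
    rings = pd.DataFrame([{"ring_id": 0, "x_nm": cx, "y_nm": cy,
                           "has_pre": channel == "pre",
                           "has_post": channel == "post",
                           "opposed": False, "diameter_pre_nm": diameter,
                           "diameter_post_nm": np.nan, "tilt_deg": 0.0}],
                         columns=RING_COLUMNS)
    return nr.GroundTruth(rings=rings,
                          clusters=pd.DataFrame(rows, columns=CLUSTER_COLUMNS),
                          field_width_nm=field, field_height_nm=field)


@pytest.fixture(scope="session")
def small_scene(wt_preset):
    """A 24-ring wild-type scene with ground truth and rendered channels."""
    truth = nr.sample_ground_truth(wt_preset, 24, seed=7)
    pre, post = nr.render_scene(truth, wt_preset, seed=7)
    return {"preset": wt_preset, "truth": truth, "pre": pre, "post": post}


@pytest.fixture(scope="session")
def small_detections(small_scene):
    return {
        "pre": nr.detect_rings(small_scene["pre"]),
        "post": nr.detect_rings(small_scene["post"]),
    }


def _analyze_wt_scene(preset, n_rings, seed):
    """Run the full STED recovery analysis on one wild-type scene."""
    truth = nr.sample_ground_truth(preset, n_rings, seed=seed)
    pre, post = nr.render_scene(truth, preset, seed=seed)
    dpre = nr.detect_rings(pre)
    dpost = nr.detect_rings(post)
    out = {
        "truth": truth,
        "detections": {"pre": dpre, "post": dpost},
        "diameters": {"pre": [], "post": []},
        "counts": {"pre": [], "post": []},
        "alignments": [],
    }
    for chan, dets, img in (("pre", dpre, pre), ("post", dpost, post)):
        for det in dets:
            if det.profile_class != "ring_like":
                continue
            out["diameters"][chan].append(nr.interpeak_distance(det.profile))
            out["counts"][chan].append(nr.detect_clusters(img, det).n)
    pairing = nr.pair_rings(dpre, dpost)
    out["pairing"] = pairing
    for i, j, _ in pairing.pairs:
        if dpre[i].profile_class != "ring_like" or dpost[j].profile_class != "ring_like":
            continue
        a = nr.detect_clusters(pre, dpre[i])
        b = nr.detect_clusters(post, dpost[j])
        if a.n and b.n:
            out["alignments"].append(nr.nn_alignment(a, b))
    return out


@pytest.fixture(scope="session")
def wt_panel(wt_preset):
    """Recovery panel: wild-type preset, 200 rings, seeds 1-3."""
    scenes = [_analyze_wt_scene(wt_preset, 200, seed) for seed in (1, 2, 3)]
    panel = {
        "scenes": scenes,
        "diam_pre": np.concatenate([s["diameters"]["pre"] for s in scenes]),
        "diam_post": np.concatenate([s["diameters"]["post"] for s in scenes]),
        "counts_pre": np.concatenate([s["counts"]["pre"] for s in scenes]),
        "counts_post": np.concatenate([s["counts"]["post"] for s in scenes]),
    }
    panel["alignments"] = [a for s in scenes for a in s["alignments"]]
    panel["pooled"] = nr.pool_alignments(panel["alignments"])
    panel["n_paired"] = sum(len(s["pairing"].pairs) for s in scenes)
    panel["n_pre"] = sum(len(s["detections"]["pre"]) for s in scenes)
    panel["n_post"] = sum(len(s["detections"]["post"]) for s in scenes)
    panel["n_unopposed_post"] = sum(len(s["pairing"].unopposed_post) for s in scenes)
    return panel


@pytest.fixture(scope="session")
def confocal_panel(wt_preset):
    """Confocal renders of the 5-min perturbation vs time-matched control."""
    p_tx = nr.make_preset("phtx_5min")
    changes = {"pre": [], "post": []}
    for seed in (1, 2, 3):
        tr_ctrl = nr.sample_ground_truth(wt_preset, 200, seed=seed)
        tr_tx = nr.sample_ground_truth(p_tx, 200, seed=seed + 100)
        ctrl = nr.render_confocal(tr_ctrl, wt_preset, seed=seed)
        tx = nr.render_confocal(tr_tx, p_tx, seed=seed + 100)
        for k, chan in ((0, "pre"), (1, "post")):
            s_ctrl = nr.segment_puncta(ctrl[k], condition="control")
            s_tx = nr.segment_puncta(tx[k], condition="treated")
            changes[chan].append(nr.relative_change(s_tx, s_ctrl).percent_change)
    return changes
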