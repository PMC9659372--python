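"""End-to-end orchestration: simulate → detect → profile → cluster → report.

A :class:`RunConfig` fully determines a run; re-running an archived config
reproduces all outputs bit-for-bit (all randomness flows from the config
seed).  Stage boundaries are logged; outputs are CSV/JSON plus a manifest
recording the config hash, package version and seeds.  Physical units (nm,
µm²) everywhere; pixel units are never exported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import (AlignmentResult, count_histogram, detect_clusters,
                       nn_alignment, pool_alignments)
from .io import ImageChannel, read_tiff, write_tiff
from .presets import make_preset
from .profiles import (GeometryError, UndefinedDiameterError, average_profiles,
                       extract_profile, intensity_at, interpeak_distance)
from .rings import RingDetection, detect_rings, pair_rings
from .simulate import render_scene, sample_ground_truth

logger = logging.getLogger("nanoring")

CHANNEL_ROLES = ("pre", "post")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    preset: str = "wild_type"
    overrides: dict = field(default_factory=dict)
    n_rings: int = 100
    seed: int = 1
    out_dir: str = "nanoring_run"
    # analysis of existing images instead of simulation
    inputs: dict = field(default_factory=dict)   # role -> TIFF path
    pixel_size_nm: float | None = None           # fallback for inputs w/o metadata
    # detection
    d_min_nm: float = 140.0
    d_max_nm: float = 320.0
    score_threshold: float = 0.3
    psf_fwhm_nm: float = 40.0
    # profiles
    profile_max_r_nm: float = 300.0
    n_angles: int = 36
    # clusters / alignment
    annulus_halfwidth_nm: float = 60.0
    min_sep_nm: float = 40.0
    prominence: float = 0.2
    align_threshold_nm: float = 40.0
    pair_max_dist_nm: float = 40.0
    force: bool = False

    def validate(self) -> None:
        for role in self.inputs:
            if role not in CHANNEL_ROLES:
                raise ValueError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
        if self.inputs and set(self.inputs) != set(CHANNEL_ROLES):
            raise ValueError("inputs must map both 'pre' and 'post' channels")
        if self.n_rings < 0:
            raise ValueError("n_rings must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(bad))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _analyze_channel(image: ImageChannel, cfg: RunConfig) -> tuple[list[RingDetection], pd.DataFrame]:
    dets = detect_rings(image, d_min_nm=cfg.d_min_nm, d_max_nm=cfg.d_max_nm,
                        score_threshold=cfg.score_threshold,
                        psf_fwhm_nm=cfg.psf_fwhm_nm,
                        profile_max_r_nm=cfg.profile_max_r_nm)
    rows = []
    for det in dets:
        row = dict(ring_id=det.ring_id, channel=image.channel, x_nm=det.x_nm,
                   y_nm=det.y_nm, score=det.score, profile_class=det.profile_class,
                   diameter_nm=np.nan, center_intensity=np.nan,
                   periphery_intensity=np.nan)
        if det.profile is not None:
            row["center_intensity"] = intensity_at(det.profile, 0.0)
            row["periphery_intensity"] = intensity_at(
                det.profile, min(cfg.profile_max_r_nm, det.profile.distances_nm[-1]))
            if det.profile_class == "ring_like":
                try:
                    row["diameter_nm"] = interpeak_distance(det.profile)
                except UndefinedDiameterError:
                    pass
        rows.append(row)
    return dets, pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write outputs under ``config.out_dir``.

    Returns a result bundle: per-stage DataFrames plus a summary dict.
    Refuses to overwrite an existing manifest unless ``config.force``.
    """
    config.validate()
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to re-run")
    out.mkdir(parents=True, exist_ok=True)

    preset = make_preset(config.preset, **config.overrides)
    truth = None
    if config.inputs:
        logger.info("stage=load inputs=%s", config.inputs)
        images = {role: read_tiff(path, pixel_size_nm=config.pixel_size_nm,
                                  channel=role)
                  for role, path in config.inputs.items()}
    else:
        logger.info("stage=simulate preset=%s n_rings=%d seed=%d",
                    preset.name, config.n_rings, config.seed)
        truth = sample_ground_truth(preset, config.n_rings, config.seed)
        img_pre, img_post = render_scene(truth, preset, config.seed)
        images = {"pre": img_pre, "post": img_post}
        for role, img in images.items():
            write_tiff(out / f"scene_{role}.tif", img)
        truth.to_json(out / "ground_truth.json")
        preset.to_json(out / "preset.json")

    detections: dict[str, list[RingDetection]] = {}
    tables = []
    for role in CHANNEL_ROLES:
        logger.info("stage=detect channel=%s", role)
        dets, table = _analyze_channel(images[role], config)
        detections[role] = dets
        tables.append(table)
    det_table = pd.concat(tables, ignore_index=True)
    det_table.to_csv(out / "detections.csv", index=False)

    prof_rows = []
    for role in CHANNEL_ROLES:
        for det in detections[role]:
            if det.profile is None:
                continue
            for d, v in zip(det.profile.distances_nm, det.profile.intensities):
                prof_rows.append(dict(ring_id=det.ring_id, channel=role,
                                      distance_nm=float(d), norm_intensity=float(v)))
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)

    logger.info("stage=pair")
    pairing = pair_rings(detections["pre"], detections["post"],
                         max_dist_nm=config.pair_max_dist_nm)
    pd.DataFrame(pairing.pairs, columns=["pre_id", "post_id", "distance_nm"]) \
        .to_csv(out / "ring_pairs.csv", index=False)

    logger.info("stage=clusters")
    cluster_rows, align_rows, alignments = [], [], []
    counts = {role: [] for role in CHANNEL_ROLES}
    for role in CHANNEL_ROLES:
        for det in detections[role]:
            if det.profile_class != "ring_like":
                continue
            cs = detect_clusters(images[role], det,
                                 annulus_halfwidth_nm=config.annulus_halfwidth_nm,
                                 min_sep_nm=config.min_sep_nm,
                                 prominence=config.prominence)
            counts[role].append(cs)
            for x, y, a in zip(cs.x_nm, cs.y_nm, cs.intensity):
                cluster_rows.append(dict(ring_id=det.ring_id, channel=role,
                                         x_nm=x, y_nm=y, intensity=a))
    for i_pre, i_post, _ in pairing.pairs:
        det_pre, det_post = detections["pre"][i_pre], detections["post"][i_post]
        if det_pre.profile_class != "ring_like" or det_post.profile_class != "ring_like":
            continue
        cs_pre = detect_clusters(images["pre"], det_pre,
                                 annulus_halfwidth_nm=config.annulus_halfwidth_nm,
                                 min_sep_nm=config.min_sep_nm,
                                 prominence=config.prominence)
        cs_post = detect_clusters(images["post"], det_post,
                                  annulus_halfwidth_nm=config.annulus_halfwidth_nm,
                                  min_sep_nm=config.min_sep_nm,
                                  prominence=config.prominence)
        res = nn_alignment(cs_pre, cs_post,
                           align_threshold_nm=config.align_threshold_nm)
        alignments.append(res)
        align_rows.append(dict(
            pre_ring_id=det_pre.ring_id, post_ring_id=det_post.ring_id,
            n_pre=res.n_pre, n_post=res.n_post, n_aligned=res.n_aligned,
            aligned_fraction=res.aligned_fraction,
            mean_nn_nm=float(res.distances_nm.mean()) if res.distances_nm.size else np.nan,
        ))
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.csv", index=False)
    pd.DataFrame(align_rows).to_csv(out / "alignment.csv", index=False)

    logger.info("stage=summarize")
    summary: dict = {"n_detected": {r: len(detections[r]) for r in CHANNEL_ROLES},
                     "paired_pre_fraction": pairing.paired_pre_fraction,
                     "unopposed_post_fraction": pairing.unopposed_post_fraction}
    histograms: dict = {}
    for role in CHANNEL_ROLES:
        sub = det_table[(det_table.channel == role) & det_table.diameter_nm.notna()]
        summary[f"diameter_{role}_nm"] = float(sub.diameter_nm.mean()) if len(sub) else None
        nrl = det_table[det_table.channel == role]
        summary[f"nrl_fraction_{role}"] = float((nrl.profile_class == "NRL").mean()) \
            if len(nrl) else None
        if counts[role]:
            ch = count_histogram(counts[role])
            summary[f"cluster_count_{role}"] = ch.raw_mean
            histograms[f"count_{role}"] = {
                "bin_centers": ch.bin_centers.tolist(),
                "density": ch.density.tolist(),
                "raw_mean": ch.raw_mean, "raw_sem": ch.raw_sem,
                "fit_mean": ch.fit.mean if ch.fit else None,
                "fit_sd": ch.fit.sd if ch.fit else None,
            }
    if alignments and any(r.distances_nm.size for r in alignments):
        pooled = pool_alignments(alignments)
        summary["mean_aligned_fraction"] = pooled.mean_aligned_fraction
        summary["nn_fit_mean_nm"] = pooled.nn_fit.mean
        summary["nn_raw_mean_nm"] = pooled.raw_mean_nm
        histograms["nn_distance"] = {"distances_nm": pooled.distances_nm.tolist(),
                                     "fit_mean": pooled.nn_fit.mean,
                                     "fit_sd": pooled.nn_fit.sd}
    (out / "histograms.json").write_text(json.dumps(histograms, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "version": __version__, "seed": config.seed}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("stage=done out=%s", out)
    return {"config": config, "detections": det_table, "pairing": pairing,
            "alignments": alignments, "summary": summary, "truth": truth,
            "out_dir": str(out)}


def make_report(run_dir: str | Path, fig_dir: str | Path | None = None) -> dict:
    """Build summary figures from a completed run's CSV/JSON outputs.

    All numbers are re-read from the serialized outputs (plots are views,
    never sources).  Returns {section: figure path or 'empty'}.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    fig_dir = Path(fig_dir) if fig_dir else run_dir / "figures"
    if not (run_dir / "summary.json").exists():
        raise FileNotFoundError(f"{run_dir} has no summary.json; run the pipeline first")
    fig_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, str] = {}

    det = pd.read_csv(run_dir / "detections.csv") \
        if (run_dir / "detections.csv").exists() else pd.DataFrame()
    hist = json.loads((run_dir / "histograms.json").read_text()) \
        if (run_dir / "histograms.json").exists() else {}

    # average line profiles with SEM band
    prof_path = run_dir / "profiles.csv"
    prof = pd.read_csv(prof_path) if prof_path.exists() else pd.DataFrame()
    if len(prof):
        fig, ax = plt.subplots(figsize=(4, 3))
        for role, color in (("pre", "tab:green"), ("post", "tab:purple")):
            sub = prof[prof.channel == role]
            if not len(sub):
                continue
            g = sub.groupby("distance_nm").norm_intensity
            mean, sem = g.mean(), g.sem().fillna(0.0)
            peak = mean.max()
            mean, sem = mean / peak, sem / peak
            n = sub.ring_id.nunique()
            ax.plot(mean.index, mean.values, color=color, label=f"{role} (n={n})")
            ax.fill_between(mean.index, mean - sem, mean + sem, color=color,
                            alpha=0.3, lw=0)
        ax.set_xlabel("distance to ring center (nm)")
        ax.set_ylabel("norm. intensity")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        p = fig_dir / "average_profiles.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        report["average_profiles"] = str(p)
    else:
        report["average_profiles"] = "empty"

    # diameter distributions
    if len(det) and det.diameter_nm.notna().any():
        fig, ax = plt.subplots(figsize=(4, 3))
        for role, color in (("pre", "tab:green"), ("post", "tab:purple")):
            d = det[(det.channel == role)].diameter_nm.dropna()
            if len(d):
                ax.hist(d, bins=20, alpha=0.5, label=f"{role} (n={len(d)})",
                        color=color)
        ax.set_xlabel("interpeak diameter (nm)")
        ax.set_ylabel("rings")
        ax.legend(frameon=False)
        fig.tight_layout()
        p = fig_dir / "diameters.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        report["diameters"] = str(p)
    else:
        report["diameters"] = "empty"

    # cluster-count histograms with Gaussian fits
    has_counts = any(k.startswith("count_") for k in hist)
    if has_counts:
        fig, ax = plt.subplots(figsize=(4, 3))
        for role, color in (("pre", "tab:green"), ("post", "tab:purple")):
            h = hist.get(f"count_{role}")
            if not h:
                continue
            x = np.asarray(h["bin_centers"])
            ax.bar(x, h["density"], width=0.8, alpha=0.4, color=color,
                   label=f"{role} mean={h['raw_mean']:.2f}")
            if h["fit_mean"] is not None:
                xx = np.linspace(x.min() - 1, x.max() + 1, 200)
                amp = max(h["density"])
                ax.plot(xx, amp * np.exp(-(xx - h["fit_mean"])**2
                                         / (2 * h["fit_sd"]**2)), color=color)
        ax.set_xlabel("clusters / ring")
        ax.set_ylabel("fraction of rings")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        p = fig_dir / "cluster_counts.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        report["cluster_counts"] = str(p)
    else:
        report["cluster_counts"] = "empty"

    # NN-distance histogram
    if "nn_distance" in hist and hist["nn_distance"]["distances_nm"]:
        h = hist["nn_distance"]
        d = np.asarray(h["distances_nm"])
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(d, bins=np.arange(0, max(d.max(), 40) + 4, 4), density=True,
                alpha=0.6, color="tab:blue")
        ax.axvline(h["fit_mean"], color="k", ls="--",
                   label=f"Gaussian fit mean = {h['fit_mean']:.1f} nm")
        ax.set_xlabel("nearest-neighbor distance (nm)")
        ax.set_ylabel("density")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        p = fig_dir / "nn_distance.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        report["nn_distance"] = str(p)
    else:
        report["nn_distance"] = "empty"

    # alignment summary bar
    al_path = run_dir / "alignment.csv"
    al = pd.read_csv(al_path) if al_path.exists() else pd.DataFrame()
    if len(al) and al.aligned_fraction.notna().any():
        fig, ax = plt.subplots(figsize=(3, 3))
        frac = al.aligned_fraction.dropna()
        ax.bar([0], [100 * frac.mean()],
               yerr=[100 * frac.std(ddof=1) / np.sqrt(len(frac))] if len(frac) > 1 else None,
               color="tab:blue", width=0.5)
        ax.set_xticks([0])
        ax.set_xticklabels(["aligned"])
        ax.set_ylabel("aligned pre clusters (%)")
        ax.set_ylim(0, 100)
        fig.tight_layout()
        p = fig_dir / "alignment.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        report["alignment"] = str(p)
    else:
        report["alignment"] = "empty"

    (fig_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
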