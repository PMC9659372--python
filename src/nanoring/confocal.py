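"""Confocal-level punctum quantification and the homeostatic time-course.

At confocal resolution each synapse collapses to a single punctum.  Puncta
are segmented by thresholding (Otsu per image, or a fixed threshold for
cross-condition comparability) and connected components; per-punctum mean
intensity and area feed the treatment-vs-control relative-change readout
and distributional comparisons.  Magnitudes are only comparable between
groups acquired with identical settings, so ``relative_change`` refuses to
compare groups whose settings flags differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .io import ImageChannel


@dataclass
class PunctumRecord:
    """One segmented punctum."""

    punctum_id: int
    channel: str
    x_nm: float
    y_nm: float
    area_um2: float
    mean_intensity: float
    condition: str = ""
    settings: str = "default"

    def __post_init__(self) -> None:
        if not self.area_um2 > 0:
            raise ValueError("area_um2 must be positive")
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be non-negative")


def segment_puncta(
    image: ImageChannel,
    method: str = "otsu",
    min_area_um2: float = 0.05,
    fixed_threshold: float | None = None,
    condition: str = "",
    settings: str = "default",
) -> list[PunctumRecord]:
    """Segment puncta by threshold + connected components + area filter.

    ``method`` is ``"otsu"`` (per-image Otsu threshold) or ``"fixed"``
    (requires ``fixed_threshold`` in intensity units).  Blank images yield
    an empty list.
    """
    data = np.asarray(image.data, float)
    if method == "otsu":
        if np.ptp(data) == 0:
            return []
        thr = threshold_otsu(data)
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    lab = label(data > thr)
    px_um = image.pixel_size_nm / 1000.0
    min_px = min_area_um2 / (px_um**2)
    out: list[PunctumRecord] = []
    for rp in regionprops(lab, intensity_image=data):
        if rp.area < min_px:
            continue
        cy, cx = rp.centroid
        out.append(PunctumRecord(
            punctum_id=len(out), channel=image.channel,
            x_nm=(cx + 0.5) * image.pixel_size_nm,
            y_nm=(cy + 0.5) * image.pixel_size_nm,
            area_um2=rp.area * px_um**2,
            mean_intensity=float(rp.intensity_mean),
            condition=condition, settings=settings,
        ))
    return out


@dataclass
class RelativeChange:
    percent_change: float        # 100 * (treated/control - 1)
    normalized_to_control: float  # 100 * treated/control
    n_treated: int
    n_control: int


def relative_change(treated: list[PunctumRecord],
                    control: list[PunctumRecord]) -> RelativeChange:
    """Percent change of mean punctum intensity, treated vs control.

    Both groups must be non-empty, from the same channel, and acquired with
    the same settings flag (magnitudes are not comparable otherwise).
    """
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    for attr in ("channel", "settings"):
        vals = {getattr(p, attr) for p in treated} | {getattr(p, attr) for p in control}
        if len(vals) > 1:
            raise ValueError(f"groups mix different {attr} values: {sorted(vals)}")
    mt = float(np.mean([p.mean_intensity for p in treated]))
    mc = float(np.mean([p.mean_intensity for p in control]))
    if mc <= 0:
        raise ValueError("control group has non-positive mean intensity")
    ratio = mt / mc
    return RelativeChange(percent_change=100.0 * (ratio - 1.0),
                          normalized_to_control=100.0 * ratio,
                          n_treated=len(treated), n_control=len(control))


def compare_distributions(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test; returns (statistic, p-value)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def cumulative_frequency(values) -> pd.DataFrame:
    """Empirical cumulative-frequency curve as a tidy DataFrame."""
    v = np.sort(np.asarray(values, float))
    return pd.DataFrame({"value": v,
                         "cumulative_frequency": np.arange(1, v.size + 1) / v.size})


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with Bonferroni adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    # mean rank per group
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        m = groups[g].size
        mean_rank[g] = ranks[start:start + m].mean()
        sizes[g] = m
        start += m
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    n_comp = len(labels) * (len(labels) - 1) // 2
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": g1, "group_b": g2, "test": "dunn", "statistic": z,
                     "p_value": p, "p_adjusted": min(1.0, p * n_comp)})
    return pd.DataFrame(rows)


def group_stats(groups: dict[str, "np.ndarray | list"],
                design: str = "multi_group",
                normal_path: bool | None = None,
                alpha_normal: float = 0.05) -> pd.DataFrame:
    """Hypothesis tests across condition groups.

    ``design='two_group'``: Mann–Whitney rank-sum (or t test on the normal
    path).  ``design='multi_group'``: Kruskal–Wallis omnibus followed by
    Dunn's pairwise comparisons with Bonferroni adjustment (or one-way
    ANOVA + Tukey HSD on the normal path).  Normality is screened per group
    with the D'Agostino–Pearson test unless ``normal_path`` is forced.

    Returns a tidy table with one row for the omnibus test (multi-group)
    plus one per pairwise contrast.
    """
    g = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    if any(v.size < 2 for v in g.values()):
        raise ValueError("singleton groups are not testable")
    if normal_path is None:
        normal_path = all(
            v.size >= 20 and stats.normaltest(v).pvalue > alpha_normal
            for v in g.values()
        )

    labels = list(g)
    if design == "two_group":
        if len(labels) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        a, b = g[labels[0]], g[labels[1]]
        if normal_path:
            s, p = stats.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
        else:
            s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann_whitney"
        return pd.DataFrame([{"group_a": labels[0], "group_b": labels[1],
                              "test": test, "statistic": float(s),
                              "p_value": float(p), "p_adjusted": float(p)}])
    if design != "multi_group":
        raise ValueError(f"unknown design {design!r}")

    if normal_path:
        s, p = stats.f_oneway(*g.values())
        if not np.isfinite(p):  # degenerate: zero between-group variance
            s, p = 0.0, 1.0
        omnibus = {"group_a": "all", "group_b": "all", "test": "anova",
                   "statistic": float(s), "p_value": float(p), "p_adjusted": float(p)}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = np.concatenate(list(g.values()))
        labs = np.concatenate([[k] * v.size for k, v in g.items()])
        tk = pairwise_tukeyhsd(vals, labs)
        rows = [omnibus]
        for row, stat, padj in zip(tk.summary().data[1:], tk.meandiffs, tk.pvalues):
            rows.append({"group_a": str(row[0]), "group_b": str(row[1]),
                         "test": "tukey", "statistic": float(stat),
                         "p_value": float(padj), "p_adjusted": float(padj)})
        return pd.DataFrame(rows)

    s, p = stats.kruskal(*g.values())
    omnibus = pd.DataFrame([{"group_a": "all", "group_b": "all",
                             "test": "kruskal_wallis", "statistic": float(s),
                             "p_value": float(p), "p_adjusted": float(p)}])
    return pd.concat([omnibus, _dunn_posthoc(g)], ignore_index=True)


def quantal_content(epsp_mean_mv: float, mepsp_mean_mv: float) -> float:
    """Quantal content: ratio of mean EPSP to mean mEPSP amplitude."""
    if not (epsp_mean_mv > 0 and mepsp_mean_mv > 0):
        raise ValueError("EPSP and mEPSP means must be positive")
    return epsp_mean_mv / mepsp_mean_mv
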