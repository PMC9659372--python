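"""Ring-centered radial line-profile analysis.

A line profile is the average, over evenly spaced orientations, of the
image intensity sampled along full diameter lines through a ring center,
expressed on a signed-distance grid (negative = one side, positive = the
other) and normalized to its own maximum.  The interpeak distance between
the two rim peaks is the ring's diameter readout; intensity at 0 nm
(center) and 300 nm (periphery) quantifies fluorescence inside and outside
the ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .io import ImageChannel


class GeometryError(ValueError):
    """Requested profile geometry does not fit inside the image."""


class UndefinedDiameterError(ValueError):
    """Diameter is undefined for a non-ring-like profile."""


@dataclass
class LineProfile:
    """Signed-distance intensity profile of one ring (or an average).

    ``distances_nm`` is a strictly increasing symmetric grid about 0;
    ``intensities`` is peak-normalized (max = 1).  ``sem`` is per-point
    standard error when the profile is an average of several rings.
    """

    distances_nm: np.ndarray
    intensities: np.ndarray
    n_angles: int = 0
    ring_id: int = -1
    channel: str = ""
    n_averaged: int = 1
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances_nm = np.asarray(self.distances_nm, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.distances_nm.shape != self.intensities.shape:
            raise ValueError("distance and intensity grids differ in length")
        d = self.distances_nm
        if not np.all(np.diff(d) > 0):
            raise ValueError("distance grid must be strictly increasing")
        if not np.allclose(d, -d[::-1], atol=1e-9):
            raise ValueError("distance grid must be symmetric about 0")

    @property
    def step_nm(self) -> float:
        return float(self.distances_nm[1] - self.distances_nm[0])

    def is_normalized(self, atol: float = 1e-6) -> bool:
        return abs(float(self.intensities.max()) - 1.0) <= atol


def extract_profile(
    image: ImageChannel,
    center_nm: tuple[float, float],
    max_r_nm: float = 300.0,
    n_angles: int = 36,
    ring_id: int = -1,
) -> LineProfile:
    """Extract the orientation-averaged, peak-normalized radial profile.

    For each of ``n_angles`` evenly spaced orientations in [0, pi), the
    intensity is sampled by bilinear interpolation along the full diameter
    line through ``center_nm``; orientation profiles are averaged and the
    result normalized to its own maximum.

    Raises
    ------
    GeometryError
        If the center is closer than ``max_r_nm`` to any image edge.
    """
    cx, cy = float(center_nm[0]), float(center_nm[1])
    if (cx < max_r_nm or cy < max_r_nm
            or cx > image.width_nm - max_r_nm or cy > image.height_nm - max_r_nm):
        raise GeometryError(
            f"center ({cx:.0f}, {cy:.0f}) nm closer than {max_r_nm:.0f} nm to an edge"
        )
    px = image.pixel_size_nm
    k = int(round(max_r_nm / px))
    dist = np.arange(-k, k + 1) * px
    thetas = np.arange(n_angles) * (np.pi / n_angles)
    ct, st = np.cos(thetas), np.sin(thetas)
    # sample all orientations at once: shape (n_angles, n_dist)
    xs = cx + dist[None, :] * ct[:, None]
    ys = cy + dist[None, :] * st[:, None]
    rows = ys / px - 0.5
    cols = xs / px - 0.5
    vals = map_coordinates(image.data, [rows.ravel(), cols.ravel()],
                           order=1, mode="nearest").reshape(n_angles, dist.size)
    mean = vals.mean(axis=0)
    peak = mean.max()
    if peak > 0:
        mean = mean / peak
    else:
        mean = np.ones_like(mean)
    return LineProfile(distances_nm=dist, intensities=mean, n_angles=n_angles,
                       ring_id=ring_id, channel=image.channel)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabola refinement of a discrete peak; returns (pos, value)."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a proper local max
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = x[1] - x[0]
    val = y1 - 0.25 * (y0 - y2) * delta
    return float(x[i] + delta * step), float(val)


def side_peaks(profile: LineProfile) -> tuple[tuple[float, float], tuple[float, float]]:
    """Refined (position, value) of the maximum on each signed side.

    Positions are in nm; the left peak position is negative.  d = 0 is
    excluded from both sides.
    """
    d, y = profile.distances_nm, profile.intensities
    zero = len(d) // 2
    il = int(np.argmax(y[:zero]))
    ir = zero + 1 + int(np.argmax(y[zero + 1:]))
    pl = _parabolic_refine(d, y, il)
    pr = _parabolic_refine(d, y, ir)
    return pl, pr


def interpeak_distance(profile: LineProfile) -> float:
    """Distance between the two refined rim-peak positions, in nm.

    Raises :class:`UndefinedDiameterError` for non-ring-like profiles.
    """
    from .rings import classify_profile  # local import to avoid cycle

    if classify_profile(profile) != "ring_like":
        raise UndefinedDiameterError("interpeak distance undefined for NRL profile")
    (pl, _), (pr, _) = side_peaks(profile)
    return float(pr - pl)


def intensity_at(profile: LineProfile, distance_nm: float) -> float:
    """Normalized intensity at ``|distance_nm|``: mean of the two signed sides.

    Linear interpolation between grid points; raises ValueError out of range.
    """
    d = abs(float(distance_nm))
    if d > profile.distances_nm[-1] + 1e-9:
        raise ValueError(
            f"distance {d:.1f} nm outside profile range "
            f"(max {profile.distances_nm[-1]:.1f} nm)"
        )
    lo = float(np.interp(-d, profile.distances_nm, profile.intensities))
    hi = float(np.interp(d, profile.distances_nm, profile.intensities))
    return 0.5 * (lo + hi)


def average_profiles(profiles: list[LineProfile]) -> LineProfile:
    """Pointwise mean profile with per-point SEM, renormalized to its peak."""
    if not profiles:
        raise ValueError("no profiles to average")
    d0 = profiles[0].distances_nm
    for p in profiles[1:]:
        if p.distances_nm.shape != d0.shape or not np.allclose(p.distances_nm, d0):
            raise ValueError("profiles have mismatched distance grids")
    stack = np.vstack([p.intensities for p in profiles])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    peak = mean.max()
    return LineProfile(distances_nm=d0.copy(), intensities=mean / peak,
                       sem=sem / peak, n_averaged=n,
                       channel=profiles[0].channel)


def cross_channel_offset(profile_a: LineProfile, profile_b: LineProfile) -> float:
    """Difference of mean absolute rim-peak position, b minus a, in nm.

    Positive values mean channel b peaks farther from the ring center.
    Both profiles must be ring-like and share one distance grid.
    """
    from .rings import classify_profile

    if profile_a.distances_nm.shape != profile_b.distances_nm.shape or \
            not np.allclose(profile_a.distances_nm, profile_b.distances_nm):
        raise ValueError("profiles have mismatched distance grids")
    for p, tag in ((profile_a, "a"), (profile_b, "b")):
        if classify_profile(p) != "ring_like":
            raise UndefinedDiameterError(f"profile {tag} is not ring-like")

    def mean_abs_peak(p: LineProfile) -> float:
        (pl, _), (pr, _) = side_peaks(p)
        return 0.5 * (abs(pl) + abs(pr))

    return mean_abs_peak(profile_b) - mean_abs_peak(profile_a)
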