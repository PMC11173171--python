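"""Spatial firing analysis: rate maps, autocorrelograms, grid score,
field detection, and distribution comparisons.

The grid score follows the standard rotational-correlation definition:
an annulus of the spatial autocorrelogram (excluding the central peak)
is correlated with itself rotated by 30/60/90/120/150 degrees and

    score = min(corr60, corr120) - max(corr30, corr90, corr150).

A score above 0.2 is treated as an acceptable grid pattern.  Because
the exact annulus choice varies between laboratories, the outer radius
is swept and the best score reported (robust variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .drive import Trajectory

__all__ = [
    "RateMap",
    "GridMetrics",
    "rate_map",
    "autocorrelogram",
    "grid_score",
    "detect_fields",
    "grid_metrics",
    "compare_metric_distributions",
    "sheet_snapshot",
]


@dataclass
class RateMap:
    """Binned, smoothed spatial firing-rate map.

    ``rate`` is spikes/s with NaN in unvisited bins; ``occupancy`` is
    raw seconds per bin.  Row index = y bin, column index = x bin.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    bin_cm: float
    smooth_cm: float
    arena: tuple[float, float]

    @property
    def visited(self) -> np.ndarray:
        return ~np.isnan(self.rate)

    @property
    def mean_rate(self) -> float:
        v = self.rate[self.visited]
        return float(v.mean()) if v.size else 0.0

    @property
    def peak_rate(self) -> float:
        v = self.rate[self.visited]
        return float(v.max()) if v.size else 0.0


@dataclass
class GridMetrics:
    """Per-cell grid summary: score, rates, field geometry."""

    grid_score: float
    mean_rate: float
    peak_rate: float
    field_sizes_cm: list = field(default_factory=list)
    spacing_cm: float = np.nan
    orientation_deg: float = np.nan

    @property
    def mean_field_size_cm(self) -> float:
        return float(np.mean(self.field_sizes_cm)) if self.field_sizes_cm else np.nan


def rate_map(
    spike_times_ms: np.ndarray,
    traj: Trajectory,
    bin_cm: float = 3.0,
    smooth_cm: float = 3.0,
    occupancy_threshold_s: float = 0.1,
) -> RateMap:
    """Occupancy-normalized firing-rate map.

    Spike and occupancy histograms are binned at ``bin_cm``, separately
    Gaussian-smoothed with ``smooth_cm``, and divided; bins whose raw
    occupancy is below ``occupancy_threshold_s`` are flagged unvisited
    (NaN) and excluded from statistics.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    w, h = traj.arena
    nx = max(1, int(round(w / bin_cm)))
    ny = max(1, int(round(h / bin_cm)))
    edges_x = np.linspace(0, w, nx + 1)
    edges_y = np.linspace(0, h, ny + 1)

    occ, _, _ = np.histogram2d(traj.y, traj.x, bins=[edges_y, edges_x])
    occ = occ * traj.dt

    t_s = np.asarray(spike_times_ms, dtype=float) / 1000.0
    sx = np.interp(t_s, traj.t, traj.x)
    sy = np.interp(t_s, traj.t, traj.y)
    cnt, _, _ = np.histogram2d(sy, sx, bins=[edges_y, edges_x])

    sigma = smooth_cm / bin_cm
    if sigma > 0:
        occ_s = ndimage.gaussian_filter(occ, sigma)
        cnt_s = ndimage.gaussian_filter(cnt, sigma)
    else:
        occ_s, cnt_s = occ, cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = cnt_s / occ_s
    rate[occ < occupancy_threshold_s] = np.nan
    rate[~np.isfinite(rate)] = np.nan
    return RateMap(rate, occ, bin_cm, smooth_cm, traj.arena)


def autocorrelogram(map_or_array: RateMap | np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Spatial autocorrelogram: Pearson correlation of the map with
    itself at every 2-D lag, over overlapping visited bins.

    Output shape is ``(2*ny - 1, 2*nx - 1)`` with zero lag at the
    center.  Lags with fewer than ``min_overlap`` valid bins, or zero
    variance, are set to 0 by convention.
    """
    m = map_or_array.rate if isinstance(map_or_array, RateMap) else np.asarray(map_or_array, float)
    ny, nx = m.shape
    valid = np.isfinite(m)
    out = np.zeros((2 * ny - 1, 2 * nx - 1))
    for dy in range(-(ny - 1), ny):
        for dx in range(-(nx - 1), nx):
            a = m[max(0, dy):ny + min(0, dy), max(0, dx):nx + min(0, dx)]
            b = m[max(0, -dy):ny + min(0, -dy), max(0, -dx):nx + min(0, -dx)]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_overlap:
                continue
            av, bv = a[ok], b[ok]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                continue
            out[dy + ny - 1, dx + nx - 1] = ((av - av.mean()) * (bv - bv.mean())).mean() / (sa * sb)
    if valid.sum() >= min_overlap and np.nanstd(m[valid]) > 0:
        out[ny - 1, nx - 1] = 1.0
    return out


def _polar_annulus(acorr: np.ndarray, inner: float, outer: float, n_phi: int = 360) -> np.ndarray:
    """Bilinear polar resampling of the annulus ``inner <= r <= outer``.

    Rotations by multiples of ``360/n_phi`` degrees become exact
    circular shifts of the columns, so all comparison angles carry the
    same interpolation error.
    """
    cy, cx = (np.asarray(acorr.shape) - 1) / 2.0
    radii = np.arange(inner, outer + 0.5, 0.5)
    phis = np.arange(n_phi) * (2 * np.pi / n_phi)
    R, P = np.meshgrid(radii, phis, indexing="ij")
    ys = cy + R * np.sin(P)
    xs = cx + R * np.cos(P)
    return ndimage.map_coordinates(acorr, [ys, xs], order=1, mode="constant", cval=np.nan)


def _rotational_correlations(polar: np.ndarray, angles=(30, 60, 90, 120, 150)) -> dict:
    ok = np.isfinite(polar)
    out = {}
    for ang in angles:
        shift = int(round(ang / 360.0 * polar.shape[1]))
        rolled = np.roll(polar, shift, axis=1)
        m = ok & np.isfinite(rolled)
        if m.sum() < 20:
            out[ang] = np.nan
            continue
        a, b = polar[m], rolled[m]
        if a.std() == 0 or b.std() == 0:
            out[ang] = 0.0
            continue
        out[ang] = float(np.corrcoef(a, b)[0, 1])
    return out


def _central_peak_radius(acorr: np.ndarray, level: float = 0.2) -> float:
    """Radius (bins) where the central peak first falls below ``level``."""
    cy, cx = (np.asarray(acorr.shape) - 1) / 2.0
    max_r = int(min(cy, cx))
    for r in range(1, max_r):
        yy, xx = np.indices(acorr.shape)
        ring = (np.hypot(yy - cy, xx - cx) >= r - 0.5) & (np.hypot(yy - cy, xx - cx) < r + 0.5)
        if acorr[ring].max() < level:
            return float(r)
    return float(max(1, max_r // 4))


def grid_score(acorr: np.ndarray) -> float:
    """Rotational-symmetry grid score of a spatial autocorrelogram.

    The annulus inner radius starts just outside the central peak; the
    outer radius is swept up to the largest circle contained in the
    autocorrelogram and the maximum score over the sweep is returned.
    Range is [-2, 2]; > 0.2 indicates an acceptable grid.
    """
    acorr = np.asarray(acorr, dtype=float)
    cy, cx = (np.asarray(acorr.shape) - 1) / 2.0
    max_r = float(min(cy, cx))
    inner0 = _central_peak_radius(acorr)
    best = -2.0
    found = False
    for outer in np.linspace(min(inner0 + 3, max_r), max_r, 8):
        for inner in (inner0, inner0 + 1):
            if outer <= inner + 2:
                continue
            corrs = _rotational_correlations(_polar_annulus(acorr, inner, outer))
            if any(np.isnan(v) for v in corrs.values()):
                continue
            score = min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
            best = max(best, score)
            found = True
    return best if found else 0.0


def detect_fields(
    rmap: RateMap,
    threshold_frac: float = 0.2,
    min_bins: int = 9,
) -> list[dict]:
    """Firing fields as connected components above a fraction of the
    map peak.

    Each field dict has ``center_cm`` (x, y), ``area_cm2``, and
    ``size_cm`` — the diameter of the circle of equal area.
    """
    rate = np.where(rmap.visited, rmap.rate, 0.0)
    peak = rate.max()
    if peak <= 0:
        return []
    lab, nlab = ndimage.label(rate > threshold_frac * peak)
    fields = []
    for li in range(1, nlab + 1):
        mask = lab == li
        area_bins = int(mask.sum())
        if area_bins < min_bins:
            continue
        cy, cx = ndimage.center_of_mass(rate * mask)
        area_cm2 = area_bins * rmap.bin_cm ** 2
        fields.append({
            "center_cm": ((cx + 0.5) * rmap.bin_cm, (cy + 0.5) * rmap.bin_cm),
            "area_cm2": area_cm2,
            "size_cm": 2.0 * np.sqrt(area_cm2 / np.pi),
            "peak_rate": float(rate[mask].max()),
        })
    return fields


def field_spacing(fields: list[dict], arena: tuple[float, float]) -> float:
    """Median distance from the most central field to its nearest
    neighbours (those within 1.5x the closest neighbour distance)."""
    if len(fields) < 2:
        return np.nan
    centers = np.array([f["center_cm"] for f in fields])
    mid = np.array(arena) / 2.0
    ci = int(np.argmin(np.linalg.norm(centers - mid, axis=1)))
    d = np.linalg.norm(centers - centers[ci], axis=1)
    d = np.sort(d[d > 0])
    near = d[d <= 1.5 * d[0]]
    return float(np.median(near))


def spacing_from_autocorr(acorr: np.ndarray, bin_cm: float) -> float:
    """Grid spacing (cm) as the median distance of the inner
    autocorrelogram peaks from the center."""
    peaks = _inner_peaks(acorr)
    if not peaks:
        return np.nan
    cy, cx = (np.asarray(acorr.shape) - 1) / 2.0
    d = [np.hypot(py - cy, px - cx) for py, px in peaks]
    return float(np.median(d) * bin_cm)


def grid_orientation(acorr: np.ndarray, bin_cm: float = 1.0) -> float:
    """Orientation (deg, mod 60) of the six inner autocorrelogram peaks."""
    peaks = _inner_peaks(acorr)
    if not peaks:
        return np.nan
    cy, cx = (np.asarray(acorr.shape) - 1) / 2.0
    angles = [np.degrees(np.arctan2(py - cy, px - cx)) % 60.0 for py, px in peaks]
    return float(min(angles))


def _inner_peaks(acorr: np.ndarray, n_peaks: int = 6) -> list[tuple[float, float]]:
    """The six local maxima nearest the center (excluding it)."""
    cy, cx = (np.asarray(acorr.shape) - 1) / 2.0
    mx = ndimage.maximum_filter(acorr, size=3)
    cand = np.argwhere((acorr == mx) & (acorr > 0.1))
    inner0 = _central_peak_radius(acorr)
    pts = []
    for py, px in cand:
        r = np.hypot(py - cy, px - cx)
        if r > inner0:
            pts.append((r, py, px))
    pts.sort()
    return [(py, px) for _, py, px in pts[:n_peaks]]


def grid_metrics(
    spike_times_ms: np.ndarray,
    traj: Trajectory,
    bin_cm: float = 3.0,
    smooth_cm: float = 3.0,
    min_field_bins: int = 9,
) -> GridMetrics:
    """Full per-cell metric pipeline: rate map -> autocorrelogram ->
    grid score, field sizes, spacing, orientation."""
    rmap = rate_map(spike_times_ms, traj, bin_cm, smooth_cm)
    ac = autocorrelogram(rmap)
    fields = detect_fields(rmap, min_bins=min_field_bins)
    spacing = spacing_from_autocorr(ac, bin_cm)
    if np.isnan(spacing):
        spacing = field_spacing(fields, traj.arena)
    return GridMetrics(
        grid_score=grid_score(ac),
        mean_rate=rmap.mean_rate,
        peak_rate=rmap.peak_rate,
        field_sizes_cm=[f["size_cm"] for f in fields],
        spacing_cm=spacing,
        orientation_deg=grid_orientation(ac),
    )


def compare_metric_distributions(real_values, sim_values) -> dict:
    """Non-parametric two-sample comparison (Wilcoxon rank-sum).

    Returns the rank-sum statistic, two-sided p-value, and per-group
    medians and interquartile ranges.  Refuses fewer than 3 values per
    group.
    """
    real = np.asarray(real_values, dtype=float)
    sim = np.asarray(sim_values, dtype=float)
    if len(real) < 3 or len(sim) < 3:
        raise ValueError("need at least 3 values per group")
    if np.array_equal(np.sort(real), np.sort(sim)):
        stat, p = 0.0, 1.0
    else:
        method = "exact" if max(len(real), len(sim)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(real, sim, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)
    return {
        "statistic": stat,
        "p_value": p,
        "median_real": float(np.median(real)),
        "median_sim": float(np.median(sim)),
        "iqr_real": iqr(real),
        "iqr_sim": iqr(sim),
        "n_real": len(real),
        "n_sim": len(sim),
    }


def sheet_snapshot(spikes, pop: str, side: int, t0_ms: float, t1_ms: float) -> np.ndarray:
    """Spike counts per cell within a time window, arranged on the
    population's 2-D sheet (row-major)."""
    t, ids = spikes.population(pop)
    m = (t >= t0_ms) & (t < t1_ms)
    counts = np.bincount(ids[m], minlength=side * side)
    return counts[:side * side].reshape(side, side)
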