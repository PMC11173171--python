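"""Synthetic rate-map fixtures with known ground truth.

Ideal hexagonal, square-lattice and radially symmetric maps used to
validate the grid-metric pipeline: the hexagonal generator places
Gaussian bumps on a triangular lattice with a chosen spacing, field
width and orientation, so recovered spacing/size/orientation can be
compared against construction parameters.
"""

from __future__ import annotations

import numpy as np

from .spatial import RateMap

__all__ = ["hexagonal_rate_map", "square_rate_map", "concentric_ring_map", "lattice_map"]


def lattice_map(
    basis: np.ndarray,
    spacing: float,
    sigma: float,
    arena: tuple[float, float] = (100.0, 100.0),
    bin_cm: float = 3.0,
    peak_rate: float = 10.0,
    phase: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RateMap:
    """Gaussian bumps of width ``sigma`` on the lattice spanned by
    ``spacing * basis`` (basis rows are unit cell vectors)."""
    w, h = arena
    nx, ny = int(round(w / bin_cm)), int(round(h / bin_cm))
    x = (np.arange(nx) + 0.5) * bin_cm
    y = (np.arange(ny) + 0.5) * bin_cm
    X, Y = np.meshgrid(x, y)
    rate = np.zeros_like(X)
    if phase is None:
        phase = (w / 2.0, h / 2.0)
    v1, v2 = spacing * np.asarray(basis, dtype=float)
    reach = int(np.ceil(max(w, h) / spacing)) + 2
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            cx = phase[0] + i * v1[0] + j * v2[0]
            cy = phase[1] + i * v1[1] + j * v2[1]
            if -3 * sigma <= cx <= w + 3 * sigma and -3 * sigma <= cy <= h + 3 * sigma:
                rate += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma ** 2))
    rate *= peak_rate / max(rate.max(), 1e-12)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rate = np.clip(rate + noise_sd * peak_rate * rng.standard_normal(rate.shape), 0, None)
    occ = np.full_like(rate, 1.0)
    return RateMap(rate, occ, bin_cm, smooth_cm=0.0, arena=arena)


def hexagonal_rate_map(
    spacing: float = 44.0,
    sigma: float = 5.0,
    arena: tuple[float, float] = (100.0, 100.0),
    bin_cm: float = 3.0,
    orientation_deg: float = 0.0,
    **kw,
) -> RateMap:
    """Ideal hexagonal (triangular-lattice) grid map."""
    th = np.radians(orientation_deg)
    b1 = np.array([np.cos(th), np.sin(th)])
    b2 = np.array([np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)])
    return lattice_map(np.array([b1, b2]), spacing, sigma, arena, bin_cm, **kw)


def square_rate_map(
    spacing: float = 30.0,
    sigma: float = 5.0,
    arena: tuple[float, float] = (100.0, 100.0),
    bin_cm: float = 3.0,
    **kw,
) -> RateMap:
    """Square-lattice bump map (90-degree symmetry: negative grid score)."""
    return lattice_map(np.array([[1.0, 0.0], [0.0, 1.0]]), spacing, sigma, arena, bin_cm, **kw)


def concentric_ring_map(
    spacing: float = 20.0,
    sigma: float = 4.0,
    arena: tuple[float, float] = (100.0, 100.0),
    bin_cm: float = 3.0,
    peak_rate: float = 10.0,
    circular_window: bool = True,
) -> RateMap:
    """Radially symmetric ring map (rotation-invariant: score near 0).

    With ``circular_window`` the map is restricted to the inscribed
    disk; a square window superimposes a 4-fold boundary artifact on
    the autocorrelogram that is not a property of the firing pattern.
    """
    w, h = arena
    nx, ny = int(round(w / bin_cm)), int(round(h / bin_cm))
    x = (np.arange(nx) + 0.5) * bin_cm
    y = (np.arange(ny) + 0.5) * bin_cm
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X - w / 2, Y - h / 2)
    rate = peak_rate * np.exp(-((np.mod(r, spacing) - spacing / 2) ** 2) / (2 * sigma ** 2))
    if circular_window:
        rate[r > min(w, h) / 2.0] = np.nan
    occ = np.full_like(rate, 1.0)
    return RateMap(rate, occ, bin_cm, smooth_cm=0.0, arena=arena)
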