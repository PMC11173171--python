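"""Trajectories and external drive currents.

Velocity information reaches the grid-cell sheet through conjunctive
(speed x direction) cells and position information through place cells:

* conjunctive cell i with preferred direction theta_i receives
  ``I_i(t) = I_base + g_speed * s(t) * max(0, cos(theta(t) - theta_i))``
  where ``s`` is running speed (cm/s) and ``theta`` the movement
  heading; the baseline keeps conjunctive cells tonically active,
* place cell j with field center c_j receives a Gaussian drive
  ``I_j(t) = g_place * exp(-||p(t) - c_j||^2 / (2 sigma_p^2))``;
  field centers tile the arena on a lattice aligned 1-to-1 with the
  grid-cell sheet, which anchors the attractor phase to position.

Real tracking data can be loaded from plain (t, x, y) tables; a
synthetic forager generates open-field trajectories when no recording
is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "load_trajectory",
    "synth_trajectory",
    "conjunctive_drive",
    "place_drive",
    "place_field_centers",
]


@dataclass
class Trajectory:
    """Uniformly sampled 2-D position track.

    ``t`` in seconds, ``x``/``y`` in cm within ``arena = (width, height)``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: tuple[float, float]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling interval must be constant; resample first")
        w, h = self.arena
        eps = 1e-6
        if np.any(self.x < -eps) or np.any(self.x > w + eps) or np.any(self.y < -eps) or np.any(self.y > h + eps):
            raise ValueError("positions outside arena bounds")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) >= 2 else 0.0

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def speed(self) -> np.ndarray:
        """Running speed (cm/s) by central differences."""
        if len(self.t) < 2:
            return np.zeros(len(self.t))
        # uniform sampling: scalar spacing keeps zero displacement exact
        vx = np.gradient(self.x, self.dt)
        vy = np.gradient(self.y, self.dt)
        return np.hypot(vx, vy)

    def heading(self) -> np.ndarray:
        """Movement direction (rad) by central differences."""
        if len(self.t) < 2:
            return np.zeros(len(self.t))
        vx = np.gradient(self.x, self.dt)
        vy = np.gradient(self.y, self.dt)
        return np.arctan2(vy, vx)

    def resample(self, dt: float) -> "Trajectory":
        """Linear-interpolation resampling to a uniform step ``dt`` (s)."""
        t_new = np.arange(self.t[0], self.t[-1] + 0.5 * dt, dt)
        return Trajectory(
            t=t_new,
            x=np.interp(t_new, self.t, self.x),
            y=np.interp(t_new, self.t, self.y),
            arena=self.arena,
        )

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(path, sep="\t", index=False)


def load_trajectory(
    path: str | Path,
    arena: tuple[float, float] = (45.0, 45.0),
    dt: float | None = None,
) -> Trajectory:
    """Read a plain (t, x, y) tracking table (tab/comma separated, with
    or without a header row).

    Gaps (NaN positions) are linearly interpolated; more than 5% missing
    samples or non-monotonic timestamps raise an error.  If ``dt`` is
    given the track is resampled to that step.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not set("txy") <= set(c.lower() for c in df.columns):
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: expected at least 3 columns (t, x, y)")
        df.columns = ["t", "x", "y"] + [f"extra{i}" for i in range(df.shape[1] - 3)]
    df.columns = [c.lower() for c in df.columns]
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotonic timestamps")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    missing = np.isnan(xy).any(axis=1)
    if missing.mean() > 0.05:
        raise ValueError(f"{path}: {missing.mean():.0%} samples missing (>5%)")
    for col in range(2):
        bad = np.isnan(xy[:, col])
        if bad.any():
            xy[bad, col] = np.interp(t[bad], t[~bad], xy[~bad, col])
    traj = Trajectory(t=t, x=xy[:, 0], y=xy[:, 1], arena=arena)
    if dt is not None and len(t) >= 2:
        traj = traj.resample(dt)
    return traj


def synth_trajectory(
    duration: float,
    arena: tuple[float, float] = (45.0, 45.0),
    speed_mean: float = 12.0,
    speed_sd: float = 7.0,
    turn_sd: float = 2.2,
    dt: float = 0.02,
    seed: int = 0,
    max_speed: float = 90.0,
) -> Trajectory:
    """Synthetic open-field foraging track in a square arena.

    A smooth heading random walk (angular diffusion ``turn_sd`` rad/s^0.5)
    with a slowly varying Ornstein–Uhlenbeck speed around ``speed_mean``
    (cm/s), reflected at the walls.  Speeds are clipped at ``max_speed``;
    the defaults keep fewer than 2% of samples near that outlier regime,
    matching mouse foraging where very fast running (~90 cm/s) is rare.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    w, h = arena
    if min(w, h) < 10.0:
        raise ValueError(f"arena {arena} too small (min side 10 cm)")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = w / 2.0, h / 2.0
    theta = rng.uniform(0, 2 * np.pi)
    s = speed_mean
    tau_s = 1.0  # speed relaxation time (s)
    for i in range(1, n):
        theta += turn_sd * np.sqrt(dt) * rng.standard_normal()
        s += dt / tau_s * (speed_mean - s) + speed_sd * np.sqrt(2 * dt / tau_s) * rng.standard_normal()
        s_clipped = min(max(s, 0.0), max_speed)
        nx = x[i - 1] + s_clipped * np.cos(theta) * dt
        ny = y[i - 1] + s_clipped * np.sin(theta) * dt
        # reflective walls
        if nx < 0:
            nx = -nx
            theta = np.pi - theta
        elif nx > w:
            nx = 2 * w - nx
            theta = np.pi - theta
        if ny < 0:
            ny = -ny
            theta = -theta
        elif ny > h:
            ny = 2 * h - ny
            theta = -theta
        x[i], y[i] = min(max(nx, 0.0), w), min(max(ny, 0.0), h)
    return Trajectory(t=np.arange(n) * dt, x=x, y=y, arena=arena)


def conjunctive_drive(
    traj: Trajectory,
    preferred_angles: np.ndarray,
    I_base: float = 500.0,
    g_speed: float = 25.0,
) -> np.ndarray:
    """Injected current (pA) per conjunctive cell at each track sample.

    Shape ``(n_samples, n_cells)``.  Zero speed yields exactly
    ``I_base`` everywhere; otherwise direction tuning is a rectified
    cosine around each cell's preferred angle, scaled by speed.
    """
    s = traj.speed()[:, None]
    theta = traj.heading()[:, None]
    tuning = np.maximum(0.0, np.cos(theta - np.asarray(preferred_angles)[None, :]))
    I = I_base + g_speed * s * tuning
    return np.where(s > 0, I, I_base)


def place_field_centers(side: int, arena: tuple[float, float]) -> np.ndarray:
    """Place-field centers on a ``side x side`` lattice over the arena,
    index-aligned with the grid-cell sheet (row-major)."""
    w, h = arena
    idx = np.arange(side * side)
    r, c = idx // side, idx % side
    return np.column_stack(((c + 0.5) * w / side, (r + 0.5) * h / side))


def place_drive(
    traj: Trajectory,
    centers: np.ndarray,
    g_place: float = 300.0,
    sigma_p: float = 3.0,
) -> np.ndarray:
    """Injected current (pA) per place cell at each track sample.

    Gaussian field of width ``sigma_p`` cm around each center; the cell
    at the animal's position receives exactly ``g_place``.
    """
    p = np.column_stack((traj.x, traj.y))
    d2 = ((p[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=-1)
    return g_place * np.exp(-d2 / (2.0 * sigma_p ** 2))
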