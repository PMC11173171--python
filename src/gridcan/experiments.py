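"""Experiment orchestration: grid-scale presets, parameter-robustness
sweeps, and cohort comparisons against recorded cells.

The robustness sweep varies one or two Izhikevich (IM) parameters of
the stellate cells, or Tsodyks–Markram (TM) parameters of all three
glutamatergic stellate-to-interneuron connection classes at once, over
9-value grids; each grid point rebuilds the network, runs a shortened
simulation, and summarizes grid quality as the median grid score of
the designated (central 3x3) stellate cells.  Regions with scores above
the 0.2 acceptability threshold are masked, alongside the biologically
realistic parameter ranges supplied in the sweep specification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drive import Trajectory, synth_trajectory
from .engine import SimConfig, run_simulation
from .network import SCALE_PRESETS, ScalePreset, build_network
from .params import NEURON_PARAMS, SYNAPSE_PARAMS, NeuronParams, SynapseParams
from .spatial import GridMetrics, compare_metric_distributions, grid_metrics

__all__ = [
    "IM_SWEEP_PARAMS",
    "TM_SWEEP_PARAMS",
    "SweepSpec",
    "SweepResult",
    "default_grid",
    "designated_cells",
    "run_point",
    "run_sweep",
    "run_scale_preset",
    "cohort_comparison",
]

#: Sweepable stellate IM parameters (NeuronParams field per name).
IM_SWEEP_PARAMS = {
    "k": "k", "a": "a", "b": "b", "d": "d", "C": "C",
    "Vr": "Vr", "Vt": "Vt", "Vpeak": "Vpeak", "Vmin": "c",
}
#: Sweepable TM parameters of the stellate->IN classes.
TM_SWEEP_PARAMS = {"g": "g_fast", "tau_d": "tau_d_fast", "tau_u": "tau_u", "tau_x": "tau_x"}

STELLATE = "MEC LII Stellate"
SI_CLASSES = (
    "MEC LII Stellate to EC LII Axo-Axonic",
    "MEC LII Stellate to MEC LII Basket",
    "MEC LII Stellate to EC LII Basket Multipolar",
)


@dataclass
class SweepSpec:
    """One- or two-parameter robustness sweep specification.

    ``params`` holds one or two parameter names from
    :data:`IM_SWEEP_PARAMS` / :data:`TM_SWEEP_PARAMS`; ``grids`` maps
    each name to its (usually 9-value) grid, which must contain the
    default value; ``bio_ranges`` maps each name to the biologically
    realistic (lo, hi) interval shown alongside the score threshold.
    """

    params: list[str]
    grids: dict[str, np.ndarray]
    bio_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    threshold: float = 0.2

    def __post_init__(self):
        if not 1 <= len(self.params) <= 2:
            raise ValueError("sweep over one or two parameters")
        for p in self.params:
            if p not in IM_SWEEP_PARAMS and p not in TM_SWEEP_PARAMS:
                raise ValueError(f"unknown sweep parameter {p!r}")
            g = np.asarray(self.grids[p], dtype=float)
            default = _default_value(p)
            if not np.any(np.isclose(g, default, rtol=0.051)):
                raise ValueError(f"grid for {p!r} must contain the default value {default}")
            self.grids[p] = g
        for p, (lo, hi) in self.bio_ranges.items():
            if not lo < hi:
                raise ValueError(f"bio range for {p!r} ill-ordered")


@dataclass
class SweepResult:
    spec: SweepSpec
    scores: np.ndarray          # (n1,) or (n1, n2) median grid score
    above_threshold: np.ndarray
    bio_mask: np.ndarray
    intersection: np.ndarray
    failed: np.ndarray


def _default_value(param: str) -> float:
    if param in IM_SWEEP_PARAMS:
        return getattr(NEURON_PARAMS[STELLATE], IM_SWEEP_PARAMS[param])
    return getattr(SYNAPSE_PARAMS[SI_CLASSES[0]], TM_SWEEP_PARAMS[param])


def default_grid(param: str, n: int = 9, span: float = 2.0) -> np.ndarray:
    """A geometric-ish grid of ``n`` values bracketing the default.

    Spans ``default/span`` to ``default*span`` for positive parameters;
    for signed voltage-like parameters an additive span of ±25% of the
    magnitude (min 5 mV) is used.  The default value is always on the
    grid (center point, n odd).
    """
    v0 = _default_value(param)
    if v0 > 0 and param not in ("Vr", "Vt", "Vpeak", "Vmin", "c"):
        lo, hi = v0 / span, v0 * span
        grid = np.geomspace(lo, hi, n)
    else:
        delta = max(abs(v0) * 0.25, 5.0)
        grid = np.linspace(v0 - delta, v0 + delta, n)
    grid[n // 2] = v0
    return grid


def designated_cells(side: int) -> list[int]:
    """The central 3x3 block of the grid-cell sheet (row-major ids)."""
    c = side // 2
    return [r * side + col for r in (c - 1, c, c + 1) for col in (c - 1, c, c + 1)]


def _build_with_overrides(
    overrides: dict[str, float],
    scale: str | ScalePreset,
    seed: int,
    grid_side: int,
) -> "tuple":
    nparams = dict(NEURON_PARAMS)
    sparams = dict(SYNAPSE_PARAMS)
    for p, val in overrides.items():
        if p in IM_SWEEP_PARAMS:
            nparams[STELLATE] = nparams[STELLATE].replace(**{IM_SWEEP_PARAMS[p]: val})
        else:
            # TM sweeps vary all three stellate->IN classes at once
            for cls in SI_CLASSES:
                sparams[cls] = sparams[cls].replace(**{TM_SWEEP_PARAMS[p]: val})
    return build_network(scale, seed=seed, grid_side=grid_side,
                         neuron_params=nparams, synapse_params=sparams)


def run_point(
    overrides: dict[str, float],
    traj: Trajectory,
    seed: int = 0,
    scale: str | ScalePreset = "intermediate",
    grid_side: int = 20,
    cfg: SimConfig | None = None,
    bin_cm: float = 2.0,
) -> float:
    """Median grid score of the designated cells for one parameter point."""
    net = _build_with_overrides(overrides, scale, seed, grid_side)
    spikes, _ = run_simulation(net, traj, cfg or SimConfig(), seed=seed)
    trains = spikes.spike_trains(STELLATE)
    cells = designated_cells(grid_side)
    scores = [
        grid_metrics(trains[ci], traj, bin_cm=bin_cm, smooth_cm=bin_cm, min_field_bins=5).grid_score
        for ci in cells
    ]
    return float(np.median(scores))


def run_sweep(
    spec: SweepSpec,
    traj: Trajectory | None = None,
    seed: int = 0,
    scale: str | ScalePreset = "intermediate",
    grid_side: int = 20,
    duration_s: float = 120.0,
    cfg: SimConfig | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run the robustness sweep over the spec's parameter grid(s).

    Uses a shortened simulation per point (the sweep protocol trades
    run length for grid coverage).  A point whose simulation aborts is
    marked failed (NaN score), not fatal.
    """
    if traj is None:
        traj = synth_trajectory(duration_s, seed=seed + 101)
    names = spec.params
    grids = [spec.grids[p] for p in names]
    shape = tuple(len(g) for g in grids)
    scores = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    it = np.ndindex(*shape)
    for idx in it:
        overrides = {p: float(grids[k][idx[k]]) for k, p in enumerate(names)}
        try:
            scores[idx] = run_point(overrides, traj, seed=seed, scale=scale,
                                    grid_side=grid_side, cfg=cfg)
        except (FloatingPointError, ValueError):
            failed[idx] = True
        if progress:
            print(f"sweep {idx}: {overrides} -> {scores[idx]:+.2f}", flush=True)

    above = np.where(np.isnan(scores), False, scores > spec.threshold)
    bio = np.ones(shape, dtype=bool)
    for k, p in enumerate(names):
        if p in spec.bio_ranges:
            lo, hi = spec.bio_ranges[p]
            in_range = (grids[k] >= lo) & (grids[k] <= hi)
            bio &= np.expand_dims(in_range, axis=tuple(a for a in range(len(shape)) if a != k))
    return SweepResult(spec, scores, above, bio, above & bio, failed)


def run_scale_preset(
    preset: str | ScalePreset,
    traj: Trajectory | None = None,
    seed: int = 0,
    grid_side: int = 20,
    duration_s: float = 300.0,
    cfg: SimConfig | None = None,
    bin_cm: float = 2.0,
) -> pd.DataFrame:
    """Full simulate-and-analyze pipeline for one grid-scale preset.

    Returns per-designated-cell grid metrics as a DataFrame (columns:
    cell, grid_score, mean_rate, peak_rate, field_size_cm, spacing_cm,
    orientation_deg).
    """
    preset_obj = SCALE_PRESETS[preset] if isinstance(preset, str) else preset
    if traj is None:
        traj = synth_trajectory(duration_s, seed=seed + 101)
    net = build_network(preset_obj, seed=seed, grid_side=grid_side)
    if cfg is None:
        # keep total surround inhibition comparable across scales: the
        # per-scale out-degree (5/12/16) otherwise changes the summed
        # stellate->IN weight by ~3x between presets
        cfg = SimConfig()
        ratio = 12.0 / preset_obj.out_degree_mean
        for cls in SI_CLASSES:
            cfg.weight_scale[cls] = cfg.weight_scale.get(cls, 1.0) * ratio
    spikes, _ = run_simulation(net, traj, cfg, seed=seed)
    trains = spikes.spike_trains(STELLATE)
    rows = []
    for ci in designated_cells(grid_side):
        m = grid_metrics(trains[ci], traj, bin_cm=bin_cm, smooth_cm=bin_cm, min_field_bins=5)
        rows.append({
            "cell": ci,
            "grid_score": m.grid_score,
            "mean_rate": m.mean_rate,
            "peak_rate": m.peak_rate,
            "field_size_cm": m.mean_field_size_cm,
            "spacing_cm": m.spacing_cm,
            "orientation_deg": m.orientation_deg,
        })
    return pd.DataFrame(rows)


def cohort_comparison(
    real_metrics: pd.DataFrame,
    sim_metrics: pd.DataFrame,
    metrics: tuple[str, ...] = ("mean_rate", "field_size_cm", "spacing_cm"),
) -> pd.DataFrame:
    """Non-parametric comparison of per-cell metric distributions
    between a recorded and a simulated cohort.

    Both frames need one row per cell and the metric columns; returns
    medians, IQRs and the two-sided rank-sum p per metric.
    """
    missing = [m for m in metrics if m not in real_metrics or m not in sim_metrics]
    if missing:
        raise ValueError(f"metric columns missing from input: {missing}")
    rows = []
    for m in metrics:
        r = real_metrics[m].dropna().to_numpy()
        s = sim_metrics[m].dropna().to_numpy()
        res = compare_metric_distributions(r, s)
        res["metric"] = m
        rows.append(res)
    return pd.DataFrame(rows).set_index("metric")


def stratify_by_reference_mean(values, reference_mean: float) -> np.ndarray:
    """Split cells into 'low' (<= reference mean) and 'high' strata.

    Used to group cohort cells by scale or firing level relative to the
    recorded cohort's mean.
    """
    values = np.asarray(values, dtype=float)
    return np.where(values <= reference_mean, "low", "high")


def plot_sweep(result: SweepResult, path=None):
    """Render a sweep heatmap (bilinear display interpolation) with the
    threshold and biological-range contours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = result.spec
    fig, ax = plt.subplots(figsize=(5, 4))
    if result.scores.ndim == 1:
        g = spec.grids[spec.params[0]]
        ax.plot(g, result.scores, "o-")
        ax.axhline(spec.threshold, color="k", ls="--", lw=1)
        if spec.params[0] in spec.bio_ranges:
            ax.axvspan(*spec.bio_ranges[spec.params[0]], color="teal", alpha=0.15)
        ax.set_xlabel(spec.params[0])
        ax.set_ylabel("grid score")
    else:
        im = ax.imshow(result.scores.T, origin="lower", aspect="auto",
                       interpolation="bilinear", cmap="viridis")
        fig.colorbar(im, ax=ax, label="grid score")
        ax.contour(result.above_threshold.T.astype(float), levels=[0.5], colors="k")
        if result.bio_mask.any() and not result.bio_mask.all():
            ax.contour(result.bio_mask.T.astype(float), levels=[0.5], colors="teal")
        ax.set_xticks(range(len(spec.grids[spec.params[0]])))
        ax.set_xticklabels([f"{v:.3g}" for v in spec.grids[spec.params[0]]], rotation=45)
        ax.set_yticks(range(len(spec.grids[spec.params[1]])))
        ax.set_yticklabels([f"{v:.3g}" for v in spec.grids[spec.params[1]]])
        ax.set_xlabel(spec.params[0])
        ax.set_ylabel(spec.params[1])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
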