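"""Network construction: neural sheets and center-surround connectivity.

Populations are laid out on square 2-D sheets that all span the same
normalized toroidal coordinate space, so sheets of different sizes (the
40x40 grid-cell sheet, the smaller interneuron sheets) align spatially.
Distances are quoted in *grid-sheet units* (1 unit = 1/40 of the space
for the full-scale network).

The connectivity that makes the continuous attractor work is
center-surround (CS): each grid (stellate) cell excites interneurons
lying on an annulus whose center is displaced from the cell's own
position along its preferred direction, and each interneuron inhibits
grid cells on a tight annulus around itself, sparing the center.  The
composition yields displaced ring inhibition between grid cells — bumps
of activity are stable at ring centers and move when direction-tuned
drive favours one preferred direction.  Ring radius sets the bump
lattice spacing and is the knob behind the dorsoventral grid-scale
presets; the per-scale stellate-to-interneuron out-degrees follow the
dorsoventral connectivity trend (about 5 / 12 / 16 connections per grid
cell for large / intermediate / small scales).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    CONNECTION_COUNTS,
    IN_TYPES,
    LARGE_SCALE_IN_COUNT,
    NEURON_PARAMS,
    POPULATION_COUNTS,
    SYNAPSE_PARAMS,
    NeuronParams,
    SynapseParams,
)

__all__ = [
    "PopulationSpec",
    "ScalePreset",
    "SCALE_PRESETS",
    "ConnectionSet",
    "NetworkSpec",
    "sheet_side",
    "sheet_positions",
    "toroidal_delta",
    "toroidal_distance",
    "build_sheets",
    "assign_preferred_directions",
    "annulus_members",
    "build_cs_connectivity",
    "build_network",
    "connectivity_census",
]

#: Preferred-direction unit vectors in sheet coordinates.
DIRECTION_VECTORS = {
    "E": np.array([1.0, 0.0]),
    "N": np.array([0.0, 1.0]),
    "W": np.array([-1.0, 0.0]),
    "S": np.array([0.0, -1.0]),
}
DIRECTION_ANGLES = {"E": 0.0, "N": 0.5 * np.pi, "W": np.pi, "S": 1.5 * np.pi}

MAX_STELLATE_TO_IN_FRACTION = 0.259  # reported connectivity ceiling in mouse MEC


@dataclass
class PopulationSpec:
    name: str
    count: int
    sheet_dims: tuple[int, int]
    params: NeuronParams
    role: str  # grid | interneuron | conjunctive | place
    positions: np.ndarray = field(default=None, repr=False)  # (count, 2) normalized

    def __post_init__(self):
        rows, cols = self.sheet_dims
        if rows * cols < self.count:
            raise ValueError(
                f"{self.name}: sheet {rows}x{cols} holds {rows * cols} < {self.count} cells; "
                f"suggest {sheet_side(self.count)}x{sheet_side(self.count)}"
            )
        if self.positions is None:
            self.positions = sheet_positions(self.count, self.sheet_dims)


@dataclass(frozen=True)
class ScalePreset:
    """Dorsoventral grid-scale preset: CS ring geometry in grid-sheet
    units plus interneuron counts and target out-degrees.

    The ``*_width`` fields bound annulus *membership* (which cells may
    be connected); the ``*_sigma`` fields set the Gaussian weight
    falloff from the ring radius, so the dynamically effective kernel
    can be tighter than the connection footprint.
    """

    name: str
    ring_radius: float       # stellate->IN annulus radius (sheet units)
    ring_width: float        # annulus membership band, full width
    ring_sigma: float        # weight falloff from the ring radius
    offset: float            # preferred-direction displacement of ring centers
    back_radius: float       # IN->stellate annulus radius
    back_width: float        # membership band (wide: holds the ~142 targets)
    back_sigma: float        # weight falloff (narrow: local inhibition blob)
    in_count: int            # per interneuron type
    out_degree_mean: float   # stellate->IN connections per stellate, per IN type
    out_degree_sd: float
    back_degree_mean: float  # IN->stellate connections per interneuron
    back_degree_sd: float
    topology: str = "twisted"  # twisted | torus sheet boundary metric
    # Six-fold angular concentration of the outgoing ring (arc half-width
    # in degrees; 0 disables).  Pins the bump-lattice orientation to the
    # sheet axes so grid orientation is shared across cells and stable
    # over time, playing the role of the orientation-locking that larger
    # sheets get from boundary effects.
    hex_arc_deg: float = 0.0


#: Ring radii decrease dorsally (small scale) and grow ventrally (large);
#: out-degrees follow the opposite trend (5 / 12 / 16).
SCALE_PRESETS: dict[str, ScalePreset] = {
    "large": ScalePreset(
        name="large", ring_radius=12.0, ring_width=4.0, ring_sigma=1.5, offset=2.0,
        back_radius=2.0, back_width=13.0, back_sigma=0.75,
        in_count=LARGE_SCALE_IN_COUNT,
        out_degree_mean=5, out_degree_sd=2,
        back_degree_mean=142, back_degree_sd=66),
    "intermediate": ScalePreset(
        name="intermediate", ring_radius=8.0, ring_width=3.0, ring_sigma=1.0, offset=2.0,
        back_radius=2.0, back_width=13.0, back_sigma=0.75,
        in_count=834,
        out_degree_mean=12, out_degree_sd=2,
        back_degree_mean=142, back_degree_sd=66),
    "small": ScalePreset(
        name="small", ring_radius=5.5, ring_width=2.5, ring_sigma=1.0, offset=1.5,
        back_radius=1.5, back_width=13.0, back_sigma=0.6,
        in_count=834,
        out_degree_mean=16, out_degree_sd=2,
        back_degree_mean=142, back_degree_sd=66),
}


@dataclass
class ConnectionSet:
    """Explicit synapse lists grouped by connection class.

    ``classes`` maps a connection-class name to a dict with integer
    arrays ``pre`` and ``post`` (indices within the pre/post populations)
    and a float array ``weight``.  Weights are non-negative; the
    excitatory/inhibitory sign is carried by the synapse class.
    """

    classes: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, pre_pop: str, post_pop: str,
            pre: np.ndarray, post: np.ndarray, weight: np.ndarray) -> None:
        pre = np.asarray(pre, dtype=np.int64)
        post = np.asarray(post, dtype=np.int64)
        weight = np.asarray(weight, dtype=float)
        if np.any(weight < 0):
            raise ValueError(f"{name}: negative weights")
        if pre_pop == post_pop and np.any(pre == post):
            raise ValueError(f"{name}: self-connections are not allowed")
        self.classes[name] = {
            "pre_pop": pre_pop, "post_pop": post_pop,
            "pre": pre, "post": post, "weight": weight,
        }

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name, c in self.classes.items():
            frames.append(pd.DataFrame({
                "class": name, "pre": c["pre"], "post": c["post"], "weight": c["weight"],
            }))
        if not frames:
            return pd.DataFrame(columns=["class", "pre", "post", "weight"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class NetworkSpec:
    populations: dict[str, PopulationSpec]
    directions: np.ndarray  # per-stellate preferred direction labels
    connections: ConnectionSet
    scale: ScalePreset
    grid_side: int  # stellate sheet side length (sheet-unit scale)
    synapse_params: dict[str, SynapseParams] = field(default_factory=lambda: dict(SYNAPSE_PARAMS))


def sheet_side(count: int) -> int:
    """Side of the smallest square sheet holding ``count`` cells."""
    return int(math.ceil(math.sqrt(count)))


def sheet_positions(count: int, sheet_dims: tuple[int, int]) -> np.ndarray:
    """Normalized (x, y) centers of ``count`` slots on the sheet, row-major.

    When the sheet has more slots than cells, the unused slots are
    spread evenly across the sheet (not bunched at the end), so partial
    populations still cover the space uniformly.
    """
    rows, cols = sheet_dims
    total = rows * cols
    if count == total:
        idx = np.arange(count)
    else:
        idx = np.floor(np.arange(count) * total / count).astype(np.int64)
    r, c = idx // cols, idx % cols
    return np.column_stack(((c + 0.5) / cols, (r + 0.5) / rows))


def toroidal_delta(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Shortest displacement q - p on the unit torus, components in (-1/2, 1/2]."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - np.round(d)


def toroidal_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    d = toroidal_delta(p, q)
    return np.sqrt(np.sum(np.atleast_2d(d) ** 2, axis=-1)).squeeze()


def twisted_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Distance on the twisted torus: wrapping in y shifts x by half a
    sheet.  This boundary identification makes triangular (hexagonal)
    bump lattices commensurate with the sheet, which a square torus
    frustrates."""
    d = np.atleast_2d(np.asarray(q, dtype=float) - np.asarray(p, dtype=float))
    dx = d[..., 0]
    dy = d[..., 1]
    best = np.full(dx.shape, np.inf)
    for j in (-1.0, 0.0, 1.0):
        ddy = dy + j
        ddx = dx + 0.5 * j
        ddx = ddx - np.round(ddx)  # plain wrap in x
        best = np.minimum(best, ddx ** 2 + ddy ** 2)
    return np.sqrt(best).squeeze()


def build_sheets(
    counts: dict[str, int] | None = None,
    neuron_params: dict[str, NeuronParams] | None = None,
) -> dict[str, PopulationSpec]:
    """Arrange every population on its square sheet.

    The grid (stellate), conjunctive and place sheets share identical
    dimensions so the 1-to-1 conjunctive->grid and place->grid mappings
    are index-aligned; each interneuron type gets its own (smaller)
    sheet spanning the same normalized space.
    """
    counts = dict(POPULATION_COUNTS if counts is None else counts)
    nparams = NEURON_PARAMS if neuron_params is None else neuron_params
    n_grid = counts["MEC LII Stellate"]
    side = sheet_side(n_grid)
    if side * side != n_grid:
        raise ValueError(
            f"stellate count {n_grid} is not a square; use {side * side} "
            f"for a {side}x{side} sheet"
        )
    roles = {
        "MEC LII Stellate": "grid",
        "EC LI-II Multipolar Pyramidal": "conjunctive",
        "CA1 Pyramidal": "place",
        "EC LII Axo-Axonic": "interneuron",
        "MEC LII Basket": "interneuron",
        "EC LII Basket Multipolar": "interneuron",
    }
    pops = {}
    for name, count in counts.items():
        role = roles.get(name, "interneuron")
        if role in ("conjunctive", "place"):
            if count != n_grid:
                raise ValueError(f"{name} count {count} must match stellate count {n_grid} (1-to-1 mapping)")
            dims = (side, side)
        elif role == "grid":
            dims = (side, side)
        else:
            s = sheet_side(count)
            dims = (s, s)
        pops[name] = PopulationSpec(name, count, dims, nparams[name], role)
    return pops


def assign_preferred_directions(sheet_dims: tuple[int, int]) -> np.ndarray:
    """Preferred direction (N/S/E/W) per grid cell, tiled in 2x2 blocks.

    Every 2x2 block of the sheet contains all four directions, so each
    direction covers exactly a quarter of the sheet and the labels are
    locally interleaved.
    """
    rows, cols = sheet_dims
    pattern = np.array([["E", "N"], ["W", "S"]])
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return pattern[r % 2, c % 2].ravel()


def annulus_members(
    center: np.ndarray,
    positions: np.ndarray,
    radius: float,
    width: float,
    units_per_space: float,
    metric=toroidal_distance,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances (sheet units) of cells whose wrapped distance
    from ``center`` lies in the band ``[radius - width/2, radius + width/2]``.

    ``units_per_space`` converts normalized distance to sheet units (the
    grid-sheet side length); ``metric`` is the sheet boundary metric
    (plain or twisted torus).
    """
    d = np.atleast_1d(metric(center, positions)) * units_per_space
    idx = np.flatnonzero(np.abs(d - radius) <= 0.5 * width)
    return idx, d[idx]


def _cs_weights(distances: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Gaussian falloff from the ring radius; peak weight 1 on the ring."""
    return np.exp(-0.5 * ((distances - radius) / max(sigma, 1e-9)) ** 2)


def _sample_annulus_targets(
    rng: np.random.Generator,
    center: np.ndarray,
    positions: np.ndarray,
    radius: float,
    width: float,
    sigma: float,
    units: float,
    degree_mean: float,
    degree_sd: float,
    inner_min: float = 0.0,
    metric=toroidal_distance,
    hex_arc_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    idx, dist = annulus_members(center, positions, radius, width, units, metric=metric)
    if inner_min > 0.0 and idx.size:
        keep = dist >= inner_min
        idx, dist = idx[keep], dist[keep]
    if hex_arc_deg > 0.0 and idx.size:
        ang6 = 6.0 * np.arctan2(*toroidal_delta(center, positions[idx]).T[::-1])
        # keep cells within +-hex_arc_deg of the nearest multiple of 60 deg
        keep = np.abs((ang6 + np.pi) % (2 * np.pi) - np.pi) <= np.radians(6.0 * hex_arc_deg)
        if keep.any():
            idx, dist = idx[keep], dist[keep]
    if idx.size == 0:
        return idx, np.empty(0)
    k = int(round(rng.normal(degree_mean, degree_sd)))
    k = max(1, min(k, idx.size))
    # Stratified pick: candidates ordered by angle around the ring
    # center, every (n/k)-th taken from a random start.  This matches
    # the requested out-degree while keeping the sampled ring nearly
    # isotropic — unstructured random subsets leave frozen heterogeneity
    # that pins the attractor pattern to the sheet.
    ang = np.arctan2(*toroidal_delta(center, positions[idx]).T[::-1])
    order = np.argsort(ang)
    start = rng.random() * idx.size
    pick = order[(np.floor(start + np.arange(k) * idx.size / k) % idx.size).astype(int)]
    chosen = idx[pick]
    w = _cs_weights(dist[pick], radius, sigma)
    return chosen, w


def build_cs_connectivity(
    populations: dict[str, PopulationSpec],
    directions: np.ndarray,
    scale: ScalePreset,
    seed: int,
    sheet_scale: float = 1.0,
) -> ConnectionSet:
    """Build the full synapse list for one grid-scale preset.

    Ring geometry (radius, width, offset — given in full-scale 40x40
    sheet units) is multiplied by ``sheet_scale`` so reduced sheets keep
    the same geometry relative to sheet size.  Sampling order is
    row-major by presynaptic index, from a single seeded generator, so
    connection sets are reproducible.
    """
    rng = np.random.default_rng(seed)
    grid = populations["MEC LII Stellate"]
    side = grid.sheet_dims[1]
    units = float(side)  # sheet units per normalized space

    radius = scale.ring_radius * sheet_scale
    width = scale.ring_width * sheet_scale
    ring_sigma = scale.ring_sigma * sheet_scale
    offset = scale.offset * sheet_scale
    back_radius = scale.back_radius * sheet_scale
    back_width = scale.back_width * sheet_scale
    back_sigma = scale.back_sigma * sheet_scale
    if radius + width / 2.0 > units / 2.0:
        raise ValueError(
            f"annulus radius {radius}+{width / 2} exceeds half the sheet ({units / 2}): "
            "rings would overlap themselves across the torus"
        )

    metric = twisted_distance if scale.topology == "twisted" else toroidal_distance
    conns = ConnectionSet()
    n_grid = grid.count
    idx_grid = np.arange(n_grid)

    # 1-to-1 drive pathways, unitary weights.
    for cls, pre_pop in (
        ("EC LI-II Multipolar Pyramidal to MEC LII Stellate", "EC LI-II Multipolar Pyramidal"),
        ("CA1 Pyramidal to MEC LII Stellate", "CA1 Pyramidal"),
    ):
        conns.add(cls, pre_pop, "MEC LII Stellate", idx_grid, idx_grid, np.ones(n_grid))

    # Ring centers are displaced OPPOSITE to the preferred direction:
    # when movement drives e.g. east-preferring cells, their inhibitory
    # surround sits west of the bump, so the bump slides east.
    offsets_xy = np.stack([DIRECTION_VECTORS[d] for d in directions]) * (offset / units)
    ring_centers = np.mod(grid.positions - offsets_xy, 1.0)

    # Stellate -> interneurons: displaced annuli, out-degree ~ N(mean, sd).
    for in_type in IN_TYPES:
        if in_type not in populations:
            continue
        cls = f"MEC LII Stellate to {in_type}"
        in_pos = populations[in_type].positions
        pre_l, post_l, w_l = [], [], []
        for s in range(n_grid):
            tgt, w = _sample_annulus_targets(
                rng, ring_centers[s], in_pos, radius, width, ring_sigma, units,
                scale.out_degree_mean, scale.out_degree_sd, metric=metric,
                hex_arc_deg=scale.hex_arc_deg,
            )
            pre_l.append(np.full(tgt.size, s)); post_l.append(tgt); w_l.append(w)
        pre = np.concatenate(pre_l); post = np.concatenate(post_l); w = np.concatenate(w_l)
        frac = pre.size / (n_grid * populations[in_type].count)
        if frac > MAX_STELLATE_TO_IN_FRACTION:
            raise ValueError(f"{cls}: connectivity fraction {frac:.3f} exceeds the 25.9% ceiling")
        conns.add(cls, "MEC LII Stellate", in_type, pre, post, w)

    # Interneurons -> stellate: tight CS annulus around the IN itself
    # (center spared — bump centers escape inhibition, surrounds do not).
    for in_type in IN_TYPES:
        if in_type not in populations:
            continue
        cls = f"{in_type} to MEC LII Stellate"
        in_pos = populations[in_type].positions
        pre_l, post_l, w_l = [], [], []
        for i in range(populations[in_type].count):
            tgt, w = _sample_annulus_targets(
                rng, in_pos[i], grid.positions, back_radius, back_width, back_sigma, units,
                scale.back_degree_mean * sheet_scale ** 2,
                scale.back_degree_sd * sheet_scale ** 2,
                inner_min=0.5 * sheet_scale, metric=metric,
            )
            pre_l.append(np.full(tgt.size, i)); post_l.append(tgt); w_l.append(w)
        conns.add(cls, in_type, "MEC LII Stellate",
                  np.concatenate(pre_l), np.concatenate(post_l), np.concatenate(w_l))
    return conns


def build_network(
    scale: str | ScalePreset = "intermediate",
    seed: int = 0,
    grid_side: int | None = None,
    counts: dict[str, int] | None = None,
    neuron_params: dict[str, NeuronParams] | None = None,
    synapse_params: dict[str, SynapseParams] | None = None,
) -> NetworkSpec:
    """Assemble populations, preferred directions and connectivity.

    ``grid_side`` shrinks the whole network proportionally (e.g. 20 for
    a quarter-size desk-scale model); population counts and ring
    geometry scale with it.
    """
    preset = SCALE_PRESETS[scale] if isinstance(scale, str) else scale
    if counts is None:
        counts = dict(POPULATION_COUNTS)
        for t in IN_TYPES:
            counts[t] = preset.in_count
    full_side = sheet_side(counts["MEC LII Stellate"])
    if grid_side is None:
        grid_side = full_side
    sheet_scale = grid_side / full_side
    if sheet_scale != 1.0:
        ratio = (grid_side / full_side) ** 2
        counts = {k: max(4, int(round(v * ratio))) for k, v in counts.items()}
        counts["MEC LII Stellate"] = grid_side ** 2
        counts["EC LI-II Multipolar Pyramidal"] = grid_side ** 2
        counts["CA1 Pyramidal"] = grid_side ** 2
    pops = build_sheets(counts, neuron_params)
    dirs = assign_preferred_directions(pops["MEC LII Stellate"].sheet_dims)
    conns = build_cs_connectivity(pops, dirs, preset, seed, sheet_scale=sheet_scale)
    sp = dict(SYNAPSE_PARAMS) if synapse_params is None else dict(synapse_params)
    return NetworkSpec(pops, dirs, conns, preset, grid_side, sp)


def connectivity_census(conns: ConnectionSet, populations: dict[str, PopulationSpec] | None = None) -> pd.DataFrame:
    """Per-class out-degree / in-degree summary.

    Returns a DataFrame indexed by connection class with mean and SD of
    the presynaptic out-degree, mean in-degree, synapse count, and mean
    weight.  Degree statistics are over all cells of the pre/post
    population when ``populations`` is given (cells with zero
    connections included), otherwise over connected cells only.
    """
    rows = {}
    for name, c in conns.classes.items():
        if c["pre"].size == 0:
            rows[name] = dict(n_synapses=0, out_mean=0.0, out_sd=0.0,
                              in_mean=0.0, weight_mean=0.0)
            continue
        if populations is not None:
            n_pre = populations[c["pre_pop"]].count
            n_post = populations[c["post_pop"]].count
        else:
            n_pre = c["pre"].max() + 1
            n_post = c["post"].max() + 1
        out = np.bincount(c["pre"], minlength=n_pre)
        into = np.bincount(c["post"], minlength=n_post)
        rows[name] = dict(
            n_synapses=c["pre"].size,
            out_mean=float(out.mean()), out_sd=float(out.std()),
            in_mean=float(into.mean()),
            weight_mean=float(c["weight"].mean()),
        )
    return pd.DataFrame.from_dict(rows, orient="index")
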