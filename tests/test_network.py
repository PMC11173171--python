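"""Sheet construction, preferred directions and center-surround
connectivity, with brute-force geometric oracles."""

import dataclasses

import numpy as np
import pytest

from gridcan.network import (
    SCALE_PRESETS,
    PopulationSpec,
    annulus_members,
    assign_preferred_directions,
    build_cs_connectivity,
    build_network,
    build_sheets,
    connectivity_census,
    sheet_positions,
    sheet_side,
    toroidal_distance,
    twisted_distance,
)
from gridcan.params import NEURON_PARAMS


@pytest.fixture(scope="module")
def full_net():
    return build_network("intermediate", seed=1)


def test_sheet_packing_rule():
    assert sheet_side(1600) == 40
    assert sheet_side(834) == 29  # smallest square sheet with >= 834 slots
    assert sheet_side(1200) == 35
    pos = sheet_positions(834, (29, 29))
    assert pos.shape == (834, 2)
    assert np.all((pos >= 0) & (pos < 1))
    # unused slots spread out: y coverage reaches the last row region
    assert pos[:, 1].max() > 0.95


def test_build_sheets_dimensions_and_alignment():
    pops = build_sheets()
    assert pops["MEC LII Stellate"].sheet_dims == (40, 40)
    assert pops["EC LI-II Multipolar Pyramidal"].sheet_dims == (40, 40)
    assert pops["CA1 Pyramidal"].sheet_dims == (40, 40)
    np.testing.assert_array_equal(
        pops["MEC LII Stellate"].positions,
        pops["CA1 Pyramidal"].positions,
    )


def test_sheet_too_small_raises():
    with pytest.raises(ValueError, match="suggest"):
        PopulationSpec("x", 100, (9, 9), NEURON_PARAMS["MEC LII Stellate"], "grid")


def test_preferred_directions_tiling():
    dirs = assign_preferred_directions((40, 40))
    values, counts = np.unique(dirs, return_counts=True)
    assert set(values) == {"E", "N", "W", "S"}
    assert np.all(counts == 400)  # equal representation
    grid = dirs.reshape(40, 40)
    # every 2x2 block contains all four directions
    for r in range(0, 40, 2):
        for c in range(0, 40, 2):
            assert set(grid[r:r + 2, c:c + 2].ravel()) == {"E", "N", "W", "S"}
    # invariant under translation by (2, 2)
    np.testing.assert_array_equal(grid, np.roll(np.roll(grid, 2, 0), 2, 1))


def test_toroidal_distance_properties():
    rng = np.random.default_rng(0)
    p, q, r = rng.random((3, 2))
    assert toroidal_distance(p, q) == pytest.approx(toroidal_distance(q, p))
    assert toroidal_distance(p, r) <= toroidal_distance(p, q) + toroidal_distance(q, r) + 1e-12
    # max component of the wrapped displacement is half the sheet
    far = toroidal_distance(np.array([0.0, 0.0]), np.array([0.5, 0.5]))
    assert far == pytest.approx(np.sqrt(0.5))
    assert toroidal_distance(p, p) == 0.0


def test_twisted_distance_identifies_shifted_wrap():
    # wrapping in y carries a half-sheet shift in x
    a = np.array([0.25, 0.02])
    b = np.array([0.75, 0.98])  # via y-wrap: dy=-0.04, dx=0.5-0.5=0
    assert twisted_distance(a, b) == pytest.approx(np.hypot(0.0, 0.04))
    assert twisted_distance(a, b) <= toroidal_distance(a, b)


def test_annulus_membership_matches_brute_force():
    """10x10 toy sheet, radius 2, width 1: membership equals exhaustive
    enumeration of cells with toroidal distance in [1.5, 2.5]."""
    pos = sheet_positions(100, (10, 10))
    center = pos[0]
    idx, dist = annulus_members(center, pos, radius=2.0, width=1.0, units_per_space=10.0)
    brute = []
    for j in range(100):
        dx = min(abs(pos[j, 0] - center[0]), 1 - abs(pos[j, 0] - center[0])) * 10
        dy = min(abs(pos[j, 1] - center[1]), 1 - abs(pos[j, 1] - center[1])) * 10
        if 1.5 <= np.hypot(dx, dy) <= 2.5:
            brute.append(j)
    assert sorted(idx.tolist()) == brute
    assert np.all((dist >= 1.5) & (dist <= 2.5))


def test_census_out_degrees_match_connection_spec(full_net):
    census = connectivity_census(full_net.connections, full_net.populations)
    for in_type in ("EC LII Axo-Axonic", "MEC LII Basket", "EC LII Basket Multipolar"):
        row = census.loc[f"MEC LII Stellate to {in_type}"]
        assert row.out_mean == pytest.approx(12.0, abs=0.5)
        assert row.out_sd == pytest.approx(2.0, abs=0.5)
        back = census.loc[f"{in_type} to MEC LII Stellate"]
        assert back.out_mean == pytest.approx(142.0, abs=15.0)
    for cls in ("EC LI-II Multipolar Pyramidal to MEC LII Stellate",
                "CA1 Pyramidal to MEC LII Stellate"):
        assert census.loc[cls].out_mean == 1.0


def test_scale_presets_reproduce_dorsoventral_out_degree_trend():
    means = {}
    for name, expected in (("large", 5.0), ("intermediate", 12.0), ("small", 16.0)):
        net = build_network(name, seed=2)
        c = connectivity_census(net.connections, net.populations)
        means[name] = c.loc["MEC LII Stellate to EC LII Axo-Axonic", "out_mean"]
        assert means[name] == pytest.approx(expected, abs=1.0)
    assert means["large"] < means["intermediate"] < means["small"]


def test_large_scale_uses_more_interneurons():
    net = build_network("large", seed=0)
    assert net.populations["EC LII Axo-Axonic"].count == 1200


def test_connectivity_fraction_below_reported_ceiling(full_net):
    for in_type in ("EC LII Axo-Axonic", "MEC LII Basket", "EC LII Basket Multipolar"):
        c = full_net.connections.classes[f"MEC LII Stellate to {in_type}"]
        n_pairs = 1600 * full_net.populations[in_type].count
        assert c["pre"].size / n_pairs <= 0.259


def test_no_self_connections_and_nonnegative_weights(full_net):
    for name, c in full_net.connections.classes.items():
        assert np.all(c["weight"] >= 0)
        if c["pre_pop"] == c["post_pop"]:
            assert not np.any(c["pre"] == c["post"])


def test_connectivity_reproducible_from_seed():
    a = build_network("intermediate", seed=5, grid_side=10)
    b = build_network("intermediate", seed=5, grid_side=10)
    for name in a.connections.classes:
        np.testing.assert_array_equal(a.connections.classes[name]["post"],
                                      b.connections.classes[name]["post"])
        np.testing.assert_array_equal(a.connections.classes[name]["weight"],
                                      b.connections.classes[name]["weight"])


def test_oversized_annulus_raises():
    preset = dataclasses.replace(SCALE_PRESETS["intermediate"], ring_radius=25.0)
    pops = build_sheets()
    dirs = assign_preferred_directions((40, 40))
    with pytest.raises(ValueError, match="half the sheet"):
        build_cs_connectivity(pops, dirs, preset, seed=0)


def test_zero_offset_pattern_has_four_fold_symmetry():
    """With no preferred-direction offset, out-degree maps per direction
    label are statistically indistinguishable (the ring construction is
    isotropic)."""
    preset = dataclasses.replace(SCALE_PRESETS["intermediate"], offset=0.0)
    net = build_network(preset, seed=3, grid_side=20)
    c = net.connections.classes["MEC LII Stellate to EC LII Axo-Axonic"]
    out = np.bincount(c["pre"], minlength=400)
    means = {d: out[net.directions == d].mean() for d in "ENWS"}
    assert max(means.values()) - min(means.values()) < 1.0


def test_census_empty_connection_set():
    from gridcan.network import ConnectionSet
    df = connectivity_census(ConnectionSet())
    assert df.empty
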