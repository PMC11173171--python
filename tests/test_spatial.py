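"""Rate maps, autocorrelograms, grid score and field metrics validated
on synthetic fixtures with known ground truth."""

import itertools

import numpy as np
import pytest

from gridcan.drive import Trajectory
from gridcan.fixtures import concentric_ring_map, hexagonal_rate_map, square_rate_map
from gridcan.spatial import (
    RateMap,
    autocorrelogram,
    compare_metric_distributions,
    detect_fields,
    field_spacing,
    grid_orientation,
    grid_score,
    rate_map,
    spacing_from_autocorr,
)


def test_rate_map_hand_computed_bins():
    """2x2-bin toy: 4 s occupancy split equally, spikes 2/0/4/0 ->
    rates 2/0/4/0 spikes/s (no smoothing)."""
    dt = 0.1
    # 1 s in each quadrant of a 10x10 cm arena (bin 5 cm)
    xs, ys = [], []
    for cx, cy in ((2.5, 2.5), (7.5, 2.5), (2.5, 7.5), (7.5, 7.5)):
        xs += [cx] * 10
        ys += [cy] * 10
    traj = Trajectory(np.arange(40) * dt, np.array(xs), np.array(ys), (10.0, 10.0))
    # 2 spikes in quadrant (0,0), 4 in quadrant (0,1) [x high, y low]
    spikes_ms = np.array([100.0, 200.0, 1100.0, 1200.0, 1300.0, 1400.0])
    rm = rate_map(spikes_ms, traj, bin_cm=5.0, smooth_cm=0.0, occupancy_threshold_s=0.05)
    assert rm.rate[0, 0] == pytest.approx(2.0)
    assert rm.rate[0, 1] == pytest.approx(4.0)
    assert rm.rate[1, 0] == pytest.approx(0.0)
    assert rm.rate[1, 1] == pytest.approx(0.0)


def test_rate_map_no_spikes_and_empty_trajectory():
    n = 100
    traj = Trajectory(np.arange(n) * 0.02, np.full(n, 5.0), np.full(n, 5.0), (10.0, 10.0))
    rm = rate_map(np.array([]), traj, bin_cm=5.0)
    assert rm.mean_rate == 0.0
    with pytest.raises(ValueError, match="empty"):
        rate_map(np.array([]), Trajectory(np.array([]), np.array([]), np.array([]), (10.0, 10.0)))


def test_uniform_spiking_gives_flat_map():
    rng = np.random.default_rng(0)
    n = 30000
    traj = Trajectory(np.arange(n) * 0.02, rng.uniform(0, 45, n), rng.uniform(0, 45, n), (45.0, 45.0))
    r = 5.0  # Hz, position-independent; spikes snapped to sample times
    idx = rng.choice(n, int(r * n * 0.02), replace=False)
    spikes = np.sort(traj.t[idx] * 1000.0)
    rm = rate_map(spikes, traj, bin_cm=3.0, smooth_cm=3.0)
    v = rm.rate[rm.visited]
    assert np.median(v) == pytest.approx(r, rel=0.15)
    assert v.std() / v.mean() < 0.3


def test_autocorrelogram_zero_lag_and_constant_map():
    m = hexagonal_rate_map(spacing=40, sigma=5)
    ac = autocorrelogram(m)
    cy, cx = (np.asarray(ac.shape) - 1) // 2
    assert ac[cy, cx] == pytest.approx(1.0)
    const = RateMap(np.full((15, 15), 3.0), np.ones((15, 15)), 3.0, 0.0, (45.0, 45.0))
    ac0 = autocorrelogram(const)
    assert np.all(ac0 == 0.0)  # zero variance handled as 0 by convention


def test_hexagonal_fixture_six_peaks_at_sixty_degrees():
    m = hexagonal_rate_map(spacing=44, sigma=5)
    ac = autocorrelogram(m)
    from gridcan.spatial import _inner_peaks
    peaks = _inner_peaks(ac)
    assert len(peaks) == 6
    cy, cx = (np.asarray(ac.shape) - 1) / 2.0
    angles = np.sort([np.degrees(np.arctan2(py - cy, px - cx)) % 360 for py, px in peaks])
    gaps = np.diff(np.concatenate([angles, [angles[0] + 360]]))
    assert np.allclose(gaps, 60.0, atol=10.0)


def test_grid_score_signs_on_fixtures():
    hex_score = grid_score(autocorrelogram(hexagonal_rate_map(spacing=44, sigma=5)))
    ring_score = grid_score(autocorrelogram(concentric_ring_map()))
    square_score = grid_score(autocorrelogram(square_rate_map(spacing=30, sigma=5)))
    assert hex_score > 0.2
    assert abs(ring_score) < 0.1
    assert square_score < 0.0


def test_grid_score_invariant_under_rate_scaling():
    m = hexagonal_rate_map(spacing=40, sigma=5)
    s1 = grid_score(autocorrelogram(m))
    m.rate = m.rate * 7.3
    s2 = grid_score(autocorrelogram(m))
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_grid_score_decreases_with_noise():
    """Adding i.i.d. noise to a hexagonal map degrades the score
    monotonically in the trend (Spearman over noise levels)."""
    from scipy.stats import spearmanr
    levels = np.linspace(0.0, 1.2, 7)
    mean_scores = []
    for nl in levels:
        scores = [
            grid_score(autocorrelogram(hexagonal_rate_map(
                spacing=40, sigma=5, noise_sd=nl, seed=seed)))
            for seed in range(3)
        ]
        mean_scores.append(np.mean(scores))
    rho, _ = spearmanr(levels, mean_scores)
    assert rho < -0.8
    assert mean_scores[0] > 0.8 > mean_scores[-1]


def test_field_size_matches_analytic_level_set():
    """A single Gaussian bump thresholded at 0.2 peak has an equal-area
    diameter of 2 sigma sqrt(2 ln 5), recovered within one bin."""
    for sigma in (4.0, 6.0, 10.0):
        m = hexagonal_rate_map(spacing=90, sigma=sigma, arena=(60.0, 60.0), bin_cm=2.0)
        fields = detect_fields(m, threshold_frac=0.2, min_bins=4)
        assert len(fields) == 1
        expected = 2.0 * sigma * np.sqrt(2.0 * np.log(5.0))
        assert fields[0]["size_cm"] == pytest.approx(expected, abs=2.0)


def test_empty_map_has_no_fields():
    m = RateMap(np.zeros((15, 15)), np.ones((15, 15)), 3.0, 0.0, (45.0, 45.0))
    assert detect_fields(m) == []


@pytest.mark.parametrize("spacing", [20.0, 44.0, 60.0, 80.0])
def test_spacing_recovered_within_one_bin(spacing):
    arena = (max(100.0, 2.5 * spacing),) * 2
    m = hexagonal_rate_map(spacing=spacing, sigma=max(3.0, spacing * 0.12),
                           arena=arena, bin_cm=3.0)
    got = spacing_from_autocorr(autocorrelogram(m), 3.0)
    assert got == pytest.approx(spacing, abs=3.0)
    fields = detect_fields(m, min_bins=4)
    got_fields = field_spacing(fields, arena)
    assert got_fields == pytest.approx(spacing, abs=3.0)


@pytest.mark.parametrize("theta", [0.0, 12.0, 25.0, 47.0])
def test_orientation_tracks_fixture_rotation(theta):
    m = hexagonal_rate_map(spacing=40, sigma=5, orientation_deg=theta)
    got = grid_orientation(autocorrelogram(m))
    expected = theta % 60.0
    delta = min(abs(got - expected), 60.0 - abs(got - expected))
    assert delta <= 6.0


def test_ranksum_identical_samples():
    out = compare_metric_distributions([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
    assert out["p_value"] == 1.0
    assert out["median_real"] == out["median_sim"] == 2.5


def test_ranksum_exact_small_sample_vs_enumeration():
    """p for {1,2,3} vs {10,20,30} equals the exhaustive permutation
    value: only 1 of C(6,3)=20 assignments is as extreme per tail."""
    out = compare_metric_distributions([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
    # enumeration oracle
    pooled = [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in [1.0, 2.0, 3.0])
    sums = [sum(ranks[pooled[i]] for i in combo)
            for combo in itertools.combinations(range(6), 3)]
    lo = sum(1 for s in sums if s <= obs) / len(sums)
    hi = sum(1 for s in sums if s >= obs) / len(sums)
    p_exact = min(1.0, 2.0 * min(lo, hi))
    assert out["p_value"] == pytest.approx(p_exact, abs=1e-9)


def test_medians_and_iqr_echo_inputs():
    out = compare_metric_distributions([1, 2, 3, 4, 5], [10, 20, 30])
    assert out["median_real"] == 3.0
    assert out["iqr_real"] == 2.0
    assert out["n_real"] == 5


def test_ranksum_refuses_tiny_groups():
    with pytest.raises(ValueError, match="at least 3"):
        compare_metric_distributions([1, 2], [1, 2, 3])
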