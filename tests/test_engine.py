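"""Simulation engine: quiescence, analytic microcircuit oracle,
determinism, bump structure, interneuron lag, anchored tracking."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gridcan.drive import Trajectory, synth_trajectory
from gridcan.engine import SimConfig, run_simulation
from gridcan.network import (
    SCALE_PRESETS,
    ConnectionSet,
    NetworkSpec,
    PopulationSpec,
    build_network,
)
from gridcan.params import NEURON_PARAMS, SYNAPSE_PARAMS
from gridcan.spatial import sheet_snapshot
from gridcan.synapses import nmda_gate
from gridcan.temporal import population_rate

CONJ_CLS = "EC LI-II Multipolar Pyramidal to MEC LII Stellate"


def _microcircuit():
    """One conjunctive cell driving one stellate cell."""
    pops = {
        "MEC LII Stellate": PopulationSpec(
            "MEC LII Stellate", 1, (1, 1), NEURON_PARAMS["MEC LII Stellate"], "grid"),
        "EC LI-II Multipolar Pyramidal": PopulationSpec(
            "EC LI-II Multipolar Pyramidal", 1, (1, 1),
            NEURON_PARAMS["EC LI-II Multipolar Pyramidal"], "conjunctive"),
        "CA1 Pyramidal": PopulationSpec(
            "CA1 Pyramidal", 1, (1, 1), NEURON_PARAMS["CA1 Pyramidal"], "place"),
    }
    conns = ConnectionSet()
    conns.add(CONJ_CLS, "EC LI-II Multipolar Pyramidal", "MEC LII Stellate",
              np.array([0]), np.array([0]), np.array([1.0]))
    return NetworkSpec(pops, np.array(["E"]), conns, SCALE_PRESETS["intermediate"], 1)


def _still(duration_s):
    n = int(duration_s / 0.02)
    return Trajectory(np.arange(n) * 0.02, np.full(n, 22.5), np.full(n, 22.5), (45.0, 45.0))


def test_zero_drive_zero_weights_silent(small_network):
    cfg = SimConfig(settle_s=0.5, I_base=0.0, g_place=0.0, g_speed=0.0,
                    noise_pA=0.0, jitter_mv=0.0,
                    weight_scale={k: 0.0 for k in small_network.connections.classes})
    spikes, _ = run_simulation(small_network, _still(10.0), cfg, seed=0)
    assert spikes.times.size == 0


def test_epsp_matches_event_driven_subthreshold_oracle():
    """A presynaptic spike's EPSP in the stellate cell matches an
    independent continuous-time integration (event-driven analytic
    conductances + adaptive-step membrane ODE) within 2%."""
    net = _microcircuit()
    dt = 0.1
    cfg = SimConfig(dt=dt, settle_s=0.0, jitter_mv=0.0, drive_jitter=0.0, noise_pA=0.0,
                    I_base=120.0, g_speed=0.0, g_place=0.0,
                    weight_scale={CONJ_CLS: 1.0}, slow_scale={})
    spikes, mon = run_simulation(net, _still(1.0), cfg, seed=0,
                                 monitor_neurons={"MEC LII Stellate": [0]})
    t_pre, _ = spikes.population("EC LI-II Multipolar Pyramidal")
    assert t_pre.size >= 1
    t0 = t_pre[0] + cfg.delay_ms  # conductance onset at the stellate
    sp = SYNAPSE_PARAMS[CONJ_CLS]
    p = NEURON_PARAMS["MEC LII Stellate"]
    R = sp.U  # first pulse from rest

    def rhs(t, y):
        v, u = y
        if t < t0:
            g_f = g_s = 0.0
        else:
            g_f = sp.g_fast * R * np.exp(-(t - t0) / sp.tau_d_fast)
            g_s = sp.g_slow * R * np.exp(-(t - t0) / sp.tau_d_slow)
        I = g_f * (0.0 - v) + nmda_gate(v) * g_s * (0.0 - v)
        return [(p.k * (v - p.Vr) * (v - p.Vt) - u + I) / p.C,
                p.a * (p.b * (v - p.Vr) - u)]

    t_end = t_pre[1] if t_pre.size > 1 else t0 + 30.0
    sol = solve_ivp(rhs, (0.0, t_end), [p.Vr, 0.0], max_step=0.05, dense_output=True)
    tt = np.arange(dt, t_end, dt)
    v_oracle = sol.sol(tt)[0]
    v_sim = mon.v[:tt.size, 0]
    # compare first-EPSP peak amplitude and timing
    win = (tt >= t0) & (tt <= t0 + 15.0)
    amp_o = v_oracle[win].max() - p.Vr
    amp_s = v_sim[win].max() - p.Vr
    t_o = tt[win][np.argmax(v_oracle[win])] - t_pre[0]
    t_s = tt[win][np.argmax(v_sim[win])] - t_pre[0]
    assert amp_s == pytest.approx(amp_o, rel=0.02)
    assert t_s == pytest.approx(t_o, rel=0.02, abs=2 * dt)


def test_deterministic_given_seed(small_network, short_trajectory):
    cfg = SimConfig(settle_s=0.5)
    a, _ = run_simulation(small_network, short_trajectory, cfg, seed=9, duration_s=5.0)
    b, _ = run_simulation(small_network, short_trajectory, cfg, seed=9, duration_s=5.0)
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.neurons, b.neurons)
    c, _ = run_simulation(small_network, short_trajectory, cfg, seed=10, duration_s=5.0)
    assert (a.times.size != c.times.size) or (not np.array_equal(a.times, c.times))


def test_grid_population_snapshot_is_multi_bump(stationary_run):
    """400 ms of grid-layer spiking arranged on the sheet shows several
    discrete activity blobs (multi-bump attractor state)."""
    spikes, _ = stationary_run
    from scipy import ndimage
    snap = sheet_snapshot(spikes, "MEC LII Stellate", 20, 7000.0, 7400.0).astype(float)
    sm = ndimage.gaussian_filter(snap, 1.0, mode="wrap")
    lab, nblobs = ndimage.label(sm > 0.5 * sm.max())
    assert nblobs >= 3
    # blobs are localized: active area well below the full sheet
    assert np.mean(sm > 0.5 * sm.max()) < 0.5


def test_interneurons_lag_grid_cells(stationary_run):
    """IN population rate peaks within 10 ms AFTER the stellate rate
    (stellate firing recruits the rings)."""
    spikes, _ = stationary_run
    dur = spikes.duration_ms
    lags = []
    for in_type in ("EC LII Axo-Axonic", "MEC LII Basket", "EC LII Basket Multipolar"):
        _, r_st = population_rate(*_pop(spikes, "MEC LII Stellate"), dur, bin_ms=1.0)
        _, r_in = population_rate(*_pop(spikes, in_type), dur, bin_ms=1.0)
        r_st = r_st - r_st.mean()
        r_in = r_in - r_in.mean()
        max_lag = 20
        xc = [np.dot(r_st[: r_st.size - k], r_in[k:]) for k in range(max_lag + 1)]
        lags.append(int(np.argmax(xc)))
    assert all(0 < lag <= 10 for lag in lags)


def _pop(spikes, name):
    t, _ = spikes.population(name)
    return t, spikes.n_neurons(name)


def test_bump_tracks_anchored_position(small_network):
    """With place anchoring on, grid-layer activity is elevated at the
    sheet location corresponding to the animal's position (drift
    correction pins the pattern phase to position)."""
    traj = synth_trajectory(60.0, seed=5)
    spikes, _ = run_simulation(small_network, traj, SimConfig(), seed=2)
    side = 20
    acc = np.zeros((side, side))
    win = 100.0
    for k in range(int(spikes.duration_ms / win)):
        t0 = k * win
        snap = sheet_snapshot(spikes, "MEC LII Stellate", side, t0, t0 + win).astype(float)
        i = min(int(t0 / 1000.0 / traj.dt), len(traj.x) - 1)
        acc += np.roll(np.roll(snap, side // 2 - int(round(traj.y[i] * side / 45.0)), axis=0),
                       side // 2 - int(round(traj.x[i] * side / 45.0)), axis=1)
    center = acc[side // 2 - 1: side // 2 + 2, side // 2 - 1: side // 2 + 2].mean()
    assert center > 1.5 * acc.mean()


def test_sheet_lattice_scale_orders_with_ring_radius():
    """The free-running bump pattern's surround radius (trough of the
    toroidal sheet autocorrelation) grows from the small to the large
    grid-scale preset — the dorsoventral scale machinery at the sheet
    level."""
    from gridcan.engine import SimConfig as SC

    def tor_ac(z):
        z = z - z.mean()
        F = np.fft.fft2(z)
        ac = np.real(np.fft.ifft2(F * np.conj(F))) / z.size
        return np.fft.fftshift(ac) / max(z.var(), 1e-12)

    troughs = {}
    for preset, odeg in (("small", 16.0), ("intermediate", 12.0), ("large", 5.0)):
        net = build_network(preset, seed=1, grid_side=20)
        cfg = SC(g_place=0.0, g_speed=0.0)
        for cls in ("MEC LII Stellate to EC LII Axo-Axonic",
                    "MEC LII Stellate to MEC LII Basket",
                    "MEC LII Stellate to EC LII Basket Multipolar"):
            cfg.weight_scale[cls] *= 12.0 / odeg  # equalize total inhibition
        spikes, _ = run_simulation(net, _still(10.0), cfg, seed=3)
        acc = np.zeros((20, 20))
        for t0 in range(2000, 10000, 1000):
            acc += tor_ac(sheet_snapshot(spikes, "MEC LII Stellate", 20,
                                         float(t0), float(t0 + 1000)).astype(float))
        yy, xx = np.indices((20, 20))
        r = np.hypot(yy - 10, xx - 10)
        prof = np.array([acc[(r >= k - 0.5) & (r < k + 0.5)].mean() for k in range(1, 10)])
        troughs[preset] = int(np.argmin(prof)) + 1
    assert troughs["small"] < troughs["large"]
    assert troughs["small"] <= troughs["intermediate"] <= troughs["large"]


def test_membrane_blowup_aborts_with_diagnostic(small_network):
    # strong hyperpolarizing bias: the spike-cutoff rule cannot rescue a
    # negative divergence, so the engine must abort with diagnostics
    cfg = SimConfig(settle_s=0.1, I_bias_stellate=-1e7, noise_pA=0.0)
    with pytest.raises(FloatingPointError, match="blow-up"):
        run_simulation(small_network, _still(1.0), cfg, seed=0)


def test_monitor_trace_shapes_and_bounds(stationary_run):
    spikes, mon = stationary_run
    n_steps = int(round(spikes.duration_ms / spikes.dt))
    assert mon.v.shape == (n_steps, 1)
    assert mon.I.shape == (n_steps, 1, 4)
    vpeak = NEURON_PARAMS["MEC LII Stellate"].Vpeak
    assert np.all(mon.v <= vpeak + 1e-9)
    assert np.all(np.isfinite(mon.I))
    # GABA_A current component is hyperpolarizing (non-positive)
    assert np.all(mon.I[:, 0, 2] <= 1e-9)


def test_spike_times_sorted_within_bounds(stationary_run):
    spikes, _ = stationary_run
    assert np.all(spikes.times >= 0)
    assert np.all(spikes.times <= spikes.duration_ms)
    trains = spikes.spike_trains("MEC LII Stellate")
    assert len(trains) == 400
    for tr in trains[:50]:
        assert np.all(np.diff(tr) > 0)
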