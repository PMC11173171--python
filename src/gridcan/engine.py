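"""Time-stepped simulation of the full spiking network.

Per step the engine decays receptor conductances, delivers spikes that
occurred one axonal delay earlier (applying the TM release update per
synapse), sums conductance-based receptor currents per postsynaptic
cell, advances every neuron's IM state, and records spikes and any
monitored voltage/current traces.  The inner loop is a numba kernel
over flat arrays; runs are deterministic given seed and configuration.

Conductances are accumulated per connection class (each class has its
own decay constants and reversal potentials), and TM state is kept per
synapse with lazy exact-exponential relaxation, so inter-spike dynamics
do not depend on the integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .drive import Trajectory, conjunctive_drive, place_drive, place_field_centers
from .network import DIRECTION_ANGLES, IN_TYPES, NetworkSpec

__all__ = ["SimConfig", "SpikeData", "MonitorTrace", "run_simulation"]

POP_ORDER = (
    "MEC LII Stellate",
    "EC LI-II Multipolar Pyramidal",
    "CA1 Pyramidal",
    "EC LII Axo-Axonic",
    "MEC LII Basket",
    "EC LII Basket Multipolar",
)


def default_weight_scale() -> dict:
    """Population-scale conductance multipliers (Table values are
    per-synapse peaks; the printed conductances are adjusted for the
    scale of the simulation).  Calibrated so that conjunctive drive
    keeps stellates active, interneurons track stellate bumps, and the
    surround inhibition sculpts a multi-bump pattern."""
    return {
        "EC LI-II Multipolar Pyramidal to MEC LII Stellate": 8.0,
        "CA1 Pyramidal to MEC LII Stellate": 5.0,
        "MEC LII Stellate to EC LII Axo-Axonic": 8.0,
        "MEC LII Stellate to MEC LII Basket": 8.0,
        "MEC LII Stellate to EC LII Basket Multipolar": 8.0,
        "EC LII Axo-Axonic to MEC LII Stellate": 240.0,
        "MEC LII Basket to MEC LII Stellate": 240.0,
        "EC LII Basket Multipolar to MEC LII Stellate": 240.0,
    }


def default_slow_scale() -> dict:
    """GABA_B gain on the grid-cell layer is kept low: slow inhibition
    otherwise acts as global adaptation and quenches pattern formation."""
    return {
        "EC LII Axo-Axonic to MEC LII Stellate": 0.05,
        "MEC LII Basket to MEC LII Stellate": 0.05,
        "EC LII Basket Multipolar to MEC LII Stellate": 0.05,
    }


@dataclass
class SimConfig:
    """Engine and drive configuration.

    Times in ms unless suffixed ``_s``; currents in pA; conductance
    scales are dimensionless multipliers on the per-synapse peaks.
    """

    dt: float = 0.5
    delay_ms: float = 1.0
    settle_s: float = 2.0
    jitter_mv: float = 2.0            # init jitter on v to break symmetry
    traj_dt: float = 0.02             # drive sampling step (s)
    I_base: float = 500.0             # conjunctive tonic drive
    g_speed: float = 25.0             # conjunctive speed gain (pA per cm/s)
    g_place: float = 400.0            # peak place-cell drive
    sigma_p: float = 3.0              # place-field width (cm)
    I_bias_stellate: float = 0.0      # optional tonic stellate depolarization
    drive_jitter: float = 0.15        # static per-cell drive heterogeneity (fraction)
    noise_pA: float = 100.0           # per-step independent current noise, std (pA)
    weight_scale: dict = field(default_factory=default_weight_scale)
    slow_scale: dict = field(default_factory=default_slow_scale)
    chunk_s: float = 20.0


@dataclass
class SpikeData:
    """Spike raster: parallel arrays of spike time (ms) and global
    neuron id, plus the population layout."""

    times: np.ndarray
    neurons: np.ndarray
    pop_slices: dict[str, slice]
    dt: float
    duration_ms: float

    def population(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Spike times and population-local neuron ids for one type."""
        sl = self.pop_slices[name]
        m = (self.neurons >= sl.start) & (self.neurons < sl.stop)
        return self.times[m], self.neurons[m] - sl.start

    def n_neurons(self, name: str) -> int:
        sl = self.pop_slices[name]
        return sl.stop - sl.start

    def spike_trains(self, name: str) -> list[np.ndarray]:
        t, ids = self.population(name)
        n = self.n_neurons(name)
        order = np.lexsort((t, ids))
        t, ids = t[order], ids[order]
        bounds = np.searchsorted(ids, np.arange(n + 1))
        return [t[bounds[i]:bounds[i + 1]] for i in range(n)]

    def to_table(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"neuron_id": self.neurons, "time_ms": self.times}).to_csv(
            path, sep="\t", index=False)


@dataclass
class MonitorTrace:
    """Voltage and per-receptor-class current traces for selected neurons.

    ``I`` has shape (steps, n_monitored, 4) with components ordered
    AMPA, NMDA, GABA_A, GABA_B.
    """

    neuron_ids: np.ndarray
    v: np.ndarray
    I: np.ndarray
    dt: float


@njit(cache=True)
def _step_kernel(
    n_steps, dt, record_from_ms,
    C, k, Vr, Vt, a, b, Vpeak, creset, dinc,
    v, u,
    indptr, syn_post, syn_w, syn_cls, syn_u, syn_x, syn_tlast,
    cls_U, cls_tau_u, cls_tau_x, cls_gf, cls_gs, cls_df, cls_ds,
    cls_Ef, cls_Es, cls_inh, cls_lo, cls_hi,
    gf_acc, gs_acc,
    drive_rows, drive_conj, drive_place, conj_lo, place_lo,
    I_bias, noise_amp, noise_seed,
    spike_ring, ring_pos, delay_steps,
    sp_t, sp_n, spike_count0,
    mon_ids, mon_v, mon_I, mon_stride,
    t_offset_ms,
):
    n = v.shape[0]
    ncls = cls_U.shape[0]
    nconj = drive_conj.shape[1]
    nplace = drive_place.shape[1]
    I = np.zeros(n)
    count = spike_count0
    cap = sp_t.shape[0]
    nmon = mon_ids.shape[0]
    for step in range(n_steps):
        t_ms = t_offset_ms + (step + 1) * dt

        # 1. decay per-class conductance accumulators over their post slice
        for ci in range(ncls):
            df = cls_df[ci]
            ds = cls_ds[ci]
            for i in range(cls_lo[ci], cls_hi[ci]):
                gf_acc[ci, i] *= df
                gs_acc[ci, i] *= ds

        # 2. deliver spikes emitted one axonal delay ago
        slot = ring_pos % delay_steps
        for j in range(n):
            if spike_ring[slot, j] == 1:
                for s in range(indptr[j], indptr[j + 1]):
                    ci = syn_cls[s]
                    dt_last = t_ms - syn_tlast[s]
                    uu = syn_u[s] * np.exp(-dt_last / cls_tau_u[ci])
                    xx = 1.0 - (1.0 - syn_x[s]) * np.exp(-dt_last / cls_tau_x[ci])
                    uu = uu + cls_U[ci] * (1.0 - uu)
                    R = uu * xx
                    syn_u[s] = uu
                    syn_x[s] = xx - R
                    syn_tlast[s] = t_ms
                    post = syn_post[s]
                    wR = syn_w[s] * R
                    gf_acc[ci, post] += cls_gf[ci] * wR
                    gs_acc[ci, post] += cls_gs[ci] * wR
                spike_ring[slot, j] = 0

        # 3. receptor currents
        for i in range(n):
            I[i] = I_bias[i]
        for ci in range(ncls):
            Ef = cls_Ef[ci]
            Es = cls_Es[ci]
            inh = cls_inh[ci]
            for i in range(cls_lo[ci], cls_hi[ci]):
                vi = v[i]
                Ii = gf_acc[ci, i] * (Ef - vi)
                g = gs_acc[ci, i]
                if g > 0.0:
                    if inh == 1:
                        gate = 1.0
                    else:
                        w80 = (vi + 80.0) / 60.0
                        gate = w80 * w80 / (1.0 + w80 * w80)
                    Ii += gate * g * (Es - vi)
                I[i] += Ii

        # 4. external drive
        row = drive_rows[step]
        for j in range(nconj):
            I[conj_lo + j] += drive_conj[row, j]
        for j in range(nplace):
            I[place_lo + j] += drive_place[row, j]
        # seeded counter-based uniform noise (std = noise_amp, mean 0)
        if noise_seed != 0:
            base = np.uint64(noise_seed) + np.uint64(ring_pos) * np.uint64(0x9E3779B97F4A7C15)
            for i in range(n):
                if noise_amp[i] > 0.0:
                    z = base + np.uint64(i + 1) * np.uint64(0xBF58476D1CE4E5B9)
                    z = (z ^ (z >> np.uint64(30))) * np.uint64(0x94D049BB133111EB)
                    z = z ^ (z >> np.uint64(31))
                    un = np.float64(z & np.uint64(0xFFFFFFFF)) / 4294967296.0
                    I[i] += noise_amp[i] * 1.7320508075688772 * (2.0 * un - 1.0)

        # 5. IM step (two v-substeps), spike detection
        new_slot = ring_pos % delay_steps
        for i in range(n):
            vi = v[i]
            ui = u[i]
            half = 0.5 * dt
            for _ in range(2):
                vi = vi + half * (k[i] * (vi - Vr[i]) * (vi - Vt[i]) - ui + I[i]) / C[i]
            ui = ui + dt * a[i] * (b[i] * (vi - Vr[i]) - ui)
            if vi >= Vpeak[i]:
                spike_ring[new_slot, i] = 1
                vi = creset[i]
                ui = ui + dinc[i]
                t_rec = t_ms - record_from_ms
                if t_rec >= 0.0:
                    if count >= cap:
                        return count, 2, step
                    sp_t[count] = t_rec
                    sp_n[count] = i
                    count += 1
            if vi > 1000.0 or vi < -1000.0 or not np.isfinite(vi):
                return count, 1, step
            v[i] = vi
            u[i] = ui
        ring_pos += 1

        # 6. monitors
        if nmon > 0 and step % mon_stride == 0:
            r = step // mon_stride
            for m in range(nmon):
                i = mon_ids[m]
                mon_v[r, m] = Vpeak[i] if spike_ring[new_slot, i] == 1 else v[i]
                for ci in range(ncls):
                    if cls_lo[ci] <= i < cls_hi[ci]:
                        vi = v[i]
                        If = gf_acc[ci, i] * (cls_Ef[ci] - vi)
                        g = gs_acc[ci, i]
                        if cls_inh[ci] == 1:
                            gate = 1.0
                            mon_I[r, m, 2] += If
                            mon_I[r, m, 3] += gate * g * (cls_Es[ci] - vi)
                        else:
                            w80 = (vi + 80.0) / 60.0
                            gate = w80 * w80 / (1.0 + w80 * w80)
                            mon_I[r, m, 0] += If
                            mon_I[r, m, 1] += gate * g * (cls_Es[ci] - vi)
    return count, 0, n_steps - 1


class _FlatNetwork:
    """Flat-array view of a NetworkSpec for the kernel."""

    def __init__(self, net: NetworkSpec, cfg: SimConfig):
        pops = [p for p in POP_ORDER if p in net.populations]
        self.pop_slices: dict[str, slice] = {}
        offset = 0
        for name in pops:
            n = net.populations[name].count
            self.pop_slices[name] = slice(offset, offset + n)
            offset += n
        self.n = offset

        self.C = np.empty(self.n); self.k = np.empty(self.n)
        self.Vr = np.empty(self.n); self.Vt = np.empty(self.n)
        self.a = np.empty(self.n); self.b = np.empty(self.n)
        self.Vpeak = np.empty(self.n); self.c = np.empty(self.n); self.d = np.empty(self.n)
        for name in pops:
            sl = self.pop_slices[name]
            p = net.populations[name].params
            for arr, val in ((self.C, p.C), (self.k, p.k), (self.Vr, p.Vr),
                             (self.Vt, p.Vt), (self.a, p.a), (self.b, p.b),
                             (self.Vpeak, p.Vpeak), (self.c, p.c), (self.d, p.d)):
                arr[sl] = val

        syn_params = net.synapse_params
        self.class_names = list(net.connections.classes.keys())
        ncls = len(self.class_names)
        self.cls_U = np.empty(ncls); self.cls_tau_u = np.empty(ncls)
        self.cls_tau_x = np.empty(ncls); self.cls_gf = np.empty(ncls)
        self.cls_gs = np.empty(ncls); self.cls_tau_df = np.empty(ncls)
        self.cls_tau_ds = np.empty(ncls)
        self.cls_Ef = np.empty(ncls); self.cls_Es = np.empty(ncls)
        self.cls_inh = np.zeros(ncls, dtype=np.int64)
        self.cls_lo = np.zeros(ncls, dtype=np.int64)
        self.cls_hi = np.zeros(ncls, dtype=np.int64)

        pre_all, post_all, w_all, cls_all = [], [], [], []
        for ci, name in enumerate(self.class_names):
            conn = net.connections.classes[name]
            sp = syn_params[name]
            scale = cfg.weight_scale.get(name, 1.0)
            self.cls_U[ci] = sp.U
            self.cls_tau_u[ci] = sp.tau_u
            self.cls_tau_x[ci] = sp.tau_x
            self.cls_gf[ci] = sp.g_fast
            self.cls_gs[ci] = sp.g_slow * cfg.slow_scale.get(name, 1.0)
            self.cls_tau_df[ci] = sp.tau_d_fast
            self.cls_tau_ds[ci] = sp.tau_d_slow
            self.cls_Ef[ci] = sp.E_rev_fast
            self.cls_Es[ci] = sp.E_rev_slow
            self.cls_inh[ci] = 1 if sp.is_inhibitory else 0
            post_sl = self.pop_slices[conn["post_pop"]]
            self.cls_lo[ci] = post_sl.start
            self.cls_hi[ci] = post_sl.stop
            pre_sl = self.pop_slices[conn["pre_pop"]]
            pre_all.append(conn["pre"] + pre_sl.start)
            post_all.append(conn["post"] + post_sl.start)
            w_all.append(conn["weight"] * scale)
            cls_all.append(np.full(conn["pre"].size, ci, dtype=np.int64))

        pre = np.concatenate(pre_all)
        order = np.argsort(pre, kind="stable")
        self.syn_pre = pre[order]
        self.syn_post = np.concatenate(post_all)[order]
        self.syn_w = np.concatenate(w_all)[order]
        self.syn_cls = np.concatenate(cls_all)[order]
        self.indptr = np.searchsorted(self.syn_pre, np.arange(self.n + 1)).astype(np.int64)
        self.n_syn = self.syn_pre.size


def run_simulation(
    net: NetworkSpec,
    traj: Trajectory,
    cfg: SimConfig | None = None,
    seed: int = 0,
    monitor_neurons: dict[str, list[int]] | None = None,
    duration_s: float | None = None,
) -> tuple[SpikeData, MonitorTrace | None]:
    """Simulate the network driven by a trajectory.

    A settling period (``cfg.settle_s``) with the animal stationary at
    its starting position precedes the run and is excluded from the
    recorded spikes; spike times are reported in ms from the end of
    settling.  ``monitor_neurons`` maps population name to local ids of
    neurons whose voltage/current should be traced every step.
    """
    cfg = cfg or SimConfig()
    if traj.dt and abs(traj.dt - cfg.traj_dt) > 1e-9:
        traj = traj.resample(cfg.traj_dt)
    if duration_s is None:
        duration_s = traj.duration
    flat = _FlatNetwork(net, cfg)
    rng = np.random.default_rng(seed)

    side = net.grid_side
    angles = np.array([DIRECTION_ANGLES[d] for d in net.directions])
    d_conj = conjunctive_drive(traj, angles, cfg.I_base, cfg.g_speed)
    centers = place_field_centers(side, traj.arena)
    d_place = place_drive(traj, centers, cfg.g_place, cfg.sigma_p)
    # settle row: stationary animal at the starting position
    settle_conj = np.full((1, d_conj.shape[1]), cfg.I_base)
    settle_place = d_place[:1]
    drive_conj = np.vstack([settle_conj, d_conj]).astype(np.float64)
    drive_place = np.vstack([settle_place, d_place]).astype(np.float64)
    if cfg.drive_jitter > 0:
        # static per-cell heterogeneity: identical tonically driven cells
        # otherwise lock into network-wide synchronous pulsing
        jit = np.random.default_rng(seed + 7919)
        drive_conj *= 1.0 + cfg.drive_jitter * (2.0 * jit.random(drive_conj.shape[1]) - 1.0)
        drive_place *= 1.0 + cfg.drive_jitter * (2.0 * jit.random(drive_place.shape[1]) - 1.0)

    dt = cfg.dt
    settle_steps = int(round(cfg.settle_s * 1000.0 / dt))
    run_steps = int(round(duration_s * 1000.0 / dt))
    n_steps = settle_steps + run_steps
    traj_dt_ms = cfg.traj_dt * 1000.0
    steps = np.arange(n_steps)
    rows = np.where(
        steps < settle_steps,
        0,
        1 + np.minimum(((steps - settle_steps) * dt / traj_dt_ms).astype(np.int64),
                       d_conj.shape[0] - 1),
    ).astype(np.int64)

    v = flat.Vr + cfg.jitter_mv * (2.0 * rng.random(flat.n) - 1.0)
    u = np.zeros(flat.n)
    gf_acc = np.zeros((len(flat.class_names), flat.n))
    gs_acc = np.zeros_like(gf_acc)
    syn_u = np.zeros(flat.n_syn)
    syn_x = np.ones(flat.n_syn)
    syn_tlast = np.zeros(flat.n_syn)
    delay_steps = max(1, int(round(cfg.delay_ms / dt)))
    spike_ring = np.zeros((delay_steps, flat.n), dtype=np.uint8)

    I_bias = np.zeros(flat.n)
    if cfg.I_bias_stellate:
        I_bias[flat.pop_slices["MEC LII Stellate"]] = cfg.I_bias_stellate
    noise_amp = np.zeros(flat.n)
    if cfg.noise_pA > 0:
        for pop in ("MEC LII Stellate", *[p for p in IN_TYPES if p in flat.pop_slices]):
            noise_amp[flat.pop_slices[pop]] = cfg.noise_pA
    noise_seed = (seed * 2654435761 + 12345) % (2**63) if cfg.noise_pA > 0 else 0

    mon_ids = np.empty(0, dtype=np.int64)
    if monitor_neurons:
        ids = []
        for pop, local in monitor_neurons.items():
            start = flat.pop_slices[pop].start
            ids.extend(start + li for li in local)
        mon_ids = np.asarray(ids, dtype=np.int64)
    mon_v = np.zeros((n_steps if mon_ids.size else 0, mon_ids.size))
    mon_I = np.zeros((n_steps if mon_ids.size else 0, mon_ids.size, 4))

    cls_df = np.exp(-dt / flat.cls_tau_df)
    cls_ds = np.exp(-dt / flat.cls_tau_ds)
    conj_lo = flat.pop_slices["EC LI-II Multipolar Pyramidal"].start
    place_lo = flat.pop_slices["CA1 Pyramidal"].start

    record_from_ms = settle_steps * dt
    all_t: list[np.ndarray] = []
    all_n: list[np.ndarray] = []
    chunk_steps = max(1, int(round(cfg.chunk_s * 1000.0 / dt)))
    step0 = 0
    ring_pos = 0
    while step0 < n_steps:
        this = min(chunk_steps, n_steps - step0)
        cap = max(200_000, int(this * dt / 1000.0 * flat.n * 120))
        while True:
            state = (v.copy(), u.copy(), gf_acc.copy(), gs_acc.copy(),
                     syn_u.copy(), syn_x.copy(), syn_tlast.copy(),
                     spike_ring.copy(), ring_pos)
            sp_t = np.empty(cap)
            sp_n = np.empty(cap, dtype=np.int64)
            count, status, last = _step_kernel(
                this, dt, record_from_ms,
                flat.C, flat.k, flat.Vr, flat.Vt, flat.a, flat.b,
                flat.Vpeak, flat.c, flat.d,
                v, u,
                flat.indptr, flat.syn_post, flat.syn_w, flat.syn_cls,
                syn_u, syn_x, syn_tlast,
                flat.cls_U, flat.cls_tau_u, flat.cls_tau_x,
                flat.cls_gf, flat.cls_gs, cls_df, cls_ds,
                flat.cls_Ef, flat.cls_Es, flat.cls_inh, flat.cls_lo, flat.cls_hi,
                gf_acc, gs_acc,
                rows[step0:step0 + this], drive_conj, drive_place, conj_lo, place_lo,
                I_bias, noise_amp, noise_seed,
                spike_ring, ring_pos, delay_steps,
                sp_t, sp_n, 0,
                mon_ids, mon_v[step0:step0 + this] if mon_ids.size else mon_v,
                mon_I[step0:step0 + this] if mon_ids.size else mon_I,
                1,
                step0 * dt,
            )
            if status == 2:  # spike buffer overflow: restore and enlarge
                (v, u, gf_acc, gs_acc, syn_u, syn_x, syn_tlast,
                 spike_ring, ring_pos) = state
                v, u = v.copy(), u.copy()
                cap *= 4
                continue
            if status == 1:
                t_fail = (step0 + last + 1) * dt
                raise FloatingPointError(
                    f"membrane potential blow-up at t={t_fail:.1f} ms "
                    f"(step {step0 + last}); check drive gains and weights"
                )
            break
        all_t.append(sp_t[:count].copy())
        all_n.append(sp_n[:count].copy())
        step0 += this
        ring_pos += this

    times = np.concatenate(all_t)
    neurons = np.concatenate(all_n)
    spikes = SpikeData(times, neurons, flat.pop_slices, dt, run_steps * dt)
    mon = None
    if mon_ids.size:
        mon = MonitorTrace(mon_ids, mon_v[settle_steps:], mon_I[settle_steps:], dt)
    return spikes, mon
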