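"""Tsodyks–Markram (TM) short-term plasticity and receptor currents.

Each synapse carries a utilization variable ``u`` (facilitation, baseline
0, relaxing with ``tau_u``) and a resource variable ``x`` (depression,
baseline 1, recovering with ``tau_x``).  On a presynaptic spike the
utilization jumps first, then a fraction ``R = u * x`` of the resources
is released and added to the receptor conductances:

    u <- u + U (1 - u)
    R  = u * x
    x <- x - R
    g_fast <- g_fast + g_peak_fast * R   (likewise slow)

Between spikes all variables relax with exact exponential updates, so
the inter-spike evolution is independent of the integration step size.

Receptor currents are conductance-based: fast AMPA / GABA_A and slow
NMDA / GABA_B, the NMDA conductance gated by the magnesium-block factor
``s(v) = ((v + 80)/60)^2 / (1 + ((v + 80)/60)^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import SynapseParams

__all__ = [
    "SynapseState",
    "tm_on_spike",
    "tm_decay",
    "nmda_gate",
    "receptor_current",
    "conductance_train",
]


@dataclass
class SynapseState:
    """Per-synapse TM state and instantaneous receptor conductances (nS)."""

    u: float = 0.0
    x: float = 1.0
    g_syn_fast: float = 0.0
    g_syn_slow: float = 0.0


def tm_on_spike(state: SynapseState, params: SynapseParams) -> SynapseState:
    """Apply the presynaptic-spike update (jump-then-release order)."""
    u = state.u + params.U * (1.0 - state.u)
    R = u * state.x
    return SynapseState(
        u=u,
        x=state.x - R,
        g_syn_fast=state.g_syn_fast + params.g_fast * R,
        g_syn_slow=state.g_syn_slow + params.g_slow * R,
    )


def tm_decay(state: SynapseState, params: SynapseParams, dt: float) -> SynapseState:
    """Relax the TM state over a spike-free interval of ``dt`` ms (exact)."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return SynapseState(
        u=state.u * np.exp(-dt / params.tau_u),
        x=1.0 - (1.0 - state.x) * np.exp(-dt / params.tau_x),
        g_syn_fast=state.g_syn_fast * np.exp(-dt / params.tau_d_fast),
        g_syn_slow=state.g_syn_slow * np.exp(-dt / params.tau_d_slow),
    )


def nmda_gate(v: np.ndarray | float) -> np.ndarray | float:
    """Voltage dependence of the NMDA conductance (magnesium block)."""
    w = (np.asarray(v, dtype=float) + 80.0) / 60.0
    s = w * w / (1.0 + w * w)
    return float(s) if np.ndim(v) == 0 else s

def receptor_current(
    g_syn_fast: float,
    g_syn_slow: float,
    v: float,
    params: SynapseParams,
) -> float:
    """Total synaptic current in pA at membrane potential ``v`` (mV).

    Positive current depolarizes.  The slow conductance is NMDA-gated for
    excitatory classes and ungated (GABA_B) for inhibitory ones.
    """
    if g_syn_fast < 0 or g_syn_slow < 0:
        raise ValueError("conductances must be non-negative")
    I = g_syn_fast * (params.E_rev_fast - v)
    gate = 1.0 if params.is_inhibitory else nmda_gate(v)
    I += gate * g_syn_slow * (params.E_rev_slow - v)
    return I


def conductance_train(
    params: SynapseParams,
    spike_times_ms: np.ndarray,
    duration_ms: float,
    dt: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Step the TM model through a presynaptic spike train.

    Returns ``(t, g_fast, g_slow, releases)`` sampled every ``dt`` ms
    (conductances recorded after the step's decay and any spike event).
    Spike times are snapped to the step grid.
    """
    spike_steps = {int(round(s / dt)) for s in np.asarray(spike_times_ms, dtype=float)}
    n = int(round(duration_ms / dt))
    t = np.arange(1, n + 1) * dt
    gf = np.empty(n)
    gs = np.empty(n)
    releases: list[float] = []
    state = SynapseState()
    for i in range(n):
        state = tm_decay(state, params, dt)
        if (i + 1) in spike_steps:
            before_x = state.x
            state = tm_on_spike(state, params)
            releases.append(before_x - state.x)
        gf[i] = state.g_syn_fast
        gs[i] = state.g_syn_slow
    return t, gf, gs, releases


def steady_state_release(params: SynapseParams, rate_hz: float, tol: float = 1e-12, max_iter: int = 100000) -> float:
    """Release fraction per spike under periodic drive, by fixed-point
    iteration of the inter-spike (u, x) map."""
    isi = 1000.0 / rate_hz
    eu = np.exp(-isi / params.tau_u)
    ex = np.exp(-isi / params.tau_x)
    u, x = 0.0, 1.0
    R_prev = np.inf
    for _ in range(max_iter):
        u_plus = u + params.U * (1.0 - u)
        R = u_plus * x
        if abs(R - R_prev) < tol:
            return R
        R_prev = R
        # relax to just before the next spike
        u = u_plus * eu
        x = 1.0 - (1.0 - (x - R)) * ex
    return R_prev
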