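"""Izhikevich-model (IM) membrane dynamics.

The nine-parameter 2007 form of the model is used for every neuron type:

    C dv/dt = k (v - Vr)(v - Vt) - u + I
      du/dt = a (b (v - Vr) - u)

with the spike rule: when ``v >= Vpeak`` the step records a spike, the
trace value is clamped to ``Vpeak``, and the state is reset ``v <- c``,
``u <- u + d``.  Integration is forward Euler with two membrane-potential
substeps per step for stability at the capacitances used here.

Functions operate on scalars or numpy arrays (one entry per neuron).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NeuronParams

__all__ = ["NeuronState", "im_step", "rheobase", "simulate_constant_current", "fi_curve"]


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV), recovery ``u`` (pA), and the spike
    flag for the current step.  ``v``/``u`` may be scalars or arrays."""

    v: np.ndarray | float
    u: np.ndarray | float
    spiked: np.ndarray | bool = False

    @classmethod
    def resting(cls, params: NeuronParams, n: int | None = None) -> "NeuronState":
        if n is None:
            return cls(v=params.Vr, u=0.0, spiked=False)
        return cls(
            v=np.full(n, params.Vr, dtype=float),
            u=np.zeros(n, dtype=float),
            spiked=np.zeros(n, dtype=bool),
        )


def im_step(
    state: NeuronState,
    params: NeuronParams,
    I_syn: np.ndarray | float,
    dt: float,
    neuron_index: int | np.ndarray | None = None,
    step: int | None = None,
) -> NeuronState:
    """Advance the IM state by one time step of ``dt`` ms.

    ``I_syn`` is the total injected current in pA (positive depolarizes).
    Returns a new :class:`NeuronState`; the spike flag is set exactly for
    neurons whose potential crossed ``Vpeak`` during this step, and the
    reported ``v`` never exceeds ``Vpeak``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    v = np.asarray(state.v, dtype=float)
    u = np.asarray(state.u, dtype=float)
    I = np.asarray(I_syn, dtype=float)

    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u)) and np.all(np.isfinite(I))):
        bad = ~(np.isfinite(v) & np.isfinite(u) & np.isfinite(np.broadcast_to(I, v.shape)))
        idx = np.flatnonzero(np.atleast_1d(bad))
        raise FloatingPointError(
            f"non-finite neuron state or input at step {step} "
            f"(neuron indices {idx.tolist() if idx.size else neuron_index})"
        )

    half = 0.5 * dt
    for _ in range(2):  # two v-substeps per step
        v = v + half * (params.k * (v - params.Vr) * (v - params.Vt) - u + I) / params.C
    u = u + dt * params.a * (params.b * (v - params.Vr) - u)

    crossed = v >= params.Vpeak
    v = np.where(crossed, params.c, v)
    u = np.where(crossed, u + params.d, u)

    if np.ndim(state.v) == 0:
        return NeuronState(v=float(v), u=float(u), spiked=bool(crossed))
    return NeuronState(v=v, u=u, spiked=crossed)


def rheobase(params: NeuronParams) -> float:
    """Closed-form saddle-node (rheobase) current in pA.

    The v- and u-nullclines touch where d/dv of
    ``k (v - Vr)(v - Vt) + I - b (v - Vr)`` vanishes, i.e. at
    ``v* = (Vr + Vt)/2 + b/(2k)``; the minimal sustained current that
    removes the resting fixed point is

        I* = -k (v* - Vr)(v* - Vt) + b (v* - Vr).
    """
    v_star = 0.5 * (params.Vr + params.Vt) + params.b / (2.0 * params.k)
    return -params.k * (v_star - params.Vr) * (v_star - params.Vt) + params.b * (v_star - params.Vr)


def simulate_constant_current(
    params: NeuronParams,
    I: float,
    duration_ms: float,
    dt: float = 0.5,
) -> np.ndarray:
    """Spike times (ms) of a single neuron from rest under constant current."""
    state = NeuronState.resting(params)
    n_steps = int(round(duration_ms / dt))
    times = []
    for i in range(n_steps):
        state = im_step(state, params, I, dt, step=i)
        if state.spiked:
            times.append((i + 1) * dt)
    return np.asarray(times)


def fi_curve(
    params: NeuronParams,
    currents: np.ndarray,
    duration_ms: float = 1000.0,
    dt: float = 0.5,
) -> np.ndarray:
    """Firing rate (spikes/s) for each injected current in ``currents``."""
    rates = [
        len(simulate_constant_current(params, float(I), duration_ms, dt)) / (duration_ms / 1000.0)
        for I in np.asarray(currents, dtype=float)
    ]
    return np.asarray(rates)
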