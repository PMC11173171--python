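"""Neuron and synapse model parameters.

Default values are the Hippocampome.org-derived constants used by the
medial-entorhinal grid-cell network: nine Izhikevich-model (IM) constants
per neuron type and Tsodyks–Markram (TM) short-term-plasticity constants
plus receptor conductances per connection class.  Parameter sets are keyed
by the neuron-type and connection-class names used throughout the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "NEURON_PARAMS",
    "SYNAPSE_PARAMS",
    "POPULATION_COUNTS",
    "LARGE_SCALE_IN_COUNT",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class NeuronParams:
    """Nine-parameter Izhikevich model constants for one neuron type.

    Parameters
    ----------
    C : float
        Membrane capacitance (pF).
    k : float
        Quadratic voltage gain (nS/mV).
    Vr : float
        Resting potential (mV).
    Vt : float
        Instantaneous threshold potential (mV).
    a : float
        Recovery-variable rate constant (1/ms).
    b : float
        Recovery-variable sensitivity to ``v - Vr`` (nS).  May be
        negative (e.g. CA1 pyramidal cells).
    Vpeak : float
        Spike cutoff value (mV).
    c : float
        Post-spike reset potential, also written ``V_min`` (mV).
    d : float
        Post-spike recovery-variable increment (pA).
    """

    C: float
    k: float
    Vr: float
    Vt: float
    a: float
    b: float
    Vpeak: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not self.Vr < self.Vt:
            raise ValueError(f"require Vr < Vt, got Vr={self.Vr}, Vt={self.Vt}")
        if not self.Vpeak > self.Vt:
            raise ValueError(f"require Vpeak > Vt, got {self.Vpeak}, {self.Vt}")
        if not self.c < self.Vpeak:
            raise ValueError(f"require c < Vpeak, got {self.c}, {self.Vpeak}")

    @property
    def V_min(self) -> float:
        """Alias for the post-spike reset value ``c``."""
        return self.c

    def replace(self, **changes) -> "NeuronParams":
        data = asdict(self)
        data.update(changes)
        return NeuronParams(**data)


@dataclass(frozen=True)
class SynapseParams:
    """TM plasticity and receptor constants for one connection class.

    The fast receptor is AMPA for excitatory classes and GABA_A for
    inhibitory ones; the slow receptor is NMDA / GABA_B respectively.
    Conductances are per-synapse peaks in nS; a global scale factor can
    be applied at network-build time.
    """

    g_fast: float
    tau_d_fast: float
    U: float
    tau_u: float
    tau_x: float
    g_slow: float
    tau_d_slow: float = 150.0
    E_rev_fast: float = 0.0
    E_rev_slow: float = 0.0
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        for name in ("tau_d_fast", "tau_u", "tau_x", "tau_d_slow"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.g_fast < 0 or self.g_slow < 0:
            raise ValueError("conductances must be non-negative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown sign {self.sign!r}")

    @property
    def is_inhibitory(self) -> bool:
        return self.sign == "inhibitory"

    def replace(self, **changes) -> "SynapseParams":
        data = asdict(self)
        data.update(changes)
        return SynapseParams(**data)


# Receptor reversal potentials (mV) and slow decay constants (ms).
E_REV_AMPA_NMDA = 0.0
E_REV_GABA_A = -70.0
E_REV_GABA_B = -90.0
TAU_D_SLOW = 150.0  # NMDA and GABA_B kinetic decay

#: IM constants per neuron type (C, k, Vr, Vt, a, b, Vpeak, c, d).
NEURON_PARAMS: dict[str, NeuronParams] = {
    "MEC LII Stellate": NeuronParams(118, 0.62, -58.53, -43.52, 0.005, 11.69, 11.48, -49.52, 0),
    "EC LI-II Multipolar Pyramidal": NeuronParams(375, 0.37, -70.53, -39.99, 0.001, 0.01, 3.96, -54.95, 7),
    "CA1 Pyramidal": NeuronParams(530, 1.74, -69.98, -57.43, 0.003, -0.782, 24.45, -60.35, 25),
    # Standard fast-spiking parameters for the three perisomatic-targeting
    # parvalbumin interneuron types (empirical IM fits unavailable).
    "EC LII Axo-Axonic": NeuronParams(20, 1, -55, -40, 0.15, 8, 25, -55, 200),
    "MEC LII Basket": NeuronParams(20, 1, -55, -40, 0.15, 8, 25, -55, 200),
    "EC LII Basket Multipolar": NeuronParams(20, 1, -55, -40, 0.15, 8, 25, -55, 200),
}

#: Neuron counts per type (intermediate/small grid-scale configuration).
POPULATION_COUNTS: dict[str, int] = {
    "MEC LII Stellate": 1600,
    "EC LI-II Multipolar Pyramidal": 1600,
    "CA1 Pyramidal": 1600,
    "EC LII Axo-Axonic": 834,
    "MEC LII Basket": 833,
    "EC LII Basket Multipolar": 833,
}

#: IN counts are raised for large grid-scale runs (bigger bumps need more
#: inhibitory control).
LARGE_SCALE_IN_COUNT = 1200

IN_TYPES = ("EC LII Axo-Axonic", "MEC LII Basket", "EC LII Basket Multipolar")


def _exc(g_fast, tau_d_fast, U, tau_u, tau_x, g_slow) -> SynapseParams:
    return SynapseParams(
        g_fast, tau_d_fast, U, tau_u, tau_x, g_slow,
        tau_d_slow=TAU_D_SLOW,
        E_rev_fast=E_REV_AMPA_NMDA, E_rev_slow=E_REV_AMPA_NMDA,
        sign="excitatory",
    )


def _inh(g_fast, tau_d_fast, U, tau_u, tau_x, g_slow) -> SynapseParams:
    return SynapseParams(
        g_fast, tau_d_fast, U, tau_u, tau_x, g_slow,
        tau_d_slow=TAU_D_SLOW,
        E_rev_fast=E_REV_GABA_A, E_rev_slow=E_REV_GABA_B,
        sign="inhibitory",
    )


#: TM constants per connection class: (g_fast nS, tau_d_fast ms, U,
#: tau_u ms, tau_x ms, g_slow nS).
SYNAPSE_PARAMS: dict[str, SynapseParams] = {
    "EC LI-II Multipolar Pyramidal to MEC LII Stellate": _exc(11.627, 3.380, 0.180, 49.920, 152.856, 7.126),
    "MEC LII Stellate to EC LII Axo-Axonic": _exc(1.050, 3.085, 0.167, 49.920, 167.686, 0.644),
    "MEC LII Stellate to MEC LII Basket": _exc(1.050, 2.887, 0.167, 49.920, 152.857, 0.644),
    "MEC LII Stellate to EC LII Basket Multipolar": _exc(1.050, 2.641, 0.197, 49.920, 136.570, 0.644),
    "EC LII Axo-Axonic to MEC LII Stellate": _inh(0.626, 4.561, 0.145, 27.306, 420.838, 0.383),
    "MEC LII Basket to MEC LII Stellate": _inh(0.626, 4.488, 0.151, 27.810, 443.499, 0.383),
    "EC LII Basket Multipolar to MEC LII Stellate": _inh(0.626, 4.948, 0.162, 30.543, 382.485, 0.383),
    "CA1 Pyramidal to MEC LII Stellate": _exc(9.248, 3.380, 0.123, 49.710, 153.400, 5.668),
}

#: Mean ± SD connection counts per presynaptic cell for each class.
CONNECTION_COUNTS: dict[str, tuple[float, float]] = {
    "EC LI-II Multipolar Pyramidal to MEC LII Stellate": (1, 0),
    "MEC LII Stellate to EC LII Axo-Axonic": (12, 2),
    "MEC LII Stellate to MEC LII Basket": (12, 2),
    "MEC LII Stellate to EC LII Basket Multipolar": (12, 2),
    "EC LII Axo-Axonic to MEC LII Stellate": (142, 66),
    "MEC LII Basket to MEC LII Stellate": (142, 66),
    "EC LII Basket Multipolar to MEC LII Stellate": (142, 66),
    "CA1 Pyramidal to MEC LII Stellate": (1, 0),
}


def default_config() -> dict:
    """Full default model configuration as a plain nested dict."""
    return {
        "neurons": {name: asdict(p) for name, p in NEURON_PARAMS.items()},
        "counts": dict(POPULATION_COUNTS),
        "synapses": {name: asdict(p) for name, p in SYNAPSE_PARAMS.items()},
        "connection_counts": {k: list(v) for k, v in CONNECTION_COUNTS.items()},
    }


def load_config(path: str | Path) -> dict:
    """Load a YAML model configuration; missing sections fall back to defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section in cfg and isinstance(values, dict):
            base = cfg[section]
            for key, val in values.items():
                if isinstance(val, dict) and isinstance(base.get(key), dict):
                    base[key].update(val)
                else:
                    base[key] = val
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def neuron_params_from_config(cfg: dict) -> dict[str, NeuronParams]:
    return {name: NeuronParams(**vals) for name, vals in cfg["neurons"].items()}


def synapse_params_from_config(cfg: dict) -> dict[str, SynapseParams]:
    return {name: SynapseParams(**vals) for name, vals in cfg["synapses"].items()}
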