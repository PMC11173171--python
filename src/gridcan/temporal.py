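"""Population spectral analysis and spike-phase coupling.

Network rhythms are read out from binned population firing rates: a
multitaper power spectral density per neuron-type group, summarized as
the fraction of 1–100 Hz power in the delta (1–4 Hz), theta (4–12 Hz),
beta (12–25 Hz) and gamma (25–100 Hz) bands; and spike-phase coupling of
each population to the stellate beta rhythm, quantified by the mean
resultant vector length (MRVL) of spike phases with a Rayleigh test for
non-uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "BANDS",
    "BandPowerSummary",
    "PhaseCoupling",
    "population_rate",
    "power_spectrum",
    "psd_band_fractions",
    "band_peak_frequency",
    "mrvl",
    "rayleigh_test",
    "spike_phase_coupling",
]

#: Frequency bands (Hz).
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "beta": (12.0, 25.0),
    "gamma": (25.0, 100.0),
}


@dataclass
class BandPowerSummary:
    """Fraction of total 1–100 Hz power per band for one population."""

    fractions: dict[str, float]
    peak_hz: dict[str, float]
    total_power: float

    def dominant_band(self) -> str:
        return max(self.fractions, key=self.fractions.get)


@dataclass
class PhaseCoupling:
    """Spike-phase coupling of one population to a reference rhythm."""

    mrvl: float
    rayleigh_p: float
    n_spikes: int
    band: tuple[float, float]
    phases: np.ndarray


def population_rate(
    spike_times_ms: np.ndarray,
    n_neurons: int,
    duration_ms: float,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined population firing rate in spikes/s per neuron.

    Returns ``(t_ms, rate)`` where ``t_ms`` are bin centers.
    """
    edges = np.arange(0.0, duration_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(spike_times_ms, bins=edges)
    rate = counts / n_neurons / (bin_ms / 1000.0)
    return 0.5 * (edges[:-1] + edges[1:]), rate


def power_spectrum(
    rate: np.ndarray,
    bin_ms: float = 1.0,
    smooth_ms: float = 3.0,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper power spectral density of a population-rate series.

    The rate series is Gaussian-smoothed with a ``smooth_ms`` window
    (suppresses binning harmonics) and mean-subtracted before the
    multitaper estimate (time-bandwidth 4, 7 tapers).
    """
    if rate.size < 2:
        raise ValueError("rate series too short")
    fs = 1000.0 / bin_ms
    x = np.asarray(rate, dtype=float)
    if smooth_ms > 0:
        x = ndimage.gaussian_filter1d(x, smooth_ms / bin_ms)
    x = x - x.mean()
    from mne.time_frequency import psd_array_multitaper
    psd, freqs = psd_array_multitaper(
        x[np.newaxis, :], sfreq=fs, fmin=0.5, fmax=120.0,
        bandwidth=bandwidth, adaptive=False, normalization="full", verbose=False,
    )
    return freqs, psd[0]


def psd_band_fractions(
    rate: np.ndarray,
    bin_ms: float = 1.0,
    smooth_ms: float = 3.0,
    min_duration_s: float = 10.0,
) -> BandPowerSummary:
    """Band power fractions over the 1–100 Hz range.

    Requires at least ``min_duration_s`` of data (spectral resolution).
    """
    duration_s = rate.size * bin_ms / 1000.0
    if duration_s < min_duration_s:
        raise ValueError(f"series of {duration_s:.1f} s is shorter than {min_duration_s} s")
    freqs, psd = power_spectrum(rate, bin_ms, smooth_ms)
    in_total = (freqs >= 1.0) & (freqs <= 100.0)
    total = np.trapezoid(psd[in_total], freqs[in_total])
    fractions, peaks = {}, {}
    for name, (lo, hi) in BANDS.items():
        m = (freqs >= lo) & (freqs <= hi)
        fractions[name] = float(np.trapezoid(psd[m], freqs[m]) / total) if total > 0 else 0.0
        peaks[name] = float(freqs[m][np.argmax(psd[m])]) if m.any() else np.nan
    return BandPowerSummary(fractions, peaks, float(total))


def band_peak_frequency(rate: np.ndarray, band: tuple[float, float], bin_ms: float = 1.0) -> float:
    """Frequency of maximal power within ``band`` (Hz)."""
    freqs, psd = power_spectrum(rate, bin_ms)
    m = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[m][np.argmax(psd[m])])


def mrvl(phases: np.ndarray) -> float:
    """Mean resultant vector length of circular data (0–1)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return 0.0
    return float(np.abs(np.exp(1j * phases).mean()))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(R, p)`` where R is the MRVL and p uses the standard
    approximation ``p = exp(sqrt(1+4n+4(n^2-Rn^2)) - (1+2n))`` with
    ``Rn = n * R`` (accurate for n >= 10 and small p).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    R = mrvl(phases)
    Rn = n * R
    z = Rn ** 2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - Rn ** 2)) - (1.0 + 2.0 * n))
    if not np.isfinite(p):
        p = 1.0
    return R, float(min(max(p, 0.0), 1.0))


def spike_phase_coupling(
    spike_times_ms: np.ndarray,
    reference_rate: np.ndarray,
    band: tuple[float, float] = BANDS["beta"],
    bin_ms: float = 1.0,
    center_hz: float | None = None,
    half_width_hz: float = 3.0,
) -> PhaseCoupling:
    """Spike-phase coupling of a spike train to a reference rhythm.

    The reference population rate is band-pass filtered around the
    band's spectral peak (width ``±half_width_hz``), the instantaneous
    phase extracted with the analytic signal, each spike is assigned the
    phase at its time, and MRVL / Rayleigh p are computed.
    """
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    if spike_times_ms.size < 10:
        raise ValueError(f"need at least 10 spikes, got {spike_times_ms.size}")
    fs = 1000.0 / bin_ms
    if center_hz is None:
        center_hz = band_peak_frequency(reference_rate, band, bin_ms)
    lo = max(center_hz - half_width_hz, 0.5)
    hi = min(center_hz + half_width_hz, 0.45 * fs)
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(reference_rate, float) - np.mean(reference_rate))
    phase = np.angle(signal.hilbert(filt))
    idx = np.clip((spike_times_ms / bin_ms).astype(np.int64), 0, phase.size - 1)
    phases = phase[idx]
    R, p = rayleigh_test(phases)
    return PhaseCoupling(mrvl=R, rayleigh_p=p, n_spikes=phases.size, band=(lo, hi), phases=phases)
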