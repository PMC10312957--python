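"""Spectral and spike-train readouts: peak gamma power, firing rates, CV_ISI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SpectralResult",
    "NetworkMetrics",
    "peak_gamma_power",
    "band_power",
    "cv_isi",
    "firing_rates",
    "trial_metrics",
    "GAMMA_BAND",
]

GAMMA_BAND = (30.0, 80.0)


@dataclass
class SpectralResult:
    frequencies: np.ndarray
    power: np.ndarray  # density, model-units^2 / Hz
    peak_gamma_power: float
    peak_frequency: float
    band: tuple
    band_integral: float


@dataclass
class NetworkMetrics:
    rate_pyramidal: float
    rate_pvi: float
    cv_isi: float
    n_cv_excluded: int
    gamma: SpectralResult | None = None


def peak_gamma_power(trace: np.ndarray, dt_ms: float,
                     band: tuple = GAMMA_BAND,
                     segment_ms: float = 500.0) -> SpectralResult:
    """Welch PSD of a current trace; peak value and frequency in ``band``.

    Hann-tapered segments of ``segment_ms`` with 50% overlap; the trace mean
    is removed per segment, so a DC offset does not change the result.
    """
    trace = np.asarray(trace, dtype=float)
    fs = 1000.0 / dt_ms
    nperseg = int(round(segment_ms / dt_ms))
    if trace.size < 2 * nperseg:
        raise ValueError("trace shorter than two Welch segments")
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2} Hz)")
    freqs, psd = signal.welch(trace, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="constant")
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError("no PSD bins inside the requested band")
    i = int(np.argmax(np.where(in_band, psd, -np.inf)))
    df = freqs[1] - freqs[0]
    return SpectralResult(
        frequencies=freqs, power=psd,
        peak_gamma_power=float(psd[i]), peak_frequency=float(freqs[i]),
        band=(lo, hi), band_integral=float(psd[in_band].sum() * df),
    )


def band_power(trace: np.ndarray, dt_ms: float, band: tuple = GAMMA_BAND,
               mode: str = "peak", segment_ms: float = 500.0) -> float:
    """Gamma power as either the band maximum of the PSD (default) or the
    band-integrated power (sensitivity-analysis mode)."""
    res = peak_gamma_power(trace, dt_ms, band=band, segment_ms=segment_ms)
    if mode == "peak":
        return res.peak_gamma_power
    if mode == "integral":
        return res.band_integral
    raise ValueError(f"unknown mode {mode!r}")


def cv_isi(spike_trains: list[np.ndarray], min_spikes: int = 3
           ) -> tuple[float, int]:
    """Mean over neurons of SD(ISI)/mean(ISI), sample SD (n-1 denominator).

    Neurons with fewer than ``min_spikes`` spikes are excluded; returns the
    mean CV and the number of excluded neurons. With no eligible neuron the
    CV is NaN (flagged by the caller).
    """
    cvs = []
    excluded = 0
    for train in spike_trains:
        train = np.asarray(train, dtype=float)
        if train.size < min_spikes:
            excluded += 1
            continue
        isi = np.diff(np.sort(train))
        m = isi.mean()
        cvs.append(isi.std(ddof=1) / m if m > 0 else np.nan)
    if not cvs:
        return float("nan"), excluded
    return float(np.nanmean(cvs)), excluded


def firing_rates(spike_trains: list[np.ndarray], window_ms: float
                 ) -> float:
    """Population-mean firing rate (spikes/s) over an analysis window."""
    if window_ms <= 0:
        raise ValueError("window must be positive")
    counts = [np.asarray(t).size for t in spike_trains]
    return float(np.mean(counts) / (window_ms / 1000.0))


def trial_metrics(result, band: tuple = GAMMA_BAND, mode: str = "peak",
                  segment_ms: float = 500.0) -> NetworkMetrics:
    """All three readouts for one simulation trial (a ``SimResult``)."""
    window = result.duration_ms - result.transient_ms
    e_trains = result.spike_trains("E")
    i_trains = result.spike_trains("I")
    spec = peak_gamma_power(result.exc_current, result.dt_ms, band=band,
                            segment_ms=segment_ms)
    cv, excl = cv_isi(e_trains)
    return NetworkMetrics(
        rate_pyramidal=firing_rates(e_trains, window),
        rate_pvi=firing_rates(i_trains, window),
        cv_isi=cv, n_cv_excluded=excl, gamma=spec,
    )
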