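"""Morlet continuous wavelet transform and band-averaged wavelet amplitude.

Slow hemodynamic oscillations are analysed with a Morlet CWT (central
frequency parameter ω0 = 6 by default) on a logarithmic frequency grid,
16 voices per octave over 0.0095–2 Hz.  The transform is evaluated in
the frequency domain: the signal is Fourier transformed once and
multiplied by the analytic Morlet window at every scale, which keeps the
many-scale transform cheap enough to run inside large surrogate
ensembles.

The wavelet amplitude (WA) of a channel is the coefficient modulus
averaged over time (outside the cone of influence by default) and then
over the frequencies of the 0.01–0.08 Hz neural band; it serves as the
activation measure that feeds the lateralization index and the group
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .errors import ConfigurationError, DataQualityError, DomainError
from .montage_io import RegionMap

ANALYSIS_BAND_HZ = (0.01, 0.08)
GRID_F_MIN_HZ = 0.0095
GRID_F_MAX_HZ = 2.0
N_VOICES_DEFAULT = 16
OMEGA0_DEFAULT = 6.0


@dataclass
class WaveletSpectrum:
    """Complex Morlet coefficients over (frequency, time)."""

    coefficients: np.ndarray      # (n_freqs, n_samples) complex
    frequencies_hz: np.ndarray    # ascending
    validity_mask: np.ndarray     # (n_freqs, n_samples) bool, False inside COI
    sample_rate_hz: float
    omega0: float = OMEGA0_DEFAULT

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        f = self.frequencies_hz
        idx = np.flatnonzero((f >= band[0]) & (f <= band[1]))
        if idx.size == 0:
            raise DomainError(
                f"band {band} Hz not covered by grid "
                f"[{f[0]:.4g}, {f[-1]:.4g}] Hz"
            )
        return idx


def morlet_scale_s(frequency_hz: np.ndarray | float,
                   omega0: float = OMEGA0_DEFAULT) -> np.ndarray | float:
    """Morlet scale (seconds) whose Fourier-equivalent frequency is given."""
    return (omega0 + np.sqrt(2.0 + omega0 ** 2)) / (4 * np.pi * np.asarray(frequency_hz))


def frequency_grid(
    f_min: float = GRID_F_MIN_HZ,
    f_max: float = GRID_F_MAX_HZ,
    n_voices: int = N_VOICES_DEFAULT,
) -> np.ndarray:
    """Logarithmic grid, ``n_voices`` frequencies per octave, ascending."""
    if not 0 < f_min < f_max:
        raise DomainError("need 0 < f_min < f_max")
    n_octaves = np.log2(f_max / f_min)
    n = int(np.floor(n_octaves * n_voices)) + 1
    freqs = f_min * 2.0 ** (np.arange(n) / n_voices)
    return freqs[freqs <= f_max * (1 + 1e-12)]


@lru_cache(maxsize=8)
def _morlet_windows(
    npad: int, sample_rate_hz: float, f_min: float, f_max: float,
    n_voices: int, omega0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency-domain Morlet windows, cached across repeated transforms.

    Surrogate ensembles evaluate thousands of transforms on one grid;
    the window matrix depends only on the grid, not the data.
    """
    dt = 1.0 / sample_rate_hz
    freqs = frequency_grid(f_min, f_max, n_voices)
    omega = 2 * np.pi * np.fft.fftfreq(npad, d=dt)  # angular frequencies
    scales = np.asarray(morlet_scale_s(freqs, omega0))  # seconds
    # analytic Morlet in the Fourier domain.  Amplitude normalization: the
    # peak response is 2, so a unit-amplitude in-band tone yields unit
    # coefficient modulus at its ridge regardless of the sampling rate, and
    # WA carries the signal's own units.
    arg = scales[:, None] * omega[None, :] - omega0
    window = 2.0 * np.exp(-0.5 * arg ** 2) * (omega[None, :] > 0)
    for a in (freqs, scales, window):
        a.setflags(write=False)
    return freqs, scales, window


def cwt_morlet(
    series: np.ndarray,
    sample_rate_hz: float,
    f_min: float = GRID_F_MIN_HZ,
    f_max: float = GRID_F_MAX_HZ,
    n_voices: int = N_VOICES_DEFAULT,
    omega0: float = OMEGA0_DEFAULT,
) -> WaveletSpectrum:
    """Continuous Morlet transform of a single series.

    The analytic Morlet window ``ψ̂(sω) ∝ exp(-(sω - ω0)²/2)·1[ω>0]`` is
    applied in the Fourier domain, normalized so a unit in-band tone has
    unit ridge modulus; the coefficient modulus therefore reads as the
    oscillation amplitude in the signal's units.  The series
    is zero-padded to suppress circular wrap-around; the cone of influence
    (e-folding time √2·s at scale s) is returned as a validity mask.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DomainError("cwt_morlet expects a 1-D series")
    n = x.size
    duration = n / sample_rate_hz
    if f_min < 1.0 / duration:
        raise DomainError(
            f"f_min {f_min} Hz below 1/duration ({1.0 / duration:.4g} Hz); "
            "series too short"
        )
    dt = 1.0 / sample_rate_hz
    npad = next_fast_len(2 * n)
    xf = fft(x - x.mean(), npad)
    freqs, scales, window = _morlet_windows(
        npad, sample_rate_hz, f_min, f_max, n_voices, omega0
    )
    coeffs = ifft(xf[None, :] * window, axis=1)[:, :n]

    # cone of influence: e-folding time sqrt(2)*s from each edge
    t = np.arange(n) * dt
    edge_dist = np.minimum(t, t[-1] - t)
    coi = np.sqrt(2.0) * scales
    valid = edge_dist[None, :] >= coi[:, None]
    return WaveletSpectrum(
        coefficients=coeffs,
        frequencies_hz=freqs,
        validity_mask=valid,
        sample_rate_hz=sample_rate_hz,
        omega0=omega0,
    )


def wavelet_amplitude(
    spec: WaveletSpectrum,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    use_coi: bool = True,
    average: str = "time_then_frequency",
) -> float:
    """Band wavelet amplitude: time-averaged |coefficients|, band-averaged.

    With ``use_coi`` the time average at each frequency runs only over
    samples outside the cone of influence.  ``average`` selects the order
    of the two means; the default averages over time first, then over the
    band frequencies (the alternative pools all valid pixels, weighting
    frequencies by their valid-sample counts).
    """
    idx = spec.band_indices(band)
    mod = np.abs(spec.coefficients[idx])
    if use_coi:
        valid = spec.validity_mask[idx]
        counts = valid.sum(axis=1)
        if (counts == 0).any():
            raise DataQualityError(
                "no samples outside the cone of influence at some band "
                "frequencies; series too short for this band"
            )
        if average == "time_then_frequency":
            per_freq = (mod * valid).sum(axis=1) / counts
            return float(per_freq.mean())
        return float(mod[valid].mean())
    if average == "time_then_frequency":
        return float(mod.mean(axis=1).mean())
    return float(mod.mean())


def channel_wa(
    data: np.ndarray,
    sample_rate_hz: float,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    n_voices: int = N_VOICES_DEFAULT,
    omega0: float = OMEGA0_DEFAULT,
    use_coi: bool = True,
) -> np.ndarray:
    """WA of every row of a (channels × samples) array.

    The transform grid is restricted to the requested band (plus its
    edges), which is all the amplitude average consumes.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    out = np.empty(data.shape[0])
    for i, row in enumerate(data):
        spec = cwt_morlet(
            row, sample_rate_hz, f_min=band[0], f_max=band[1],
            n_voices=n_voices, omega0=omega0,
        )
        out[i] = wavelet_amplitude(spec, band=band, use_coi=use_coi)
    return out


def region_wa(
    channel_values: Mapping[str, float],
    region_map: RegionMap,
    aggregator: str = "mean",
) -> dict[str, float]:
    """Aggregate per-channel WA values to the 14 effective regions.

    ``aggregator`` is ``mean`` (activation reporting) or ``sum`` (the
    quantity the lateralization index is built from); the two satisfy
    sum = mean × n_channels per region.
    """
    if aggregator not in ("mean", "sum"):
        raise DomainError(f"aggregator must be 'mean' or 'sum', got {aggregator!r}")
    missing = [ch for ch in region_map.channels if ch not in channel_values]
    if missing:
        raise ConfigurationError(f"missing WA values for channels {missing}")
    out: dict[str, float] = {}
    for region in region_map.effective_regions:
        chans = region_map.channels_in(region)
        if not chans:
            raise ConfigurationError(f"region {region} has no channels in the montage")
        vals = np.array([channel_values[ch] for ch in chans], dtype=float)
        out[region] = float(vals.sum() if aggregator == "sum" else vals.mean())
    return out
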