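"""Wavelet phase coherence (WPCO) with AAFT-surrogate significance.

For two series the instantaneous wavelet phases φx(f, t), φy(f, t) are
taken from their Morlet transforms; at each frequency the coherence is
the resultant length of the phase difference over time,

    R(f) = sqrt(⟨cos Δφ⟩² + ⟨sin Δφ⟩²),   Δφ = φx − φy,

and WPCO is R(f) averaged over the 0.01–0.08 Hz band.  WPCO is 1 when
the phase difference is constant (perfect locking) and near 0 for
unrelated phases.

Because slow narrowband signals produce sizeable coherence by chance,
significance is assessed against amplitude-adjusted Fourier-transform
(AAFT) surrogates: 50 surrogate copies of one series — same value
distribution and approximately the same autocorrelation, but randomized
Fourier phases — are each paired with the untouched partner, and the
observed WPCO is declared significant when it exceeds the surrogate
mean plus two standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft

from .errors import DataQualityError, DomainError
from .montage_io import Recording, RegionMap
from .wavelet_amplitude import (
    ANALYSIS_BAND_HZ,
    N_VOICES_DEFAULT,
    OMEGA0_DEFAULT,
    WaveletSpectrum,
    cwt_morlet,
)

N_SURROGATES_DEFAULT = 50
MIN_VALID_SAMPLES_DEFAULT = 10


# ---------------------------------------------------------------------------
# phases and the WPCO estimator
# ---------------------------------------------------------------------------

def instantaneous_phase(spec: WaveletSpectrum) -> np.ndarray:
    """Wavelet phase in (−π, π]; NaN where the coefficient modulus is 0."""
    coeffs = spec.coefficients
    phase = np.angle(coeffs)
    phase[np.abs(coeffs) == 0] = np.nan
    return phase


def wpco(
    phase_x: np.ndarray,
    phase_y: np.ndarray,
    frequencies_hz: np.ndarray,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    valid_x: np.ndarray | None = None,
    valid_y: np.ndarray | None = None,
    min_valid_samples: int = MIN_VALID_SAMPLES_DEFAULT,
) -> float:
    """Band-averaged phase-difference resultant length, in [0, 1]."""
    phase_x = np.asarray(phase_x)
    phase_y = np.asarray(phase_y)
    if phase_x.shape != phase_y.shape:
        raise DomainError("phase fields must share one (frequency, time) grid")
    f = np.asarray(frequencies_hz)
    sel = np.flatnonzero((f >= band[0]) & (f <= band[1]))
    if sel.size == 0:
        raise DomainError(f"band {band} Hz not covered by the frequency grid")
    valid = np.isfinite(phase_x[sel]) & np.isfinite(phase_y[sel])
    if valid_x is not None:
        valid &= np.asarray(valid_x)[sel]
    if valid_y is not None:
        valid &= np.asarray(valid_y)[sel]
    counts = valid.sum(axis=1)
    if (counts < min_valid_samples).any():
        raise DataQualityError(
            f"fewer than {min_valid_samples} valid samples at some band frequencies"
        )
    dphi = phase_x[sel] - phase_y[sel]
    cos_m = np.where(valid, np.cos(dphi), 0.0).sum(axis=1) / counts
    sin_m = np.where(valid, np.sin(dphi), 0.0).sum(axis=1) / counts
    r = np.hypot(cos_m, sin_m)
    return float(np.clip(r.mean(), 0.0, 1.0))


def wpco_spectra(
    spec_x: WaveletSpectrum,
    spec_y: WaveletSpectrum,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    use_coi: bool = True,
    min_valid_samples: int = MIN_VALID_SAMPLES_DEFAULT,
) -> float:
    """WPCO between two wavelet spectra on the same grid."""
    return wpco(
        instantaneous_phase(spec_x),
        instantaneous_phase(spec_y),
        spec_x.frequencies_hz,
        band=band,
        valid_x=spec_x.validity_mask if use_coi else None,
        valid_y=spec_y.validity_mask if use_coi else None,
        min_valid_samples=min_valid_samples,
    )


def wpco_series(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate_hz: float,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    n_voices: int = N_VOICES_DEFAULT,
    omega0: float = OMEGA0_DEFAULT,
    use_coi: bool = True,
) -> float:
    """WPCO of two raw series (transforms computed on the analysis band)."""
    sx = cwt_morlet(x, sample_rate_hz, f_min=band[0], f_max=band[1],
                    n_voices=n_voices, omega0=omega0)
    sy = cwt_morlet(y, sample_rate_hz, f_min=band[0], f_max=band[1],
                    n_voices=n_voices, omega0=omega0)
    return wpco_spectra(sx, sy, band=band, use_coi=use_coi)


# ---------------------------------------------------------------------------
# AAFT surrogates
# ---------------------------------------------------------------------------

def aaft_surrogate(
    series: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate of a series.

    (i) a Gaussian sample is reordered to the ranks of the input,
    (ii) its Fourier phases are randomized, (iii) the original sample
    values are reassigned by the ranks of the phase-randomized series.
    The surrogate therefore has exactly the original's sorted values and
    approximately its power spectrum, but no phase relation to any
    partner series.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise DomainError("AAFT needs a 1-D series of at least 64 samples")
    if not np.isfinite(x).all():
        raise DomainError("AAFT needs finite input")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = x.size
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    gauss = np.sort(rng.standard_normal(n))[ranks]

    spec = rfft(gauss)
    phases = rng.uniform(0.0, 2 * np.pi, spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # keep the Nyquist bin real
    randomized = irfft(np.abs(spec) * np.exp(1j * phases), n)

    out_ranks = np.argsort(np.argsort(randomized, kind="stable"), kind="stable")
    return np.sort(x)[out_ranks]


@dataclass
class SurrogateEnsemble:
    """WPCO values of an AAFT surrogate ensemble plus its summary."""

    n: int
    seed: int
    values: np.ndarray
    method: str = "AAFT"

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def threshold(self) -> float:
        """Significance threshold: surrogate mean + 2 SD."""
        return self.mean + 2.0 * self.sd


@dataclass
class SignificanceResult:
    wpco: float
    threshold: float | None
    significant: bool | None   # None when the test is inapplicable
    ensemble: SurrogateEnsemble | None
    applicable: bool = True
    reason: str = ""


def significance_test(
    series_x: np.ndarray,
    series_y: np.ndarray,
    sample_rate_hz: float,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    seed: int = 0,
    n_voices: int = N_VOICES_DEFAULT,
    omega0: float = OMEGA0_DEFAULT,
    both_sided: bool = False,
) -> SignificanceResult:
    """Mean+2SD surrogate test of the WPCO between two series.

    Surrogates replace ``series_x`` while ``series_y`` stays original
    (with ``both_sided`` each surrogate pair replaces both).  For a
    constant input the surrogate spread is degenerate and the test is
    reported as inapplicable instead of returning a flag.
    """
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SignificanceResult(
            wpco=np.nan, threshold=None, significant=None, ensemble=None,
            applicable=False, reason="constant input series",
        )
    rng = np.random.default_rng(seed)
    spec_y = cwt_morlet(y, sample_rate_hz, f_min=band[0], f_max=band[1],
                        n_voices=n_voices, omega0=omega0)
    phase_y = instantaneous_phase(spec_y)
    spec_x = cwt_morlet(x, sample_rate_hz, f_min=band[0], f_max=band[1],
                        n_voices=n_voices, omega0=omega0)
    observed = wpco_spectra(spec_x, spec_y, band=band)

    values = np.empty(n_surrogates)
    for i in range(n_surrogates):
        sx = aaft_surrogate(x, rng)
        ssx = cwt_morlet(sx, sample_rate_hz, f_min=band[0], f_max=band[1],
                         n_voices=n_voices, omega0=omega0)
        if both_sided:
            sy = aaft_surrogate(y, rng)
            ssy = cwt_morlet(sy, sample_rate_hz, f_min=band[0], f_max=band[1],
                             n_voices=n_voices, omega0=omega0)
            values[i] = wpco_spectra(ssx, ssy, band=band)
        else:
            values[i] = wpco(
                instantaneous_phase(ssx), phase_y, ssx.frequencies_hz,
                band=band, valid_x=ssx.validity_mask,
                valid_y=spec_y.validity_mask,
            )
    ensemble = SurrogateEnsemble(n=n_surrogates, seed=seed, values=values)
    if ensemble.sd == 0:
        return SignificanceResult(
            wpco=observed, threshold=None, significant=None, ensemble=ensemble,
            applicable=False, reason="degenerate surrogate spread",
        )
    return SignificanceResult(
        wpco=observed,
        threshold=ensemble.threshold,
        significant=bool(observed > ensemble.threshold),
        ensemble=ensemble,
    )


# ---------------------------------------------------------------------------
# region-level connectivity
# ---------------------------------------------------------------------------

@dataclass
class WPCOMatrix:
    """Symmetric region × region WPCO matrix with surrogate statistics."""

    regions: tuple[str, ...]
    values: np.ndarray            # (n, n), unit diagonal
    surrogate_mean: np.ndarray    # NaN where no test was run
    surrogate_sd: np.ndarray
    threshold: np.ndarray
    significant: np.ndarray       # boolean; False on diagonal / untested
    state: str = ""
    chromophore: str = ""

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.regions)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "region_a": self.regions[i],
                        "region_b": self.regions[j],
                        "wpco": self.values[i, j],
                        "threshold": self.threshold[i, j],
                        "significant": bool(self.significant[i, j]),
                        "state": self.state,
                        "chromophore": self.chromophore,
                    }
                )
        return pd.DataFrame(rows)


def region_signals(
    rec: Recording, region_map: RegionMap, chromophore: str, state: str
) -> dict[str, np.ndarray]:
    """Per-region series: mean over the region's channels, state-sliced."""
    sl = rec.state_slice(state)
    data = rec.series(chromophore)
    idx = {ch: k for k, ch in enumerate(rec.channel_names)}
    out = {}
    for region in region_map.effective_regions:
        rows = [idx[ch] for ch in region_map.channels_in(region)]
        out[region] = data[rows, sl].mean(axis=0)
    return out


def connectivity_map(
    rec: Recording,
    region_map: RegionMap,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    chromophore: str = "o2hb",
    state: str = "rest",
    n_surrogates: int = N_SURROGATES_DEFAULT,
    seed: int = 0,
    n_voices: int = N_VOICES_DEFAULT,
    omega0: float = OMEGA0_DEFAULT,
    test_significance: bool = True,
) -> WPCOMatrix:
    """All-pairs region WPCO for one state and chromophore.

    Region signals are channel means of the (already preprocessed)
    recording.  For each unordered pair the first region's signal is
    surrogate-replaced ``n_surrogates`` times; surrogate transforms are
    computed once per first region and reused across its partners.  A
    region whose transform fails the quality checks has its row and
    column marked missing (NaN).
    """
    regions = region_map.effective_regions
    sigs = region_signals(rec, region_map, chromophore, state)
    rng = np.random.default_rng(seed)

    specs: dict[str, WaveletSpectrum | None] = {}
    phases: dict[str, np.ndarray] = {}
    for r in regions:
        try:
            spec = cwt_morlet(sigs[r], rec.sample_rate_hz, f_min=band[0],
                              f_max=band[1], n_voices=n_voices, omega0=omega0)
            specs[r] = spec
            phases[r] = instantaneous_phase(spec)
        except (DomainError, DataQualityError):
            specs[r] = None

    n = len(regions)
    values = np.full((n, n), np.nan)
    s_mean = np.full((n, n), np.nan)
    s_sd = np.full((n, n), np.nan)
    thresh = np.full((n, n), np.nan)
    signif = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(values, 1.0)

    for i, ra in enumerate(regions):
        if specs[ra] is None:
            continue
        spec_a = specs[ra]
        partners = [
            j for j in range(i + 1, n) if specs[regions[j]] is not None
        ]
        if not partners:
            continue
        surrogate_phases: list[tuple[np.ndarray, np.ndarray]] = []
        if test_significance:
            for _ in range(n_surrogates):
                sx = aaft_surrogate(sigs[ra], rng)
                ssx = cwt_morlet(sx, rec.sample_rate_hz, f_min=band[0],
                                 f_max=band[1], n_voices=n_voices, omega0=omega0)
                surrogate_phases.append(
                    (instantaneous_phase(ssx), ssx.validity_mask)
                )
        for j in partners:
            rb = regions[j]
            spec_b = specs[rb]
            try:
                obs = wpco_spectra(spec_a, spec_b, band=band)
            except DataQualityError:
                continue
            values[i, j] = values[j, i] = obs
            if not test_significance:
                continue
            surr = np.array([
                wpco(
                    ph, phases[rb], spec_a.frequencies_hz, band=band,
                    valid_x=vm, valid_y=spec_b.validity_mask,
                )
                for ph, vm in surrogate_phases
            ])
            mu, sd = surr.mean(), surr.std(ddof=1)
            s_mean[i, j] = s_mean[j, i] = mu
            s_sd[i, j] = s_sd[j, i] = sd
            if sd > 0:
                t = mu + 2.0 * sd
                thresh[i, j] = thresh[j, i] = t
                signif[i, j] = signif[j, i] = obs > t
    return WPCOMatrix(
        regions=regions, values=values, surrogate_mean=s_mean,
        surrogate_sd=s_sd, threshold=thresh, significant=signif,
        state=state, chromophore=chromophore,
    )
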