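"""Hemodynamic-signal preprocessing.

The cleaning chain mirrors standard continuous-wave fNIRS practice:

1. optional modified Beer–Lambert (MBLL) conversion of dual-wavelength
   optical-density changes to ΔO2Hb/ΔHHb concentration changes;
2. zero-phase Butterworth bandpass (default 0.0095–2 Hz, overall order 6)
   to remove baseline drift and out-of-band noise;
3. PCA+ICA decomposition with an automated retention criterion: a
   component is kept iff the fraction of its spectral power inside the
   neural band (0.01–0.08 Hz) reaches a threshold, replacing the visual
   component inspection used with real recordings; a manual-override
   list allows forced rejection and every decision is logged in a
   :class:`ComponentReport`;
4. motion-artifact detection against a centered 3-s moving average with
   a robust (MAD-scaled) threshold, and cubic-spline repair of the
   flagged spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation, uniform_filter1d
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import ConfigurationError, DataQualityError, PreprocessingError

NEURAL_BAND_HZ = (0.01, 0.08)

# Hemoglobin extinction coefficients, mM^-1 cm^-1 (Gratzer/Cope tabulation),
# rows = wavelength (740, 850 nm), cols = (O2Hb, HHb).  Overridable.
DEFAULT_EXTINCTION = {
    740.0: (0.446, 1.1159),
    850.0: (1.058, 0.6913),
}
DEFAULT_DPF = {740.0: 6.0, 850.0: 6.0}


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass description; ``order`` is the overall filter order."""

    low_hz: float = 0.0095
    high_hz: float = 2.0
    order: int = 6
    zero_phase: bool = True

    def validate(self, sample_rate_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz < sample_rate_hz / 2:
            raise ConfigurationError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < "
                f"Nyquist ({sample_rate_hz / 2})"
            )
        if self.order < 2 or self.order % 2:
            raise ConfigurationError("bandpass order must be even and >= 2")


@dataclass(frozen=True)
class ComponentInfo:
    index: int
    band_fraction: float
    retained: bool
    reason: str  # "auto" or "manual"


@dataclass
class ComponentReport:
    """Audit trail of the PCA/ICA component selection."""

    components: list[ComponentInfo] = field(default_factory=list)
    method: str = "ica"  # "ica" or "pca" when ICA failed to converge
    converged: bool = True

    @property
    def retained_indices(self) -> list[int]:
        return [c.index for c in self.components if c.retained]


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------

def mbll_convert(
    od_740: np.ndarray,
    od_850: np.ndarray,
    separation_mm: float = 30.0,
    dpf: dict[float, float] | None = None,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert optical-density changes at 740/850 nm to (ΔO2Hb, ΔHHb) in µM.

    Solves the 2×2 modified Beer–Lambert system
    ``ΔOD(λ) = [ε_O2Hb(λ)·ΔO2Hb + ε_HHb(λ)·ΔHHb] · d · DPF(λ)``
    with the source–detector distance ``d`` in cm.  Linear in its inputs.
    """
    od_740 = np.asarray(od_740, dtype=float)
    od_850 = np.asarray(od_850, dtype=float)
    if od_740.shape != od_850.shape:
        raise PreprocessingError("optical-density series must have equal shapes")
    dpf = DEFAULT_DPF if dpf is None else dpf
    ext = DEFAULT_EXTINCTION if extinction is None else extinction
    if separation_mm <= 0 or any(v <= 0 for v in dpf.values()):
        raise ConfigurationError("separation and DPF must be positive")
    d_cm = separation_mm / 10.0
    wavelengths = sorted(ext)
    a = np.array(
        [[e * d_cm * dpf[wl] for e in ext[wl]] for wl in wavelengths]
    )  # (2, 2): rows wavelengths, cols (O2Hb, HHb)
    if abs(np.linalg.det(a)) < 1e-12:
        raise ConfigurationError("extinction system is singular; check coefficients")
    sol = np.linalg.solve(a, np.stack([od_740.ravel(), od_850.ravel()]))
    shape = od_740.shape
    # mM → µM
    return sol[0].reshape(shape) * 1e3, sol[1].reshape(shape) * 1e3


def mbll_forward(
    o2hb_um: np.ndarray,
    hhb_um: np.ndarray,
    separation_mm: float = 30.0,
    dpf: dict[float, float] | None = None,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer–Lambert model: concentrations (µM) → ΔOD at 740/850 nm."""
    dpf = DEFAULT_DPF if dpf is None else dpf
    ext = DEFAULT_EXTINCTION if extinction is None else extinction
    d_cm = separation_mm / 10.0
    conc_mm = np.stack([np.asarray(o2hb_um) / 1e3, np.asarray(hhb_um) / 1e3])
    wavelengths = sorted(ext)
    a = np.array([[e * d_cm * dpf[wl] for e in ext[wl]] for wl in wavelengths])
    od = np.tensordot(a, conc_mm, axes=(1, 0))
    return od[0], od[1]


# ---------------------------------------------------------------------------
# bandpass
# ---------------------------------------------------------------------------

def bandpass(
    series: np.ndarray,
    sample_rate_hz: float,
    spec: FilterSpec | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis."""
    spec = spec or FilterSpec()
    spec.validate(sample_rate_hz)
    x = np.asarray(series, dtype=float)
    sos = signal.butter(
        spec.order // 2,
        [spec.low_hz, spec.high_hz],
        btype="band",
        fs=sample_rate_hz,
        output="sos",
    )
    # padlen as used by sosfiltfilt's default padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= 3 * padlen:
        raise PreprocessingError(
            f"series of {x.shape[-1]} samples too short for stable order-"
            f"{spec.order} zero-phase filtering"
        )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# PCA / ICA denoising
# ---------------------------------------------------------------------------

def _band_power_fraction(
    source: np.ndarray, sample_rate_hz: float, band: tuple[float, float]
) -> float:
    nperseg = min(source.size, 4096)
    freqs, psd = signal.welch(source, fs=sample_rate_hz, nperseg=nperseg)
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        return 0.0
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]) / total)


def pca_ica_denoise(
    multichannel: np.ndarray,
    sample_rate_hz: float,
    band: tuple[float, float] = NEURAL_BAND_HZ,
    retain_fraction_threshold: float = 0.5,
    manual_overrides: list[int] | None = None,
    seed: int = 0,
    variance_to_keep: float = 0.99,
) -> tuple[np.ndarray, ComponentReport]:
    """Remove components without substantial neural-band (0.01–0.08 Hz) power.

    Channels are decomposed with PCA (rank chosen to retain
    ``variance_to_keep`` of the variance) followed by FastICA.  Components
    whose neural-band power fraction is below ``retain_fraction_threshold``
    are dropped, as are any listed in ``manual_overrides``; the cleaned
    channels are reconstructed from the remaining components.  If ICA does
    not converge the selection falls back to the PCA basis and the report
    says so.
    """
    x = np.asarray(multichannel, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise PreprocessingError("need a (channels >= 2, samples) array")
    if not np.isfinite(x).all():
        raise PreprocessingError("non-finite samples; repair before denoising")
    overrides = set(manual_overrides or [])

    xt = x.T  # samples × channels
    pca = PCA(n_components=variance_to_keep, svd_solver="full")
    scores = pca.fit_transform(xt)
    n_comp = scores.shape[1]

    report = ComponentReport()
    sources: np.ndarray
    mixing: np.ndarray
    mean = pca.mean_
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            ica = FastICA(
                n_components=n_comp, random_state=seed, whiten="unit-variance",
                max_iter=1000,
            )
            sources = ica.fit_transform(xt)
            mixing = ica.mixing_
            mean = ica.mean_
    except (ConvergenceWarning, ValueError):
        converged = False
        sources = scores
        mixing = pca.components_.T  # orthonormal, so inverse == transpose
    report.method = "ica" if converged else "pca"
    report.converged = converged

    keep = np.ones(sources.shape[1], dtype=bool)
    for j in range(sources.shape[1]):
        frac = _band_power_fraction(sources[:, j], sample_rate_hz, band)
        if j in overrides:
            retained, reason = False, "manual"
        else:
            retained, reason = frac >= retain_fraction_threshold, "auto"
        keep[j] = retained
        report.components.append(ComponentInfo(j, frac, retained, reason))

    kept_sources = sources * keep[np.newaxis, :]
    cleaned = kept_sources @ mixing.T + mean
    return cleaned.T, report


# ---------------------------------------------------------------------------
# despiking and repair
# ---------------------------------------------------------------------------

def despike_moving_average(
    series: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 3.0,
    k: float = 5.0,
    dilate_samples: int = 2,
) -> np.ndarray:
    """Flag samples deviating from a centered moving average by > k robust SDs.

    The deviation scale is 1.4826×MAD of the residual, so isolated spikes do
    not inflate their own threshold.  The returned boolean mask has the same
    length as the series; flagged spans are slightly dilated to cover spike
    shoulders.
    """
    x = np.asarray(series, dtype=float)
    win = int(round(window_s * sample_rate_hz))
    if win < 3:
        raise PreprocessingError("moving-average window must span >= 3 samples")
    ma = uniform_filter1d(x, size=win, mode="nearest")
    resid = x - ma
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma == 0:
        sigma = resid.std()
    if sigma == 0:
        return np.zeros_like(x, dtype=bool)
    mask = np.abs(resid) > k * sigma
    if dilate_samples > 0 and mask.any():
        mask = binary_dilation(mask, iterations=dilate_samples)
    return mask


def spline_repair(
    series: np.ndarray,
    mask: np.ndarray,
    max_masked_fraction: float = 0.5,
) -> np.ndarray:
    """Replace masked interior spans by cubic-spline interpolation.

    Unmasked samples pass through unchanged.  Spans touching either edge
    cannot be bracketed by valid neighbours, so they are held at the
    nearest valid value instead of splined.
    """
    x = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise PreprocessingError("mask and series shapes differ")
    if not mask.any():
        return x.copy()
    frac = mask.mean()
    if frac > max_masked_fraction:
        raise DataQualityError(
            f"{frac:.0%} of samples flagged exceeds the {max_masked_fraction:.0%} limit"
        )
    valid = ~mask
    if valid.sum() < 4:
        raise DataQualityError("too few valid samples for cubic-spline repair")
    idx = np.arange(x.size)
    out = x.copy()
    first_valid, last_valid = idx[valid][0], idx[valid][-1]
    interior = mask & (idx > first_valid) & (idx < last_valid)
    if interior.any():
        cs = CubicSpline(idx[valid], x[valid])
        out[interior] = cs(idx[interior])
    # edge spans: constant extension of the nearest valid sample
    out[: first_valid][mask[: first_valid]] = x[first_valid]
    out[last_valid + 1:][mask[last_valid + 1:]] = x[last_valid]
    return out


def despike_and_repair(
    series: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 3.0,
    k: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: detect artifacts and spline-repair them in one call."""
    mask = despike_moving_average(series, sample_rate_hz, window_s=window_s, k=k)
    return spline_repair(series, mask), mask
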