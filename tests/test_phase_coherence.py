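"""Wavelet phase estimation, WPCO estimator behavior and surrogate tests."""

import numpy as np
import pytest
from scipy.signal import periodogram

from nirswave.errors import DomainError
from nirswave.montage_io import remap_hemispheres
from nirswave.phase_coherence import (
    aaft_surrogate,
    connectivity_map,
    instantaneous_phase,
    significance_test,
    wpco,
    wpco_series,
)
from nirswave.synthetic_data import (
    SyntheticConfig,
    _analytic_narrowband,
    _jitter_phase,
    generate_subject,
)
from nirswave.wavelet_amplitude import cwt_morlet

from conftest import FS, quiet_config, tone

BAND = (0.01, 0.08)


def narrowband(seed, n=6000):
    return _analytic_narrowband(np.random.default_rng(seed), n, FS, BAND).real.copy()


def jittered_pair(seed, kappa, n=6000):
    rng = np.random.default_rng(seed)
    z = _analytic_narrowband(rng, n, FS, BAND)
    theta = _jitter_phase(rng, n, FS, kappa, 15.0)
    return z.real.copy(), (z * np.exp(1j * theta)).real.copy()


class TestPhase:
    def test_tone_phase_slope(self):
        f0 = 0.04
        spec = cwt_morlet(tone(f0), FS, *BAND)
        i = np.argmin(np.abs(spec.frequencies_hz - f0))
        phase = instantaneous_phase(spec)[i]
        valid = spec.validity_mask[i]
        slope = np.polyfit(
            np.arange(valid.sum()) / FS, np.unwrap(phase[valid]), 1
        )[0]
        assert slope == pytest.approx(2 * np.pi * f0, rel=0.02)

    def test_quarter_period_shift(self):
        f0 = 0.04
        n_shift = int(round(1 / (4 * f0) * FS))
        t = np.arange(6000 + n_shift) / FS
        x = np.sin(2 * np.pi * f0 * t)
        a, b = x[:-n_shift] if n_shift else x, x[n_shift:]
        sa = cwt_morlet(a, FS, *BAND)
        sb = cwt_morlet(b, FS, *BAND)
        i = np.argmin(np.abs(sa.frequencies_hz - f0))
        valid = sa.validity_mask[i] & sb.validity_mask[i]
        dphi = np.angle(np.exp(1j * (
            instantaneous_phase(sa)[i, valid] - instantaneous_phase(sb)[i, valid]
        )))
        assert np.median(np.abs(dphi)) == pytest.approx(np.pi / 2, rel=0.05)

    def test_zero_series_invalid(self):
        spec = cwt_morlet(np.zeros(6000), FS, *BAND)
        assert np.isnan(instantaneous_phase(spec)).all()


class TestWpcoEstimator:
    def test_self_coherence_is_one(self):
        x = narrowband(0)
        assert wpco_series(x, x, FS) == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_shift_is_one(self):
        n = 6000
        z = _analytic_narrowband(np.random.default_rng(1), n, FS, BAND)
        a = z.real.copy()
        b = (z * np.exp(1j * 0.7)).real.copy()
        assert wpco_series(a, b, FS) > 0.99

    def test_symmetry(self):
        x, y = narrowband(2), narrowband(3)
        assert wpco_series(x, y, FS) == pytest.approx(wpco_series(y, x, FS),
                                                      abs=1e-12)

    def test_amplitude_invariance(self):
        x, y = narrowband(4), narrowband(5)
        assert wpco_series(5 * x, 0.1 * y, FS) == pytest.approx(
            wpco_series(x, y, FS), abs=1e-9
        )

    def test_monotone_in_coupling_concentration(self):
        values = []
        for kappa in (0.5, 2.0, 8.0):
            a, b = jittered_pair(29, kappa)
            values.append(wpco_series(a, b, FS))
        assert values[0] < values[1] < values[2]

    def test_band_must_be_covered(self):
        x = narrowband(6)
        spec = cwt_morlet(x, FS, *BAND)
        ph = instantaneous_phase(spec)
        with pytest.raises(DomainError):
            wpco(ph, ph, spec.frequencies_hz, band=(0.5, 1.0))


class TestAaft:
    def test_values_preserved_exactly(self):
        x = narrowband(7)
        s = aaft_surrogate(x, seed=0)
        np.testing.assert_array_equal(np.sort(s), np.sort(x))
        assert s.mean() == pytest.approx(x.mean())
        assert s.std() == pytest.approx(x.std())

    def test_spectrum_preserved_on_ar1(self):
        rng = np.random.default_rng(8)
        n = 4096
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = 0.95 * x[i - 1] + rng.standard_normal()
        s = aaft_surrogate(x, seed=1)
        _, px = periodogram(x)
        _, ps = periodogram(s)
        corr = np.corrcoef(np.log(px[1:]), np.log(ps[1:]))[0, 1]
        assert corr > 0.8

    def test_surrogate_differs_from_original(self):
        x = narrowband(9)
        s = aaft_surrogate(x, seed=2)
        assert not np.array_equal(s, x)

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            aaft_surrogate(np.arange(10.0), seed=0)


class TestSignificance:
    def test_phase_locked_pair_significant(self):
        a, b = jittered_pair(10, kappa=8.0)
        res = significance_test(a, b, FS, seed=0)
        assert res.applicable and res.significant
        assert res.ensemble.n == 50  # default ensemble size
        # surrogate destruction: the null level sits well below the observed
        assert res.ensemble.mean < 0.7 * res.wpco

    def test_independent_pair_not_significant(self):
        res = significance_test(narrowband(11), narrowband(12), FS, seed=0)
        assert res.applicable and not res.significant

    def test_constant_series_inapplicable(self):
        res = significance_test(np.ones(6000), narrowband(13), FS, seed=0)
        assert not res.applicable
        assert res.significant is None

    def test_deterministic_in_seed(self):
        a, b = jittered_pair(14, kappa=2.0)
        r1 = significance_test(a, b, FS, seed=5, n_surrogates=10)
        r2 = significance_test(a, b, FS, seed=5, n_surrogates=10)
        np.testing.assert_array_equal(r1.ensemble.values, r2.ensemble.values)


class TestConnectivityMap:
    def test_identical_channels_full_coherence(self, montage):
        layout, rmap = montage
        cfg = quiet_config(seed=20)
        rec, _ = generate_subject(cfg, 0)
        common = rec.o2hb[0]
        rec.o2hb[:] = common
        emap = remap_hemispheres(rmap, rec.meta.lesion_side)
        m = connectivity_map(rec, emap, state="rest", test_significance=False)
        off = m.values[~np.eye(14, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-9)
        np.testing.assert_array_equal(np.diag(m.values), 1.0)

    def test_single_coupled_pair_recovered(self, montage):
        layout, rmap = montage
        cfg = quiet_config(
            coupling=[("ISFC", "CM1", 8.0)], channel_noise_level=0.02, seed=21
        )
        rec, _ = generate_subject(cfg, 0)
        emap = remap_hemispheres(rmap, rec.meta.lesion_side)
        m = connectivity_map(
            rec, emap, state="rest", n_surrogates=50, seed=3, n_voices=8
        )
        i = m.regions.index("ISFC")
        j = m.regions.index("CM1")
        assert m.significant[i, j]
        edges = m.to_edge_list()
        false_edges = edges[
            edges.significant
            & ~((edges.region_a == "ISFC") & (edges.region_b == "CM1"))
            & ~((edges.region_a == "CM1") & (edges.region_b == "ISFC"))
        ]
        # at most a small number of chance edges among the 90 null pairs
        assert len(false_edges) <= 9

    def test_matrix_symmetry(self, montage):
        layout, rmap = montage
        cfg = quiet_config(channel_noise_level=0.02, seed=22)
        rec, _ = generate_subject(cfg, 0)
        emap = remap_hemispheres(rmap, rec.meta.lesion_side)
        m = connectivity_map(rec, emap, state="rest", test_significance=False)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
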