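"""Graph Fourier transform, spectral filtering, and the decoupling index."""

import numpy as np
import pytest

from neurogsp.gsp import (
    GraphCoefficients,
    GraphPsd,
    RegionTimeSeries,
    SdiMap,
    ZeroNormWarning,
    compute_sdi,
    decile_bin_maps,
    gft,
    graph_filter_split,
    graph_psd,
    igft,
    median_split_cutoff,
    sdi_pipeline,
    temporal_fluctuation,
    time_resolved_sdi,
)
from neurogsp.graph import GraphSpectrum
from neurogsp.synthetic import SynthSpec, expected_sdi, make_connectome, make_graph_signal, _mode_sds


def _ts(values, fs=32.0):
    return RegionTimeSeries(values=values, sampling_rate=fs)


class TestTransforms:
    def test_eigenvector_signal_maps_to_basis_coefficient(self, small_spectrum):
        k = 3
        sig = _ts(small_spectrum.eigenvectors[:, [k]])
        coeffs = gft(small_spectrum, sig).values
        expected = np.zeros((small_spectrum.n_modes, 1))
        expected[k] = 1.0
        assert np.allclose(coeffs, expected, atol=1e-12)

    def test_zero_signal_zero_coefficients(self, small_spectrum):
        n = small_spectrum.n_modes
        assert np.allclose(gft(small_spectrum, _ts(np.zeros((n, 4)))).values, 0.0)

    def test_round_trip_identity(self, small_spectrum, random_signal):
        back = igft(small_spectrum, gft(small_spectrum, random_signal), random_signal)
        assert np.allclose(back.values, random_signal.values, atol=1e-10)

    def test_parseval_per_sample(self, small_spectrum, random_signal):
        coeffs = gft(small_spectrum, random_signal)
        assert np.allclose(
            np.linalg.norm(coeffs.values, axis=0),
            np.linalg.norm(random_signal.values, axis=0),
            atol=1e-8,
        )

    def test_dimension_mismatch(self, small_spectrum):
        with pytest.raises(ValueError, match="modes"):
            gft(small_spectrum, _ts(np.zeros((small_spectrum.n_modes + 1, 3))))


class TestGraphPsd:
    def test_single_mode_power(self):
        coeffs = GraphCoefficients(np.array([[1.0, 1.0], [0.0, 0.0], [0.0, 0.0]]))
        assert np.allclose(graph_psd(coeffs).power, [1.0, 0.0, 0.0])

    def test_white_coefficients_flat_psd(self, rng):
        coeffs = GraphCoefficients(rng.standard_normal((8, 10_000)))
        power = graph_psd(coeffs).power
        assert np.all(np.abs(power - 1.0) < 0.05)

    def test_scaling_homogeneity(self, rng):
        coeffs = GraphCoefficients(rng.standard_normal((5, 50)))
        doubled = GraphCoefficients(2 * coeffs.values)
        assert np.allclose(graph_psd(doubled).power, 4 * graph_psd(coeffs).power)
        assert np.allclose(
            graph_psd(doubled, normalize=True).power,
            graph_psd(coeffs, normalize=True).power,
        )

    def test_total_power_is_total_energy_rate(self, rng):
        vals = rng.standard_normal((6, 40))
        psd = graph_psd(GraphCoefficients(vals))
        assert np.isclose(psd.power.sum(), np.mean(np.sum(vals**2, axis=0)))


class TestMedianSplitCutoff:
    def test_flat_psd_halves(self):
        assert median_split_cutoff(GraphPsd(np.full(4, 0.25))) == 2

    def test_dominant_first_mode(self):
        assert median_split_cutoff(GraphPsd(np.array([0.9, 0.05, 0.03, 0.02]))) == 1

    def test_clipping_keeps_both_halves_nonempty(self):
        # all power in the last mode: raw rule gives C = N, clipped to N-1
        assert median_split_cutoff(GraphPsd(np.array([0.0, 0.0, 1.0]))) == 2

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            median_split_cutoff(GraphPsd(np.zeros(4)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            power = rng.random(rng.integers(2, 40))
            half = power.sum() / 2
            brute = next(
                c for c in range(1, len(power) + 1) if power[:c].sum() >= half
            )
            brute = min(max(brute, 1), len(power) - 1)
            assert median_split_cutoff(GraphPsd(power)) == brute


class TestFilterSplit:
    def test_smoothest_mode_is_fully_coupled(self, small_spectrum):
        sig = _ts(small_spectrum.eigenvectors[:, [0]])
        low, high = graph_filter_split(small_spectrum, sig, 1)
        assert np.allclose(low.values, sig.values, atol=1e-10)
        assert np.allclose(high.values, 0.0, atol=1e-10)

    def test_roughest_mode_is_fully_decoupled(self, small_spectrum):
        sig = _ts(small_spectrum.eigenvectors[:, [-1]])
        low, high = graph_filter_split(small_spectrum, sig, 1)
        assert np.allclose(high.values, sig.values, atol=1e-10)
        assert np.allclose(low.values, 0.0, atol=1e-10)

    @pytest.mark.parametrize("cutoff", [1, 5, 15])
    def test_additive_split_and_energy_partition(self, small_spectrum, random_signal, cutoff):
        low, high = graph_filter_split(small_spectrum, random_signal, cutoff)
        assert np.allclose(low.values + high.values, random_signal.values, atol=1e-10)
        e_low = np.sum(low.values**2)
        e_high = np.sum(high.values**2)
        assert np.isclose(e_low + e_high, np.sum(random_signal.values**2), atol=1e-8)
        # oracle: energies from direct per-mode projection sums
        coeffs = gft(small_spectrum, random_signal).values
        assert np.isclose(e_low, np.sum(coeffs[:cutoff] ** 2), atol=1e-8)

    def test_cutoff_out_of_range(self, small_spectrum, random_signal):
        n = small_spectrum.n_modes
        for bad in (0, n):
            with pytest.raises(ValueError, match="cutoff"):
                graph_filter_split(small_spectrum, random_signal, bad)


class TestComputeSdi:
    def test_equal_norms_give_zero(self):
        a = _ts(np.ones((3, 4)))
        assert np.allclose(compute_sdi(a, a, 1).sdi, 0.0)

    def test_doubled_decoupled_gives_one(self):
        a = _ts(np.ones((3, 4)))
        b = _ts(2 * np.ones((3, 4)))
        assert np.allclose(compute_sdi(a, b, 1).sdi, 1.0)

    def test_swap_antisymmetry(self, rng):
        a, b = _ts(rng.standard_normal((5, 20))), _ts(rng.standard_normal((5, 20)))
        assert np.allclose(compute_sdi(a, b, 2).sdi, -compute_sdi(b, a, 2).sdi)

    def test_zero_norm_flagged_not_inflated(self):
        coupled = _ts(np.vstack([np.zeros(4), np.ones(4)]))
        decoupled = _ts(np.ones((2, 4)))
        with pytest.warns(ZeroNormWarning):
            m = compute_sdi(coupled, decoupled, 1)
        assert np.isposinf(m.sdi[0]) and np.isfinite(m.sdi[1])


class TestSdiPipeline:
    def test_pure_low_mode_signal_strongly_coupled(self, small_connectome, small_spectrum):
        # energy only on the smoothest harmonic -> the decoupled part is
        # pure float residue, so the log-ratio is hugely negative
        values = small_spectrum.eigenvectors[:, [0]] @ np.ones((1, 16))
        m = sdi_pipeline(small_connectome, _ts(values))
        assert np.all((m.sdi < -20) | np.isneginf(m.sdi))

    def test_deterministic(self, small_connectome, random_signal):
        a = sdi_pipeline(small_connectome, random_signal)
        b = sdi_pipeline(small_connectome, random_signal)
        assert np.array_equal(a.sdi, b.sdi) and a.cutoff_C == b.cutoff_C

    def test_scale_and_sign_flip_invariance(self, small_connectome, random_signal):
        base = sdi_pipeline(small_connectome, random_signal)
        scaled = sdi_pipeline(
            small_connectome, random_signal.replace_values(3.7 * random_signal.values)
        )
        flipped = sdi_pipeline(
            small_connectome, random_signal.replace_values(-random_signal.values)
        )
        assert np.allclose(base.sdi, scaled.sdi, atol=1e-10)
        assert np.allclose(base.sdi, flipped.sdi, atol=1e-10)

    def test_matches_analytic_expectation_at_large_t(self):
        """The l1-norm log-ratio converges to the closed-form Gaussian value."""
        conn = make_connectome(24, density=0.5, seed=11)
        from neurogsp.graph import eigendecompose, normalized_laplacian
        spectrum = eigendecompose(normalized_laplacian(conn))
        spec = SynthSpec(n_regions=24, duration_s=160.0, ar_coeff=0.0, seed=5)
        ts, truth = make_graph_signal(spectrum, spec, rng=5)
        m = sdi_pipeline(conn, ts)
        assert m.cutoff_C == truth["background_cutoff"].iloc[0]
        sds = _mode_sds(spec, 24)
        analytic = expected_sdi(spectrum, sds, m.cutoff_C)
        assert np.max(np.abs(m.sdi - analytic)) < 0.25
        assert np.mean(np.abs(m.sdi - analytic)) < 0.08


class TestTimeResolved:
    def test_single_window_equals_static(self, small_connectome, random_signal):
        fs = random_signal.sampling_rate
        window_s = random_signal.n_samples / fs
        tr = time_resolved_sdi(small_connectome, random_signal, window_s)
        static = sdi_pipeline(small_connectome, random_signal)
        assert tr.n_windows == 1
        assert np.allclose(tr.sdi[:, 0], static.sdi)
        assert tr.per_window_cutoffs[0] == static.cutoff_C

    def test_stationary_signal_windows_hover_around_static(self, small_connectome):
        from neurogsp.graph import eigendecompose, normalized_laplacian
        spectrum = eigendecompose(normalized_laplacian(small_connectome))
        spec = SynthSpec(n_regions=16, duration_s=40.0, sampling_rate=32.0,
                         ar_coeff=0.5, seed=9)
        ts, _ = make_graph_signal(spectrum, spec, rng=9)
        tr = time_resolved_sdi(small_connectome, ts, window_seconds=2.0)
        static = sdi_pipeline(small_connectome, ts)
        assert tr.n_windows == 20
        assert np.max(np.abs(tr.sdi.mean(axis=1) - static.sdi)) < 0.5
        assert np.median(np.std(tr.sdi, axis=1)) < 0.6

    def test_detects_mid_recording_switch(self, small_spectrum, small_connectome):
        """A node whose rough-mode energy appears only in the second half."""
        n, fs, t = 16, 32.0, 320
        rng = np.random.default_rng(4)
        coeffs = rng.standard_normal((n, t)) * (np.arange(1, n + 1.0) ** -1.5)[:, None]
        values = small_spectrum.eigenvectors @ coeffs
        burst = 5.0 * rng.standard_normal(t // 2)
        values[6, t // 2 :] += burst
        tr = time_resolved_sdi(small_connectome, _ts(values, fs), 1.0)
        half = tr.n_windows // 2
        first = tr.sdi[6, :half].mean()
        second = tr.sdi[6, half:].mean()
        assert second > first + 0.5

    def test_trailing_partial_window_dropped(self, small_connectome, random_signal):
        # 64 samples at 32 Hz with 1.5-s windows -> 48-sample window, 1 window
        tr = time_resolved_sdi(small_connectome, random_signal, 1.5)
        assert tr.n_windows == 1

    def test_too_short_signal_rejected(self, small_connectome, small_spectrum):
        sig = _ts(np.ones((16, 10)), fs=32.0)
        with pytest.raises(ValueError, match="window"):
            time_resolved_sdi(small_connectome, sig, 1.0)


class TestTemporalFluctuation:
    def _tr(self, sdi):
        from neurogsp.gsp import TimeResolvedSdi
        return TimeResolvedSdi(sdi=sdi, window_seconds=1.0,
                               per_window_cutoffs=np.ones(sdi.shape[1], dtype=int))

    def test_constant_courses_have_zero_std(self):
        std, low, high = temporal_fluctuation(self._tr(np.ones((5, 4))))
        assert np.allclose(std, 0.0)
        assert low.all() and high.all()  # all tied at both percentiles

    def test_injected_variance_lands_in_high_mask(self, rng):
        sdi = 0.01 * rng.standard_normal((10, 30))
        sdi[3] += rng.standard_normal(30)
        std, low, high = temporal_fluctuation(self._tr(sdi))
        assert high[3] and not low[3]

    def test_masks_disjoint_for_distinct_stds(self, rng):
        sdi = rng.standard_normal((20, 50)) * np.linspace(0.1, 2, 20)[:, None]
        _, low, high = temporal_fluctuation(self._tr(sdi))
        assert not np.any(low & high)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            temporal_fluctuation(self._tr(np.ones((5, 1))))


class TestDecileBins:
    def test_equal_split_for_distinct_values(self, rng):
        m = SdiMap(sdi=rng.permutation(360).astype(float), cutoff_C=2)
        masks = decile_bin_maps(m)
        assert masks.shape == (10, 360)
        assert np.all(masks.sum(axis=1) == 36)

    def test_partition_covers_all_regions_disjointly(self, rng):
        m = SdiMap(sdi=rng.standard_normal(47), cutoff_C=1)
        masks = decile_bin_maps(m)
        assert np.all(masks.sum(axis=0) == 1)

    def test_ordering_matches_sort_oracle(self, rng):
        sdi = rng.standard_normal(100)
        masks = decile_bin_maps(SdiMap(sdi=sdi, cutoff_C=1))
        order = np.argsort(sdi, kind="stable")
        decile_of = np.empty(100, dtype=int)
        for d in range(10):
            decile_of[masks[d]] = d
        assert np.all(np.diff(decile_of[order]) >= 0)

    def test_all_equal_values_assigned_by_stable_region_order(self):
        masks = decile_bin_maps(SdiMap(sdi=np.zeros(20), cutoff_C=1))
        for d in range(10):
            assert np.array_equal(np.flatnonzero(masks[d]), [2 * d, 2 * d + 1])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            decile_bin_maps(SdiMap(sdi=np.array([0.0, np.nan]), cutoff_C=1))
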