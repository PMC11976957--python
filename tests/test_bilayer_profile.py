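"""Bilayer intensity-profile smoothing, D_TT measurement, profile
extraction, aggregation and thick/thin domain classification."""

import numpy as np
import pytest

from memphys.bilayer_profile import (
    BilayerProfile,
    DttMeasurement,
    DttNoCallError,
    aggregate_dtt,
    classify_domains,
    extract_profiles,
    measure_dtt,
    smooth_profile,
)
from memphys.synthetic import gen_bilayer_profile, gen_liposome_image


def _two_trough(sep_px=20.0, n=81, pixel=1.99, depth=0.5, sigma=3.0):
    x = np.arange(n, dtype=float)
    c = (n - 1) / 2
    y = 1 - depth * (np.exp(-0.5 * ((x - c + sep_px / 2) / sigma) ** 2)
                     + np.exp(-0.5 * ((x - c - sep_px / 2) / sigma) ** 2))
    return BilayerProfile(y, pixel)


class TestSmoothing:
    def test_constant_unchanged(self):
        p = BilayerProfile(np.full(20, 3.0), 1.0)
        assert np.allclose(smooth_profile(p).intensity, 3.0)

    def test_delta_becomes_gaussian(self):
        y = np.zeros(41)
        y[20] = 1.0
        sm = smooth_profile(BilayerProfile(y, 1.0), sigma=2.0).intensity
        x = np.arange(41, dtype=float)
        expected = np.exp(-0.5 * ((x - 20) / 2.0) ** 2)
        expected /= expected.sum()
        # kernel truncation at 4 sigma leaves sub-1e-3 tail differences
        assert np.allclose(sm, expected, atol=5e-4)

    def test_mass_preserved_away_from_edges(self):
        rng = np.random.default_rng(1)
        y = 1 + 0.1 * rng.standard_normal(101)
        sm = smooth_profile(BilayerProfile(y, 1.0)).intensity
        assert sm.sum() == pytest.approx(y.sum(), rel=1e-3)

    def test_dip_positions_stable_under_noise(self):
        rng = np.random.default_rng(2)
        clean = _two_trough()
        noisy = BilayerProfile(
            clean.intensity + rng.normal(0, 0.025, len(clean)), 1.99)
        assert measure_dtt(noisy) == pytest.approx(measure_dtt(clean),
                                                   abs=0.5 * 1.99)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(BilayerProfile(np.ones(5), 1.0))


class TestMeasureDtt:
    def test_troughs_20px_apart_at_199_per_px(self):
        assert measure_dtt(_two_trough(20.0)) == pytest.approx(39.8,
                                                               abs=0.1)

    def test_inverted_gaussians_40A(self):
        p = _two_trough(40.0 / 1.99)
        assert measure_dtt(p) == pytest.approx(40.0, abs=1.0)

    def test_monotonic_profile_no_call(self):
        with pytest.raises(DttNoCallError) as e:
            measure_dtt(BilayerProfile(np.linspace(0, 1, 50), 1.99))
        assert e.value.n_found == 0

    def test_affine_intensity_invariance(self):
        p = _two_trough(18.0)
        base = measure_dtt(p)
        for a, b in ((2.0, 0.0), (0.5, 10.0), (3.0, -1.0)):
            q = BilayerProfile(a * p.intensity + b, p.pixel_size)
            assert measure_dtt(q) == pytest.approx(base, abs=1e-9)

    def test_linear_in_pixel_size(self):
        p = _two_trough(18.0, pixel=1.0)
        q = BilayerProfile(p.intensity, 2.0)
        assert measure_dtt(q) == pytest.approx(2 * measure_dtt(p), rel=1e-12)

    def test_recovery_under_noise(self):
        # simulated profiles: MAE < 1 A, no-call < 5% per condition
        for true_sep in (30.0, 36.0, 40.0):
            errs, nocall = [], 0
            for s in range(100):
                prof = gen_bilayer_profile(9000 + s, true_sep,
                                           noise_sd_frac=0.10)
                try:
                    errs.append(abs(measure_dtt(prof) - true_sep))
                except DttNoCallError:
                    nocall += 1
            assert np.mean(errs) < 1.0
            assert nocall < 5


class TestExtractProfiles:
    def test_site_count_contract_on_closed_ring(self):
        img, trace, _ = gen_liposome_image(1, 36.0)
        profiles = extract_profiles(img, trace, n_sites=10)
        assert len(profiles) == 10

    def test_image_round_trip_recovers_truth(self):
        img, trace, truth = gen_liposome_image(2, 36.0, noise_sd_frac=0.05)
        vals = [measure_dtt(p) for p in extract_profiles(img, trace)]
        assert np.mean(vals) == pytest.approx(36.0, abs=1.0)

    def test_profiles_normalized_to_unit_range(self):
        img, trace, _ = gen_liposome_image(3, 36.0)
        for p in extract_profiles(img, trace, n_sites=4):
            assert p.intensity.min() == pytest.approx(0.0)
            assert p.intensity.max() == pytest.approx(1.0)

    def test_flat_image_yields_no_profiles(self):
        trace = np.column_stack([50 + 20 * np.sin(np.linspace(0, 6, 30)),
                                 50 + 20 * np.cos(np.linspace(0, 6, 30))])
        with pytest.warns(UserWarning):
            profiles = extract_profiles(np.ones((100, 100)), trace,
                                        n_sites=5)
        assert profiles == []

    def test_window_leaving_image_skipped(self):
        img, trace, _ = gen_liposome_image(4, 36.0)
        shifted = trace.copy()
        shifted[:, 0] -= trace[:, 0].min() + 5  # push part off the top
        with pytest.warns(UserWarning):
            profiles = extract_profiles(img, shifted, n_sites=10)
        assert len(profiles) < 10


class TestAggregate:
    def test_single_liposome(self):
        s = aggregate_dtt([DttMeasurement("a", np.array([40.0, 40, 40]))])
        assert (s.grand_mean, s.grand_sd) == (40.0, 0.0)

    def test_hierarchical_mean(self):
        s = aggregate_dtt([
            DttMeasurement("a", np.array([30.0] * 10)),
            DttMeasurement("b", np.array([40.0] * 2)),
        ])
        # per-liposome means first: (30 + 40)/2, not the pooled mean
        assert s.grand_mean == pytest.approx(35.0)
        assert s.pooled_sites.size == 12

    def test_simulation_recovery(self):
        rng = np.random.default_rng(5)
        ms = [DttMeasurement(str(i), rng.normal(36.0, 2.0, 10))
              for i in range(20)]
        s = aggregate_dtt(ms)
        se = 2.0 / np.sqrt(200)
        assert s.grand_mean == pytest.approx(36.0, abs=3 * se)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_dtt([])


def _oracle_best_split(vals):
    v = np.sort(vals)
    best, best_k = np.inf, None
    for k in range(1, v.size):
        ss = ((v[:k] - v[:k].mean()) ** 2).sum() \
            + ((v[k:] - v[k:].mean()) ** 2).sum()
        if ss < best:
            best, best_k = ss, k
    return set(v[:best_k])


class TestClassifyDomains:
    def test_uniform_single_phase(self):
        calls = classify_domains(np.full(8, 40.0))
        assert all(c.label == "single" for c in calls)

    def test_clean_bimodal_split(self):
        vals = np.array([30.0, 30, 30, 45, 45, 45])
        calls = classify_domains(vals)
        assert [c.label for c in calls] == ["thin"] * 3 + ["thick"] * 3

    def test_matches_exhaustive_minimizer(self, rng):
        for _ in range(20):
            vals = np.concatenate([rng.normal(30, 1, 5),
                                   rng.normal(45, 1, 5)])
            thin_oracle = _oracle_best_split(vals)
            calls = classify_domains(vals)
            thin = {c.dtt_angstrom for c in calls if c.label == "thin"}
            assert thin == thin_oracle

    def test_small_gap_called_single(self):
        vals = np.array([39.0, 39.5, 40.0, 40.2, 40.8, 41.0])
        assert all(c.label == "single" for c in classify_domains(vals))

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            classify_domains(np.array([30.0, 45.0, 30, 45, 30]))

    def test_two_arc_liposome_classified(self):
        img, trace, _ = gen_liposome_image(6, (30.0, 45.0))
        vals = np.array([measure_dtt(p)
                         for p in extract_profiles(img, trace, n_sites=10)])
        labels = [c.label for c in classify_domains(vals)]
        assert set(labels) == {"thin", "thick"}
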