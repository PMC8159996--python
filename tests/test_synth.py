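"""Synthetic generator: determinism, calibration, and the linear oracle."""

import numpy as np
import pytest

from yieldnet.data import CORN, SOY, Entry, PairedDataset
from yieldnet.histograms import BinningScheme, HistogramTensor, truncate_season
from yieldnet.metrics import rmse
from yieldnet.synth import (
    GeneratorConfig,
    cropland_mask,
    generate_dataset,
    generate_histogram_dataset,
    generate_truth,
    histogram_mean_features,
    oracle_predictor,
    thin_labels,
    yield_table,
)


class TestGenerator:
    def test_same_seed_gives_identical_yield_tables(self):
        cfg = GeneratorConfig(n_locations=4, n_years=3, seed=5)
        a = yield_table(generate_truth(cfg))
        b = yield_table(generate_truth(cfg))
        assert a.equals(b)
        c = yield_table(generate_truth(GeneratorConfig(n_locations=4, n_years=3, seed=6)))
        assert not a.equals(c)

    def test_fully_shared_latent_without_noise_is_degenerate(self):
        cfg = GeneratorConfig(
            n_locations=40, n_years=5, shared_latent_weight=1.0,
            corn_noise_sd=1e-9, soy_noise_sd=1e-9, seed=1,
        )
        t = generate_truth(cfg)
        corn, soy = t.corn_yield.ravel(), t.soy_yield.ravel()
        assert np.corrcoef(corn, soy)[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert np.corrcoef(corn, t.z.ravel())[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_moments_match_corn_belt_calibration_defaults(self):
        # 10,000 location-years at the defaults (corn 146.68 +/- 36.03,
        # soybean 45.02 +/- 10.08 bu/acre)
        cfg = GeneratorConfig(n_locations=100, n_years=100, seed=2)
        t = generate_truth(cfg)
        n = t.corn_yield.size
        for y, mean, sd in (
            (t.corn_yield, 146.68, 36.03),
            (t.soy_yield, 45.02, 10.08),
        ):
            assert abs(y.mean() - mean) < 3 * sd / np.sqrt(n)
            assert abs(y.std() - sd) / sd < 0.05
        # cross-crop correlation implied by the shared-latent weight
        rho = cfg.shared_latent_weight
        s_c = np.sqrt(cfg.corn_sd**2 - cfg.corn_noise_sd**2)
        s_s = np.sqrt(cfg.soy_sd**2 - cfg.soy_noise_sd**2)
        expected = rho**2 * s_c * s_s / (cfg.corn_sd * cfg.soy_sd)
        observed = np.corrcoef(t.corn_yield.ravel(), t.soy_yield.ravel())[0, 1]
        assert observed == pytest.approx(expected, abs=0.03)

    def test_yields_are_positive(self):
        t = generate_truth(GeneratorConfig(n_locations=50, n_years=20, seed=3))
        assert (t.corn_yield > 0).all() and (t.soy_yield > 0).all()

    def test_cropland_mask_is_contiguous_block_of_requested_area(self):
        cfg = GeneratorConfig(n_locations=3, n_years=2, grid=(20, 20),
                              cropland_fraction=0.4, seed=4)
        m = cropland_mask(cfg, 0, 0).mask
        rows, cols = np.nonzero(m)
        block = m[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
        assert block.all()  # a solid rectangle
        assert abs(m.mean() - 0.4) < 0.1

    def test_missing_composites_become_zero_slices(self):
        cfg = GeneratorConfig(
            n_locations=3, n_years=2, grid=(10, 10), n_bins=4,
            missing_rate=0.4, seed=8,
        )
        data, _, _ = generate_histogram_dataset(cfg)
        slice_sums = np.stack([e.histogram.values.sum(axis=(1, 2)) for e in data])
        assert (slice_sums == 0).any()  # some composites void
        assert not (slice_sums == 0).all()

    def test_generate_dataset_materializes_consistent_artifacts(self):
        cfg = GeneratorConfig(n_locations=2, n_years=2, grid=(8, 8), seed=9)
        frames, masks, table, truth = generate_dataset(cfg)
        assert set(frames) == set(masks)
        assert len(frames) == 4 and len(table) == 8
        some = frames[("loc0000", 2004)]
        assert len(some) == cfg.n_composites
        assert some[0].bands.shape == (8, 8, 9)

    def test_invalid_configs_are_rejected(self):
        with pytest.raises(ValueError, match="noise sd"):
            GeneratorConfig(corn_noise_sd=40.0)
        with pytest.raises(ValueError):
            GeneratorConfig(shared_latent_weight=1.5)
        with pytest.raises(ValueError, match="non-decreasing"):
            GeneratorConfig(n_composites=3, season_ramp=[1.0, 0.5, 2.0])


class TestPipelineInvariants:
    def test_generated_histograms_are_normalized_frequencies(self, tiny_dataset):
        data, scheme, _ = tiny_dataset
        for e in data:
            sums = e.histogram.values.sum(axis=1)  # (T, d)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            assert (e.histogram.values >= 0).all()

    def test_edges_come_from_training_years_only(self):
        cfg = GeneratorConfig(n_locations=4, n_years=4, grid=(10, 10), n_bins=6, seed=12)
        all_years = cfg.years
        _, scheme_train, _ = generate_histogram_dataset(cfg, train_years=all_years[:2])
        _, scheme_all, _ = generate_histogram_dataset(cfg, train_years=all_years)
        assert not np.array_equal(scheme_train.edges, scheme_all.edges)


class TestThinLabels:
    def test_identity_at_full_overlap(self, tiny_dataset):
        data, _, _ = tiny_dataset
        out = thin_labels(data, 1.0, seed=0)
        assert all(
            a.corn_yield == b.corn_yield and a.soy_yield == b.soy_yield
            for a, b in zip(data, out)
        )

    def test_partial_overlap_splits_single_crop_labels(self, tiny_dataset):
        data, _, _ = tiny_dataset
        out = thin_labels(data, 0.0, seed=0)
        kinds = {
            (e.corn_yield is not None, e.soy_yield is not None) for e in out
        }
        assert kinds <= {(True, False), (False, True)}
        assert len(out) == len(data)


@pytest.fixture(scope="module")
def ramp_study():
    # three bands keep the oracle at 91 features against 900 training
    # samples (negligible estimation variance); the ramp switches on at
    # grain fill, after the 18th composite, so the late-July cutoff
    # discards essentially all of the yield signal
    cfg = GeneratorConfig(
        n_locations=150, n_years=7, grid=(12, 12), n_bins=16, n_bands=3,
        band_means=np.array([0.08, 0.35, 298.0]),
        band_effects=np.array([-0.015, 0.06, -3.0]),
        pixel_noise_sd=np.array([0.02, 0.04, 2.0]),
        corn_noise_sd=6.0, soy_noise_sd=1.8, seed=21,
        season_ramp=np.clip((np.arange(1, 31) - 17) / 13, 0, None) ** 2,
    )
    years = cfg.years
    data, scheme, _ = generate_histogram_dataset(cfg, train_years=years[:-1])
    return data.filter_years(years[:-1]), data.filter_years([years[-1]]), scheme


class TestOracle:
    @staticmethod
    def _fractional_tensor(targets, scheme, T):
        """Histogram whose per-(t,band) mean equals ``targets[t, j]`` exactly:
        mass split linearly between the two straddling bin centers."""
        b, d = scheme.n_bins, scheme.n_bands
        centers = (scheme.edges[:, :-1] + scheme.edges[:, 1:]) / 2
        values = np.zeros((T, b, d))
        for t in range(T):
            for j in range(d):
                v = targets[t, j]
                k = int(np.searchsorted(centers[j], v) - 1)
                k = min(max(k, 0), b - 2)
                w = (centers[j, k + 1] - v) / (centers[j, k + 1] - centers[j, k])
                values[t, k, j] = w
                values[t, k + 1, j] = 1 - w
        return values

    def test_exact_linear_recovery_on_fractional_histograms(self):
        # when the histogram means are exactly affine in the latent the
        # least-squares oracle recovers yields to machine precision
        T, b, d = 4, 8, 2
        scheme = BinningScheme(np.tile(np.linspace(0.0, 1.0, b + 1), (d, 1)))
        rng = np.random.default_rng(0)
        z = rng.normal(size=30)
        entries = []
        for i, zi in enumerate(z):
            targets = 0.5 + 0.08 * zi * np.ones((T, d))
            tensor = HistogramTensor(
                self._fractional_tensor(targets, scheme, T), f"L{i}", 2004 + i, T
            )
            entries.append(
                Entry(f"L{i}", 2004 + i, tensor, 150 + 30 * zi, 45 + 10 * zi)
            )
        train = PairedDataset(entries[:20])
        test = PairedDataset(entries[20:])
        oracle = oracle_predictor(train, scheme)
        preds = oracle.predict(test)
        _, yc, ys = test.to_arrays()
        scale = 150.0
        assert rmse(yc, preds[CORN]) <= 1e-6 * scale
        assert rmse(ys, preds[SOY]) <= 1e-6 * scale

    def test_zero_slice_maps_to_zero_feature(self):
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 5), (2, 1)))
        values = np.zeros((3, 4, 2))
        values[0, 1, :] = 1.0
        feats = histogram_mean_features(values, scheme)
        assert feats.shape == (6,)
        assert (feats[2:] == 0).all() and (feats[:2] > 0).all()

    def test_truncation_cannot_help_the_oracle(self, ramp_study):
        train, test, scheme = ramp_study
        _, yc, ys = test.to_arrays()

        def floor(doy):
            tr = train.map_histograms(lambda h: truncate_season(h, doy))
            te = test.map_histograms(lambda h: truncate_season(h, doy))
            p = oracle_predictor(tr, scheme).predict(te)
            return rmse(yc, p[CORN]) + rmse(ys, p[SOY]) * 36.03 / 10.08

        assert floor(204) >= floor(365) * 0.98  # July vs full season

    def test_oracle_rmse_approaches_the_label_noise_floor(self):
        # fully shared latent, low pixel noise: the only irreducible error
        # is the yield label noise itself
        # short season and three bands (31 oracle features vs 480 training
        # samples) so least-squares variance inflation stays negligible
        cfg = GeneratorConfig(
            n_locations=120, n_years=5, grid=(16, 16), n_bins=32,
            n_composites=10, n_bands=3,
            band_means=np.array([0.08, 0.35, 298.0]),
            band_effects=np.array([-0.015, 0.06, -3.0]),
            pixel_noise_sd=np.array([0.004, 0.008, 0.4]),
            corn_noise_sd=10.0, soy_noise_sd=3.0, shared_latent_weight=1.0,
            seed=13,
        )
        years = cfg.years
        data, scheme, _ = generate_histogram_dataset(cfg, train_years=years[:-1])
        train = data.filter_years(years[:-1])
        test = data.filter_years([years[-1]])
        _, yc, _ = test.to_arrays()
        p = oracle_predictor(train, scheme).predict(test)
        observed = rmse(yc, p[CORN])
        assert abs(observed - cfg.corn_noise_sd) / cfg.corn_noise_sd < 0.25
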