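"""Synthetic generator: determinism, composition control, Markov structure."""

import numpy as np
import pytest

from landesv.accuracy import accuracy_report, build_error_matrix
from landesv.change import transition_matrix
from landesv.indices import ndvi
from landesv.lulc import areas_from_landscape
from landesv.synthetic import (
    ConfigError,
    GeneratorConfig,
    SamplingError,
    apply_markov_change,
    default_config,
    generate_bands,
    generate_landscape,
    generate_reference_sample,
)


@pytest.fixture(scope="module")
def cfg():
    return default_config()


class TestGenerateLandscape:
    def test_degenerate_proportions_give_constant_grid(self, cfg, legend):
        solo = GeneratorConfig(
            legend=legend, shape=(15, 15), proportions={"cropland": 1.0},
            band_params=cfg.band_params,
        )
        scape = generate_landscape(solo, "t0", seed=4)
        assert np.all(scape.grid == legend.code_of("cropland"))

    def test_same_seed_is_bit_identical(self, cfg):
        a = generate_landscape(cfg, "t0", seed=11)
        b = generate_landscape(cfg, "t0", seed=11)
        assert np.array_equal(a.grid, b.grid)
        c = generate_landscape(cfg, "t0", seed=12)
        assert not np.array_equal(a.grid, c.grid)

    def test_realized_fractions_near_targets(self, cfg):
        big = GeneratorConfig(
            legend=cfg.legend, shape=(1000, 1000), proportions=cfg.proportions,
            transition=cfg.transition, confusion=cfg.confusion, band_params=cfg.band_params,
        )
        scape = generate_landscape(big, "t0", seed=5)
        counts = scape.class_counts()
        n = sum(counts.values())
        for cls, target in cfg.proportions.items():
            assert counts[cls] / n == pytest.approx(target, abs=0.003)

    def test_bad_proportions_rejected(self, legend):
        with pytest.raises(ConfigError):
            GeneratorConfig(legend=legend, proportions={"forest": 0.5, "cropland": 0.4})

    def test_smoothing_keeps_legend_codes(self, cfg, legend):
        smoothed = GeneratorConfig(
            legend=legend, shape=(60, 60), proportions=cfg.proportions, smoothing_passes=2,
        )
        scape = generate_landscape(smoothed, "t0", seed=3)
        assert set(np.unique(scape.grid)) <= set(legend.codes)


class TestMarkovChange:
    def test_identity_matrix_changes_nothing(self, cfg):
        scape = generate_landscape(cfg, "t0", seed=8)
        out = apply_markov_change(scape, np.eye(5), seed=9, date_label="t1")
        assert np.array_equal(out.grid, scape.grid)
        assert out.date_label == "t1"

    def test_forced_row_converts_every_pixel(self, cfg, legend):
        scape = generate_landscape(cfg, "t0", seed=8)
        P = np.eye(5)
        i = legend.class_names.index("forest")
        j = legend.class_names.index("built-up")
        P[i, i], P[i, j] = 0.0, 1.0
        out = apply_markov_change(scape, P, seed=9)
        assert not np.any(out.grid == legend.codes[i])

    def test_non_stochastic_rows_rejected(self, cfg):
        scape = generate_landscape(cfg, "t0", seed=8)
        with pytest.raises(ConfigError):
            apply_markov_change(scape, np.eye(5) * 0.9, seed=9)

    def test_measured_transitions_recover_generator_matrix(self, cfg):
        big = GeneratorConfig(
            legend=cfg.legend, shape=(1000, 1000), proportions=cfg.proportions,
            transition=cfg.transition,
        )
        l1 = generate_landscape(big, "t0", seed=21)
        P = big.transition_matrix()
        l2 = apply_markov_change(l1, P, seed=22, date_label="t1")
        measured = transition_matrix(l1, l2).row_normalized()
        assert np.abs(measured - P).max() < 0.02


class TestReferenceSample:
    def test_identity_confusion_gives_perfect_accuracy(self, cfg, legend):
        scape = generate_landscape(cfg, "t0", seed=31)
        mapped, reference = generate_reference_sample(scape, np.eye(5), 420, seed=32)
        report = accuracy_report(build_error_matrix(mapped, reference, legend))
        assert report.overall_pct == 100.0
        assert report.kappa == pytest.approx(1.0)

    def test_counts_proportional_to_areas_within_one(self, cfg, legend):
        scape = generate_landscape(cfg, "t0", seed=33)
        mapped, _ = generate_reference_sample(scape, np.eye(5), 420, seed=34)
        counts = scape.class_counts()
        n_pixels = sum(counts.values())
        for cls in legend.class_names:
            expected = 420 * counts[cls] / n_pixels
            assert abs(mapped.count(cls) - expected) <= 1

    def test_sample_determinism(self, cfg):
        scape = generate_landscape(cfg, "t0", seed=35)
        s1 = generate_reference_sample(scape, cfg.confusion_matrix(), 100, seed=36)
        s2 = generate_reference_sample(scape, cfg.confusion_matrix(), 100, seed=36)
        assert s1 == s2

    def test_oversampling_rejected(self, cfg, legend):
        small = GeneratorConfig(legend=legend, shape=(3, 3), proportions=cfg.proportions)
        scape = generate_landscape(small, "t0", seed=37)
        with pytest.raises(SamplingError):
            generate_reference_sample(scape, np.eye(5), 100, seed=38)


class TestBands:
    def test_zero_spread_is_piecewise_constant(self, cfg, legend):
        flat = {cls: {b: (m, 0.0) for b, (m, _) in per.items()} for cls, per in cfg.band_params.items()}
        config = GeneratorConfig(
            legend=legend, shape=(20, 20), proportions=cfg.proportions, band_params=flat,
        )
        scape = generate_landscape(config, "t0", seed=41)
        bands = generate_bands(scape, config, seed=42)
        for cls in ("forest", "cropland"):
            sel = scape.grid == legend.code_of(cls)
            assert np.all(bands["green"][sel] == flat[cls]["green"][0])

    def test_expected_ndsi_from_class_means(self, legend, cfg):
        flat = {cls: {b: (m, 0.0) for b, (m, _) in per.items()} for cls, per in cfg.band_params.items()}
        flat["forest"]["green"], flat["forest"]["swir"] = (0.3, 0.0), (0.1, 0.0)
        config = GeneratorConfig(
            legend=legend, shape=(10, 10), proportions={"forest": 1.0}, band_params=flat,
        )
        scape = generate_landscape(config, "t0", seed=43)
        from landesv.indices import ndsi

        assert np.allclose(ndsi(generate_bands(scape, config, seed=44)), 0.5)

    def test_ndvi_orders_vegetation_over_builtup(self, cfg):
        scape = generate_landscape(cfg, "t0", seed=45)
        bands = generate_bands(scape, cfg, seed=46)
        vi = ndvi(bands)
        legend = cfg.legend
        means = {
            cls: float(vi[scape.grid == legend.code_of(cls)].mean())
            for cls in ("forest", "grassland", "built-up")
        }
        assert means["forest"] > means["grassland"] > means["built-up"]

    def test_missing_class_parameters_rejected(self, cfg, legend):
        config = GeneratorConfig(
            legend=legend, shape=(5, 5), proportions=cfg.proportions,
            band_params={"forest": {"green": (0.1, 0.0)}},
        )
        scape = generate_landscape(config, "t0", seed=47)
        with pytest.raises(ConfigError):
            generate_bands(scape, config, seed=48)


class TestEndToEnd:
    def test_pipeline_recovers_generator_ground_truth(self, cfg, coeffs, legend):
        """Generate a study-like pair and re-measure its known structure."""
        from landesv.valuation import compute_esv

        config = GeneratorConfig(
            legend=cfg.legend, shape=(400, 400), proportions=cfg.proportions,
            transition=cfg.transition,
        )
        l1 = generate_landscape(config, "1995", seed=51)
        l2 = apply_markov_change(l1, config.transition_matrix(), seed=52, date_label="2020")
        tm = transition_matrix(l1, l2)
        # transition marginals = re-tabulated areas, exactly
        assert tm.row_totals.areas == pytest.approx(areas_from_landscape(l1).areas, abs=1e-9)
        assert tm.col_totals.areas == pytest.approx(areas_from_landscape(l2).areas, abs=1e-9)
        # valuation of the synthetic pair behaves like the real tables:
        # per-class ESV ratio equals area ratio
        r1 = compute_esv(areas_from_landscape(l1), coeffs, legend)
        r2 = compute_esv(areas_from_landscape(l2), coeffs, legend)
        a1, a2 = areas_from_landscape(l1), areas_from_landscape(l2)
        for cls in ("forest", "cropland"):
            assert r2.value(cls) / r1.value(cls) == pytest.approx(a2[cls] / a1[cls], rel=1e-12)
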