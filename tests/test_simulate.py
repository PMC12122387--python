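"""Synthetic survey generator: shapes, determinism, and calibration."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from mfdiv import simulate
from mfdiv.geo_env import DisconnectedError, waterway_distance
from mfdiv.simulate import SimConfig, SimConfigError, TRAITS


class TestGenerateSpecimens:
    def test_row_and_site_counts(self):
        cfg = SimConfig(n_marine_sites=10, n_freshwater_sites=6, n_per_site=30, seed=1)
        specimens, metadata, _ = simulate.generate_specimens(cfg)
        assert len(specimens) == 480
        assert specimens["site"].nunique() == 16
        assert len(metadata) == 16
        assert set(specimens["habitat"]) == {"marine", "freshwater"}

    def test_default_sample_sizes_match_survey_design(self):
        cfg = SimConfig(seed=0)
        specimens, _, _ = simulate.generate_specimens(cfg)
        sizes = specimens.groupby("site").size()
        marine = sizes[[s for s in sizes.index if s.startswith("marine")]]
        fresh = sizes[[s for s in sizes.index if s.startswith("lake")]]
        assert marine.min() >= 20 and marine.max() <= 60 and len(marine) == 10
        assert fresh.min() >= 25 and fresh.max() <= 60 and len(fresh) == 6
        assert sizes.sum() == sum(simulate.MARINE_N) + sum(simulate.FRESHWATER_N)

    def test_seeded_runs_identical(self):
        cfg = SimConfig(n_per_site=15, seed=11)
        a = simulate.generate_specimens(cfg)
        b = simulate.generate_specimens(cfg)
        assert_frame_equal(a[0], b[0])
        assert_frame_equal(a[1], b[1])
        assert_frame_equal(a[2].site_means, b[2].site_means)

    def test_count_traits_are_nonnegative_integers(self, survey):
        for t in simulate.COUNT_TRAITS:
            vals = survey["specimens"][t]
            assert (vals >= 0).all()
            assert np.allclose(vals, np.round(vals))

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_per_site": 1},
            {"n_per_site": -5},
            {"length_sd_mm": -1.0},
            {"trait_sds": {t: -0.1 for t in TRAITS}},
            {"n_marine_sites": 0},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(SimConfigError):
            SimConfig(**bad)

    def test_within_site_variance_converges(self):
        # one huge marine site: sample variance of a continuous trait should
        # sit within 3 SE of the configured value (chi-square sampling SE)
        n = 10_000
        cfg = SimConfig(
            n_marine_sites=1, n_freshwater_sites=1, n_per_site=n,
            length_sd_mm=0.0, seed=5,
        )
        specimens, _, _ = simulate.generate_specimens(cfg)
        marine = specimens[specimens["habitat"] == "marine"]
        sigma2 = cfg.trait_sds["body_depth"] ** 2
        se = sigma2 * np.sqrt(2.0 / (n - 1))
        assert abs(marine["body_depth"].var(ddof=1) - sigma2) < 3 * se

    def test_truth_expected_theta_zero_when_fully_parallel(self):
        zero = {t: 0.0 for t in TRAITS}
        cfg = SimConfig(nonparallel_sd=dict(zero), n_per_site=10, seed=3)
        _, _, truth = simulate.generate_specimens(cfg)
        assert np.allclose(truth.expected_theta_deg["theta_deg"], 0.0, atol=1e-9)

    def test_allometric_slope_recoverable(self):
        # trait value regresses on length with the configured slope
        cfg = SimConfig(n_marine_sites=1, n_freshwater_sites=1, n_per_site=5000, seed=9)
        specimens, _, _ = simulate.generate_specimens(cfg)
        sub = specimens[specimens["habitat"] == "marine"]
        slope = np.polyfit(sub["standard_length_mm"], sub["body_depth"], 1)[0]
        assert slope == pytest.approx(cfg.allometric_slopes["body_depth"], abs=0.02)


class TestGenerateClimate:
    def test_shape_and_determinism(self, survey):
        clim = simulate.generate_climate(survey["metadata"], seed=2)
        assert clim.shape == (16, 20)  # site + 19 BIO columns
        assert list(clim.columns[1:]) == list(simulate.BIO_VARS)
        assert_frame_equal(clim, simulate.generate_climate(survey["metadata"], seed=2))

    def test_temperature_block_collinear(self, survey):
        # BIO05 is constructed on the same thermal factor as BIO01, so the
        # pair must exceed the conventional pruning threshold
        clim = simulate.generate_climate(survey["metadata"], seed=2)
        r = np.corrcoef(clim["BIO01"], clim["BIO05"])[0, 1]
        assert abs(r) > 0.80

    def test_empty_metadata_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_climate(pd.DataFrame(columns=["site", "latitude", "longitude"]))


class TestWaterRaster:
    def test_all_water_grid(self):
        raster = simulate.generate_water_raster((10, 10), resolution_km=1.0)
        assert raster.water.sum() == 100

    def test_land_row_disconnects_components(self):
        land = [(5, c) for c in range(10)]
        raster = simulate.generate_water_raster((10, 10), land, resolution_km=1.0)
        with pytest.raises(DisconnectedError):
            waterway_distance(raster, (0, 0), (9, 9), snap_radius=1)

    def test_straight_channel_length(self):
        land = [(r, c) for r in range(3) for c in range(5) if r != 1]
        raster = simulate.generate_water_raster((3, 5), land, resolution_km=1.0)
        assert waterway_distance(raster, (1, 0), (1, 4), snap_radius=0) == pytest.approx(4.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate.generate_water_raster((10, 10), resolution_km=0)
        with pytest.raises(ValueError):
            simulate.generate_water_raster((4, 4), [(9, 9)])

    def test_synthetic_geography_connects_all_sites(self, survey):
        from mfdiv.geo_env import distance_matrix

        raster, cells = simulate.synthetic_geography(survey["metadata"])
        dists = distance_matrix(raster, cells)
        assert (dists.to_numpy()[np.triu_indices(len(dists), 1)] > 0).all()
        assert np.allclose(dists, dists.T)


def test_null_generator_removes_habitat_divergence():
    """With no habitat effect, marine-freshwater PC1 separation is
    indistinguishable from the marine-marine baseline."""
    from mfdiv import morphospace, preprocess

    cfg = simulate.with_no_divergence(SimConfig(n_per_site=40, seed=21))
    specimens, metadata, _ = simulate.generate_specimens(cfg)
    fits = preprocess.fit_all_allometries(specimens)
    corrected = preprocess.size_correct(specimens, fits)
    pca = morphospace.run_pca(corrected, orient_pc1_by_habitat=False)
    cent = morphospace.site_centroids(pca)
    marine = metadata.loc[metadata["habitat"] == "marine", "site"].tolist()
    fresh = metadata.loc[metadata["habitat"] == "freshwater", "site"].tolist()
    cross = [abs(cent.loc[f, "PC1"] - cent.loc[m, "PC1"]) for m in marine for f in fresh]
    within = [
        abs(cent.loc[a, "PC1"] - cent.loc[b, "PC1"])
        for i, a in enumerate(marine) for b in marine[i + 1:]
    ]
    # permutation test on the difference of means between the two pair sets
    pooled = np.array(cross + within)
    labels = np.array([1] * len(cross) + [0] * len(within))
    obs = pooled[labels == 1].mean() - pooled[labels == 0].mean()
    rng = np.random.default_rng(0)
    null = []
    for _ in range(999):
        perm = rng.permutation(labels)
        null.append(abs(pooled[perm == 1].mean() - pooled[perm == 0].mean()))
    p = (1 + np.sum(np.array(null) >= abs(obs))) / 1000
    assert p > 0.01
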