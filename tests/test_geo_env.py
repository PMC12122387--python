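"""Waterway distances, climate pruning, environmental difference."""

import numpy as np
import pandas as pd
import pytest

from mfdiv import geo_env, simulate
from mfdiv.geo_env import (
    DisconnectedError,
    SnapError,
    WaterRaster,
    distance_matrix,
    environment_difference,
    prune_climate_variables,
    waterway_distance,
)


def brute_force_shortest(water: np.ndarray, a, b, resolution=1.0, connectivity=8):
    """Exhaustive DFS over all simple water paths on a tiny grid."""
    nrow, ncol = water.shape
    steps = [(-1, 0, 1), (1, 0, 1), (0, -1, 1), (0, 1, 1)]
    if connectivity == 8:
        s2 = np.sqrt(2)
        steps += [(-1, -1, s2), (-1, 1, s2), (1, -1, s2), (1, 1, s2)]
    best = [np.inf]

    def dfs(cell, dist, seen):
        if dist >= best[0]:
            return
        if cell == b:
            best[0] = dist
            return
        r, c = cell
        for dr, dc, w in steps:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrow and 0 <= nc < ncol and water[nr, nc] and (nr, nc) not in seen:
                dfs((nr, nc), dist + w * resolution, seen | {(nr, nc)})

    dfs(a, 0.0, {a})
    return best[0]


class TestWaterwayDistance:
    def test_same_cell_is_zero(self):
        raster = WaterRaster(np.ones((4, 4), bool), 2.0)
        assert waterway_distance(raster, (1, 1), (1, 1)) == 0.0

    def test_straight_channel(self):
        water = np.zeros((3, 6), bool)
        water[1, :] = True
        raster = WaterRaster(water, 1.0)
        assert waterway_distance(raster, (1, 0), (1, 5), snap_radius=0) == pytest.approx(5.0)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_exhaustive_enumeration(self, rng, connectivity):
        """Dijkstra equals brute-force path enumeration on random <=6x6 masks,
        including an L-shaped corridor."""
        masks = []
        L = np.zeros((5, 5), bool)
        L[4, :] = True
        L[:, 4] = True
        masks.append((L, (4, 0), (0, 4)))
        for _ in range(6):
            w = rng.random((6, 6)) > 0.35
            w[0, 0] = w[5, 5] = True
            masks.append((w, (0, 0), (5, 5)))
        for water, a, b in masks:
            raster = WaterRaster(water, 1.0)
            expected = brute_force_shortest(water, a, b, connectivity=connectivity)
            if np.isinf(expected):
                with pytest.raises(DisconnectedError):
                    waterway_distance(raster, a, b, connectivity, snap_radius=0)
            else:
                got = waterway_distance(raster, a, b, connectivity, snap_radius=0)
                assert got == pytest.approx(expected, rel=1e-9)

    def test_symmetry_and_triangle_inequality(self, rng):
        water = rng.random((8, 8)) > 0.2
        water[:, 3] = True
        water[2, :] = True
        raster = WaterRaster(water, 1.5)
        cells = [tuple(c) for c in np.argwhere(water)[:: max(1, water.sum() // 6)]]
        cells = {f"s{i}": c for i, c in enumerate(cells[:5])}
        d = distance_matrix(raster, cells)
        assert np.allclose(d, d.T)
        sites = list(cells)
        for a in sites:
            for b in sites:
                for c in sites:
                    assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-9

    def test_refinement_never_lengthens_path_beyond_bound(self):
        # same corridor at 1 km and 0.5 km cells: the finer path can only
        # shorten (up to discretisation) the coarse estimate
        coarse = np.zeros((4, 8), bool)
        coarse[1, :] = True
        coarse[2, 4:] = True
        fine = np.kron(coarse, np.ones((2, 2), bool))
        d_coarse = waterway_distance(WaterRaster(coarse, 1.0), (1, 0), (2, 7), snap_radius=0)
        d_fine = waterway_distance(WaterRaster(fine, 0.5), (2, 0), (5, 15), snap_radius=0)
        assert d_fine <= d_coarse * np.sqrt(2) + 1e-9
        assert d_fine >= d_coarse / np.sqrt(2) - 1e-9

    def test_snap_to_water_and_snap_error(self):
        water = np.zeros((7, 7), bool)
        water[:, 0] = True
        raster = WaterRaster(water, 1.0)
        # a land point 2 cells from the channel snaps onto it
        assert waterway_distance(raster, (0, 2), (6, 0)) == pytest.approx(6.0)
        with pytest.raises(SnapError):
            waterway_distance(raster, (0, 6), (6, 0))


class TestPruneClimate:
    def _climate(self, rng, n=16):
        meta = pd.DataFrame(
            {
                "site": [f"s{i}" for i in range(n)],
                "habitat": "marine",
                "latitude": rng.uniform(48, 51, n),
                "longitude": rng.uniform(-128, -122, n),
            }
        )
        return simulate.generate_climate(meta, seed=3)

    def test_weakly_correlated_all_retained(self, rng):
        clim = pd.DataFrame(
            {"site": list("abcdefgh")}
            | {f"BIO{i:02d}": rng.normal(size=8) for i in range(1, 20)}
        )
        retained = prune_climate_variables(clim)
        # independent noise at n=8 can exceed r=0.8 by chance only rarely
        assert len(retained) >= 15

    def test_exact_duplicate_dropped(self, rng):
        clim = self._climate(rng)
        clim["BIO05"] = clim["BIO01"]  # duplicate of a higher-priority var
        assert "BIO05" not in prune_climate_variables(clim)

    def test_constant_variable_dropped(self, rng):
        clim = self._climate(rng)
        clim["BIO01"] = 7.7
        retained = prune_climate_variables(clim)
        assert "BIO01" not in retained

    def test_invariant_to_site_order(self, rng):
        clim = self._climate(rng)
        shuffled = clim.sample(frac=1, random_state=5).reset_index(drop=True)
        assert prune_climate_variables(clim) == prune_climate_variables(shuffled)

    def test_annual_variables_preferred(self, rng):
        retained = prune_climate_variables(self._climate(rng))
        assert "BIO01" in retained and "BIO12" in retained
        # collinear temperature-block partners of BIO01 are pruned
        assert "BIO05" not in retained and "BIO10" not in retained

    def test_needs_two_sites(self):
        with pytest.raises(ValueError):
            prune_climate_variables(pd.DataFrame({"site": ["a"], "BIO01": [1.0]}))


class TestEnvironmentDifference:
    def test_identical_climates_zero_difference(self):
        clim = pd.DataFrame(
            {
                "site": ["m1", "f1", "x"],
                "BIO01": [5.0, 5.0, 9.0],
                "BIO12": [100.0, 100.0, 300.0],
            }
        )
        diff = environment_difference(
            clim, ["BIO01", "BIO12"], axes=("PC1",), pairs=[("m1", "f1")]
        )
        assert diff["abs_diff_PC1"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_variable_difference_scales_with_loading(self):
        # three sites varying on BIO01 only: PC1 differences are proportional
        # to the z-scored BIO01 differences
        clim = pd.DataFrame(
            {
                "site": ["a", "b", "c"],
                "BIO01": [1.0, 2.0, 4.0],
                "BIO12": [100.0, 100.0, 100.0],
            }
        )
        diff = environment_difference(
            clim, ["BIO01"], axes=("PC1",), pairs=[("a", "b"), ("a", "c")]
        )
        z = (clim["BIO01"] - clim["BIO01"].mean()) / clim["BIO01"].std(ddof=1)
        ratio = abs(z[2] - z[0]) / abs(z[1] - z[0])
        assert diff["abs_diff_PC1"].iloc[1] / diff["abs_diff_PC1"].iloc[0] == pytest.approx(ratio)

    def test_default_pairs_from_metadata(self, survey):
        clim = simulate.generate_climate(survey["metadata"], seed=4)
        retained = prune_climate_variables(clim)
        diff = environment_difference(clim, retained, metadata=survey["metadata"])
        assert len(diff) == 60
        assert diff["abs_diff_PC1"].notna().all()
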