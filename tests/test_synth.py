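"""Synthetic world generators: determinism, statistical structure, and
the sampling properties the downstream analysis relies on."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sdmshift.errors import ConfigError, SimulationError
from sdmshift.predictors import derive_ndvi_layers
from sdmshift.synth import (
    SyntheticWorldConfig,
    make_ndvi_stack,
    make_predictor_stack,
    make_protected_areas,
    make_species_and_presences,
    _smooth_field,
)


def small_cfg(**kw):
    defaults = dict(seed=5, n_rows=50, n_cols=60, n_species=3,
                    n_presences_per_species=40, n_pas=6)
    defaults.update(kw)
    return SyntheticWorldConfig(**defaults)


class TestPredictorStack:
    def test_same_seed_identical(self):
        cfg = small_cfg()
        cur1, fut1 = make_predictor_stack(cfg)
        cur2, fut2 = make_predictor_stack(cfg)
        for a, b in zip(cur1.layers, cur2.layers):
            assert np.array_equal(a.values, b.values)
            assert np.array_equal(a.mask, b.mask)
        key = (2050, "A2a")
        assert np.array_equal(fut1[key].layers[0].values, fut2[key].layers[0].values)

    def test_standardized_over_land(self):
        cur, _ = make_predictor_stack(small_cfg())
        land = cur.land_mask
        for idx in cur.continuous_indices():
            vals = cur.layers[idx].values[land]
            assert abs(vals.mean()) < 1e-9
            assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_pair_achieves_target(self):
        cfg = small_cfg(collinear_pairs=[(0, 1, 0.95)])
        cur, _ = make_predictor_stack(cfg)
        land = cur.land_mask
        r = np.corrcoef(cur.layers[0].values[land], cur.layers[1].values[land])[0, 1]
        assert 0.85 < r < 1.0

    def test_zero_deltas_future_equals_current(self):
        cfg = small_cfg(future_deltas=[0.0] * 6)
        cur, futures = make_predictor_stack(cfg)
        for stack in futures.values():
            for a, b in zip(cur.layers, stack.layers):
                assert np.array_equal(a.values, b.values)

    def test_future_shift_matches_deltas(self):
        cfg = small_cfg()
        cur, futures = make_predictor_stack(cfg)
        land = cur.land_mask
        # second time slice, severe scenario: temperature-like layer 0
        stack = futures[(2050, "A2a")]
        shift = (stack.layers[0].values[land] - cur.layers[0].values[land]).mean()
        assert shift == pytest.approx(0.5 * 2 * 1.0, abs=1e-9)
        shift5 = (stack.layers[5].values[land] - cur.layers[5].values[land]).mean()
        assert shift5 == pytest.approx(-0.2 * 2 * 1.0, abs=1e-9)

    def test_habitat_layer_is_categorical_codes(self):
        cur, _ = make_predictor_stack(small_cfg())
        hab = cur.layers[cur.index_of("habitat")]
        codes = np.unique(hab.values[cur.land_mask])
        assert np.array_equal(codes, codes.astype(int))
        assert codes.min() >= 1 and codes.max() <= 11

    def test_map_inventory(self):
        _, futures = make_predictor_stack(small_cfg())
        assert len(futures) == 6  # 3 times x 2 scenarios

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticWorldConfig(collinear_pairs=[(0, 1, 1.0)])


class TestSpeciesPresences:
    def test_uniform_suitability_uniform_presences(self):
        cfg = small_cfg(sea_fraction=0.0, n_rows=60, n_cols=60)
        cur, _ = make_predictor_stack(cfg)
        _, occ = make_species_and_presences(cur, [0.0] * 6, 2000, seed=2,
                                            intercept=0.0)
        rows = np.array([c[0] for c in occ.cells])
        cols = np.array([c[1] for c in occ.cells])
        quadrant = (rows >= 30).astype(int) * 2 + (cols >= 30).astype(int)
        counts = np.bincount(quadrant, minlength=4)
        assert chisquare(counts).pvalue > 0.001

    def test_presences_track_the_dominant_predictor(self):
        cfg = small_cfg()
        cur, _ = make_predictor_stack(cfg)
        land = cur.land_mask
        land_mean = cur.layers[0].values[land].mean()
        hits = 0
        for rep in range(100):
            _, occ = make_species_and_presences(
                cur, [3.0, 0, 0, 0, 0, 0], 50, seed=1000 + rep, intercept=-2.0
            )
            at_pres = np.mean([cur.layers[0].values[c] for c in occ.cells])
            hits += at_pres > land_mean
        assert hits >= 95

    def test_single_presence(self):
        cur, _ = make_predictor_stack(small_cfg())
        _, occ = make_species_and_presences(cur, [1, 0, 0, 0, 0, 0], 1, seed=0)
        assert len(occ.cells) == 1

    def test_oversized_request_rejected(self):
        cur, _ = make_predictor_stack(small_cfg())
        n_land = int(cur.land_mask.sum())
        with pytest.raises(SimulationError):
            make_species_and_presences(cur, [0.0] * 6, n_land + 1, seed=0)

    def test_suitability_masked_off_land(self):
        cur, _ = make_predictor_stack(small_cfg())
        sp, _ = make_species_and_presences(cur, [1, 0, 0, 0, 0, 0], 10, seed=0)
        assert np.array_equal(sp.true_suitability.mask, ~cur.land_mask)


class TestNdvi:
    def test_constant_series(self):
        cfg = small_cfg(ndvi_noise_sd=0.0)
        comps = make_ndvi_stack(cfg, base=0.4, amplitude=0.0)
        max_l, diff_l = derive_ndvi_layers(comps)
        land = ~max_l.mask
        assert np.allclose(max_l.values[land], 0.4)
        assert np.allclose(diff_l.values[land], 0.0)

    def test_sinusoid_extremes(self):
        cfg = small_cfg(ndvi_noise_sd=0.0, ndvi_n_composites=400)
        comps = make_ndvi_stack(cfg, base=0.5, amplitude=0.3)
        max_l, diff_l = derive_ndvi_layers(comps)
        land = ~max_l.mask
        assert max_l.values[land].mean() == pytest.approx(0.8, abs=0.05)
        assert diff_l.values[land].mean() == pytest.approx(0.6, abs=0.05)

    def test_seeded_repeat_identical(self):
        cfg = small_cfg()
        a = make_ndvi_stack(cfg)
        b = make_ndvi_stack(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_values_bounded(self):
        comps = make_ndvi_stack(small_cfg())
        for c in comps:
            assert c.values.min() >= -1.0 and c.values.max() <= 1.0


class TestProtectedAreas:
    def test_count_and_disjointness(self):
        cfg = small_cfg(n_pas=5)
        cur, _ = make_predictor_stack(cfg)
        pas = make_protected_areas(cfg, cur.grid, land_mask=cur.land_mask)
        assert len(pas) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert not pas[i].polygon.intersects(pas[j].polygon)

    def test_subcell_reserve_present(self):
        cfg = small_cfg(n_pas=6)
        cur, _ = make_predictor_stack(cfg)
        pas = make_protected_areas(cfg, cur.grid, land_mask=cur.land_mask)
        cell_area = cur.grid.cell_size ** 2
        assert any(pa.polygon.area < cell_area for pa in pas)

    def test_richness_biased_placement(self):
        cfg0 = small_cfg()
        cur, _ = make_predictor_stack(cfg0)
        land = cur.land_mask
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(4000 + rep)
            hint_vals = _smooth_field(rng, cur.grid.shape, cfg0.smooth_sigma)
            hint = cur.grid.like(hint_vals, mask=~land)
            cfg = small_cfg(seed=4000 + rep, n_pas=8,
                            pa_placement="richness-biased")
            pas = make_protected_areas(cfg, cur.grid, richness_hint=hint,
                                       land_mask=land)
            rows, cols = np.nonzero(land)
            xs, ys = cur.grid.cell_center(rows, cols)
            import shapely
            pts = shapely.points(xs, ys)
            inside = np.zeros(len(rows), dtype=bool)
            for pa in pas:
                inside |= shapely.covers(pa.polygon, pts)
            if inside.any():
                hits += hint_vals[rows[inside], cols[inside]].mean() > \
                    hint_vals[rows, cols].mean()
        assert hits >= 90

    def test_same_seed_identical(self):
        cfg = small_cfg()
        cur, _ = make_predictor_stack(cfg)
        a = make_protected_areas(cfg, cur.grid, land_mask=cur.land_mask)
        b = make_protected_areas(cfg, cur.grid, land_mask=cur.land_mask)
        assert [p.vertices for p in a] == [p.vertices for p in b]
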