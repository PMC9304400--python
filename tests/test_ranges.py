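import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from carnrec.ranges import (
    GridSpec,
    RangeFeature,
    RealmMap,
    altitude_mask,
    filter_features,
    rasterize,
    realm_proportions,
    richness,
)


def feat(sid="s", origin="native", presence="extant", cells=None, polygon=None):
    return RangeFeature(sid, origin=origin, presence=presence,
                        cells=frozenset(cells) if cells is not None else None,
                        polygon=polygon)


class TestFilterFeatures:
    @pytest.mark.parametrize(
        "origin,presence,kept",
        [
            ("native", "extant", True),
            ("reintroduced", "probably_extant", True),
            ("introduced", "extant", False),
            ("vagrant", "extant", False),
            ("native", "possibly_extinct", False),
            ("native", "extinct", False),
            ("uncertain", "uncertain", False),
        ],
    )
    def test_origin_presence_rules(self, origin, presence, kept):
        retained, _ = filter_features([feat(origin=origin, presence=presence, cells={(0, 0)})])
        assert bool(retained) == kept

    def test_species_losing_all_features_reported(self):
        features = [
            feat("keep", cells={(0, 0)}),
            feat("lost", origin="introduced", cells={(1, 1)}),
            feat("lost", presence="extinct", cells={(2, 2)}),
        ]
        retained, excluded = filter_features(features)
        assert [f.species_id for f in retained] == ["keep"]
        assert excluded == ["lost"]

    def test_empty_input(self):
        assert filter_features([]) == ([], [])


class TestRasterize:
    def test_rectangle_covering_four_cells(self):
        grid = GridSpec(4, 4)
        cells = rasterize(feat(polygon=box(0, 0, 2, 2)), grid)
        assert cells == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_full_grid_polygon(self):
        grid = GridSpec(3, 5)
        cells = rasterize(feat(polygon=box(0, 0, 5, 3)), grid)
        assert cells == {(r, c) for r in range(3) for c in range(5)}

    def test_random_polygon_matches_center_in_polygon_oracle(self):
        rng = np.random.default_rng(0)
        grid = GridSpec(12, 12)
        for _ in range(5):
            pts = rng.uniform(0, 12, size=(6, 2))
            poly = Polygon(pts).convex_hull
            got = rasterize(feat(polygon=poly), grid)
            brute = {
                (r, c)
                for r in range(12)
                for c in range(12)
                if poly.contains(Point(c + 0.5, r + 0.5))
            }
            assert got == brute

    def test_intersects_rule_superset_of_center_rule(self):
        grid = GridSpec(8, 8)
        poly = Polygon([(1.2, 1.2), (5.7, 1.9), (3.1, 6.4)])
        center = rasterize(feat(polygon=poly), grid, rule="center")
        inter = rasterize(feat(polygon=poly), grid, rule="intersects")
        assert center <= inter

    def test_polygon_outside_grid_empty_with_warning(self, caplog):
        grid = GridSpec(4, 4)
        with caplog.at_level("WARNING"):
            cells = rasterize(feat(polygon=box(10, 10, 12, 12)), grid)
        assert cells == set()
        assert any("outside grid" in m for m in caplog.messages)

    def test_explicit_cells_pass_through(self):
        grid = GridSpec(4, 4)
        assert rasterize(feat(cells={(1, 2), (3, 3)}), grid) == {(1, 2), (3, 3)}

    def test_out_of_bounds_cells_error(self):
        with pytest.raises(ValueError, match="outside grid"):
            rasterize(feat(cells={(9, 9)}), GridSpec(4, 4))


class TestAltitudeMask:
    def test_no_limits_is_identity(self):
        cells = {(0, 0), (1, 1)}
        elev = np.array([[100.0, 200.0], [300.0, 4000.0]])
        assert altitude_mask(cells, elev, None) == cells

    def test_limits_excluding_everything(self):
        cells = {(0, 0), (1, 1)}
        elev = np.array([[100.0, 200.0], [300.0, 400.0]])
        assert altitude_mask(cells, elev, (5000, 6000)) == set()

    def test_mixed_case_matches_brute_force(self):
        rng = np.random.default_rng(1)
        elev = rng.uniform(0, 3000, size=(10, 10))
        cells = {(r, c) for r in range(10) for c in range(10) if (r + c) % 3 == 0}
        lo, hi = 500.0, 2000.0
        got = altitude_mask(cells, elev, (lo, hi))
        brute = {(r, c) for (r, c) in cells if lo <= elev[r, c] <= hi}
        assert got == brute

    def test_masking_is_contraction(self):
        rng = np.random.default_rng(2)
        elev = rng.uniform(0, 1000, size=(6, 6))
        cells = {(r, c) for r in range(6) for c in range(6)}
        assert altitude_mask(cells, elev, (200, 800)) <= cells

    def test_open_ended_limits(self):
        elev = np.array([[100.0, 900.0]])
        cells = {(0, 0), (0, 1)}
        assert altitude_mask(cells, elev, (None, 500)) == {(0, 0)}
        assert altitude_mask(cells, elev, (500, None)) == {(0, 1)}


class TestRichness:
    def test_single_full_grid_species(self):
        grid = GridSpec(3, 3)
        layer = {(r, c) for r in range(3) for c in range(3)}
        counts = richness({"a": layer}, grid)
        np.testing.assert_array_equal(counts, np.ones((3, 3), dtype=int))

    def test_disjoint_ranges_max_one(self):
        grid = GridSpec(4, 4)
        counts = richness({"a": {(0, 0), (0, 1)}, "b": {(3, 3)}}, grid)
        assert counts.max() == 1
        assert counts.sum() == 3

    def test_double_counting_identity(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(9, 9)
        layers = {}
        for i in range(12):
            n = int(rng.integers(1, 20))
            layers[f"s{i}"] = {
                (int(rng.integers(0, 9)), int(rng.integers(0, 9))) for _ in range(n)
            }
        counts = richness(layers, grid)
        assert counts.sum() == sum(len(v) for v in layers.values())

    def test_additive_over_disjoint_subsets(self):
        grid = GridSpec(5, 5)
        layers = {"a": {(0, 0)}, "b": {(0, 0), (1, 1)}, "c": {(2, 2)}}
        full = richness(layers, grid)
        part = richness(layers, grid, subset=["a"]) + richness(layers, grid, subset=["b", "c"])
        np.testing.assert_array_equal(full, part)

    def test_subset_restricts_to_named_species(self):
        grid = GridSpec(2, 2)
        layers = {"a": {(0, 0)}, "b": {(0, 0)}}
        assert richness(layers, grid, subset=["a"])[0, 0] == 1

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="outside"):
            richness({"a": {(5, 5)}}, GridSpec(3, 3))


class TestRealmProportions:
    def _map(self):
        labels = np.array(
            [
                ["west", "west", "east", "east"],
                ["west", "west", "east", "east"],
                ["sea", "sea", "sea", "sea"],
            ],
            dtype=object,
        )
        types = {"west": "terrestrial", "east": "terrestrial", "sea": "marine"}
        return RealmMap(labels, types)

    def test_wholly_within_one_realm(self):
        props = realm_proportions({(0, 0), (1, 1)}, self._map(), {"terrestrial"})
        assert props == {"east": 0.0, "west": 1.0}

    def test_fifty_fifty_split(self):
        props = realm_proportions({(0, 0), (0, 3)}, self._map(), {"terrestrial"})
        assert props == {"east": 0.5, "west": 0.5}

    def test_marine_realms_only_for_marine_species(self):
        cells = {(0, 0), (2, 0)}
        terrestrial_view = realm_proportions(cells, self._map(), {"terrestrial"})
        marine_view = realm_proportions(cells, self._map(), {"marine"})
        assert set(terrestrial_view) == {"west", "east"}
        assert set(marine_view) == {"sea"}

    def test_proportions_sum_to_applicable_share(self):
        cells = {(0, 0), (0, 2), (2, 1), (2, 3)}
        props = realm_proportions(cells, self._map(), {"terrestrial", "marine"})
        assert sum(props.values()) == pytest.approx(1.0)

    def test_empty_cells_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert realm_proportions(set(), self._map(), {"marine"}) == {}
        assert any("empty" in m for m in caplog.messages)

    def test_unlabeled_realm_type_rejected(self):
        with pytest.raises(ValueError, match="realm type"):
            RealmMap(np.array([["x"]], dtype=object), {})
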