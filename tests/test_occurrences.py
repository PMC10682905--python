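import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nichekit.errors import InputError
from nichekit.grids import EnvStack, GridGeometry, Layer
from nichekit.occurrences import (
    EARTH_RADIUS_KM, OccurrenceSet, correlation_filter, expand_class,
    extract_env, haversine_km, split_train_test, thin,
)


def pts(*coords, cls="wild"):
    return OccurrenceSet.from_records(
        [(f"r{i}", lon, lat, cls, "test") for i, (lon, lat) in enumerate(coords)]
    )


def km_to_deg_lat(km: float) -> float:
    return math.degrees(km / EARTH_RADIUS_KM)


class TestClassLabels:
    def test_unions(self):
        assert expand_class("wild_sl") == ("wild", "semiwild")
        assert expand_class("cultivated") == ("landrace", "commercial")
        assert expand_class("wild") == ("wild",)
        with pytest.raises(InputError):
            expand_class("feral")

    def test_for_class_broad(self):
        occ = OccurrenceSet.from_records([
            ("a", 0, 0, "wild", "s"), ("b", 1, 0, "semiwild", "s"),
            ("c", 2, 0, "landrace", "s"), ("d", 3, 0, "commercial", "s"),
        ])
        assert len(occ.for_class("wild_sl")) == 2
        assert len(occ.for_class("cultivated")) == 2
        assert len(occ.for_class("landrace")) == 1

    def test_unique_ids_required(self):
        with pytest.raises(InputError):
            OccurrenceSet.from_records([("a", 0, 0, "wild", "s"), ("a", 1, 0, "wild", "s")])

    def test_coordinate_bounds(self):
        with pytest.raises(InputError):
            OccurrenceSet.from_records([("a", 500.0, 0, "wild", "s")])


class TestHaversine:
    def test_one_degree_latitude(self):
        # 1 degree of latitude = R * pi/180
        d = haversine_km(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(EARTH_RADIUS_KM * math.pi / 180.0, rel=1e-9)

    def test_symmetric(self):
        assert haversine_km(3, 4, 7, 9) == pytest.approx(haversine_km(7, 9, 3, 4))


class TestThin:
    def test_two_points_3km_apart(self):
        d = km_to_deg_lat(3.0)
        occ = pts((0.0, 0.0), (0.0, d))
        out = thin(occ, 5.0)
        assert len(out) == 1
        assert out.ids[0] == "r0"

    def test_min_dist_zero_identity(self):
        occ = pts((0, 0), (0, 1e-9), (0, 0))  # duplicate locations fine at d=0
        out = thin(occ, 0.0)
        assert len(out) == 3

    def test_collinear_0_4_8_km(self):
        d4, d8 = km_to_deg_lat(4.0), km_to_deg_lat(8.0)
        occ = pts((0.0, 0.0), (0.0, d4), (0.0, d8))
        out = thin(occ, 5.0)
        assert out.ids.tolist() == ["r0", "r2"]

    def test_output_pairwise_distances(self):
        rng = np.random.default_rng(0)
        occ = pts(*[(float(x), float(y)) for x, y in rng.uniform(0, 0.3, size=(60, 2))])
        out = thin(occ, 5.0)
        for i, j in itertools.combinations(range(len(out)), 2):
            assert haversine_km(out.lon[i], out.lat[i], out.lon[j], out.lat[j]) >= 5.0

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        occ = pts(*[(float(x), float(y)) for x, y in rng.uniform(0, 0.5, size=(80, 2))])
        once = thin(occ, 5.0)
        twice = thin(once, 5.0)
        assert once.ids.tolist() == twice.ids.tolist()

    def test_empty(self):
        out = thin(OccurrenceSet.empty(), 5.0)
        assert len(out) == 0

    def test_seeded_shuffle_variant(self):
        rng = np.random.default_rng(2)
        occ = pts(*[(float(x), float(y)) for x, y in rng.uniform(0, 0.3, size=(50, 2))])
        a = thin(occ, 5.0, seed=1)
        b = thin(occ, 5.0, seed=1)
        assert a.ids.tolist() == b.ids.tolist()


class TestExtractEnv:
    def test_constant_layer_value(self, geom_tiny, constant_layer):
        stack = EnvStack([constant_layer])
        occ = pts((0.25, 1.75))  # center of cell (0,0)
        out = extract_env(occ, stack)
        assert out.env[0, 0] == 7.0
        assert out.valid[0]

    def test_outside_grid_flagged(self, geom_tiny, constant_layer):
        stack = EnvStack([constant_layer])
        occ = pts((99.0, 0.0))
        out = extract_env(occ, stack)
        assert not out.valid[0]
        assert len(out.valid_env()) == 0

    def test_masked_cell_flagged(self, geom_tiny):
        mask = np.zeros(geom_tiny.shape, bool)
        mask[0, 0] = True
        stack = EnvStack([Layer("x", geom_tiny, np.ones(geom_tiny.shape), mask)])
        out = extract_env(pts((0.25, 1.75)), stack)
        assert not out.valid[0]

    def test_boundary_half_open_rule(self, geom_tiny):
        vals = np.arange(20, dtype=float).reshape(geom_tiny.shape)
        stack = EnvStack([Layer("x", geom_tiny, vals)])
        # left edge of col 1 (x=0.5) -> col 1; top edge of row 1 (y=1.5) -> row 0
        out = extract_env(pts((0.5, 1.75), (0.25, 1.5)), stack)
        assert out.env[0, 0] == vals[0, 1]
        assert out.env[1, 0] == vals[0, 0]
        # the grid's own top edge is excluded
        out2 = extract_env(pts((0.25, 2.0)), stack)
        assert not out2.valid[0]
        # grid bottom edge y=0 is included (row 3)
        out3 = extract_env(pts((0.25, 0.0)), stack)
        assert out3.valid[0] and out3.env[0, 0] == vals[3, 0]

    def test_matches_nearest_center_on_random_points(self):
        rng = np.random.default_rng(5)
        geom = GridGeometry(7, 9, -3.0, 4.0, 0.37)
        vals = rng.random(geom.shape)
        stack = EnvStack([Layer("x", geom, vals)])
        lon = rng.uniform(-3.0, -3.0 + 9 * 0.37, 200)
        lat = rng.uniform(4.0 - 7 * 0.37, 4.0, 200)
        occ = pts(*zip(lon, lat))
        out = extract_env(occ, stack)
        clon, clat = geom.cell_centers()
        for i in range(200):
            if not out.valid[i]:
                continue
            d2 = (clon - lon[i]) ** 2 + (clat - lat[i]) ** 2
            r, c = np.unravel_index(np.argmin(d2), d2.shape)
            assert out.env[i, 0] == vals[r, c]


class TestCorrelationFilter:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        kept = correlation_filter(df, 0.8)
        assert len(kept) == 1

    def test_identity_when_uncorrelated(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        kept = correlation_filter(df, 0.8)
        assert kept == list("abcd")

    def test_constant_variable_excluded(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=50), "k": np.ones(50)})
        kept = correlation_filter(df, 0.8)
        assert kept == ["a"]

    def test_keep_list_overrides(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x + 0.05 * rng.normal(size=300), "b": x})
        kept = correlation_filter(df, 0.8, keep=["b"])
        assert "b" in kept

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_subset_oracle(self, seed):
        """Greedy result satisfies the constraint and has maximal size
        among constraint-satisfying subsets (<= 6 variables)."""
        rng = np.random.default_rng(seed)
        n, p, thr = 300, 5, 0.7
        base = rng.normal(size=(n, p))
        X = base.copy()
        X[:, 1] = 0.95 * X[:, 0] + 0.3 * rng.normal(size=n)  # force one high pair
        names = [f"v{j}" for j in range(p)]
        kept = correlation_filter(X, thr, names=names)
        R = np.abs(np.corrcoef(X, rowvar=False))

        def ok(subset):
            return all(R[i, j] <= thr for i, j in itertools.combinations(subset, 2))

        kept_idx = [names.index(k) for k in kept]
        assert ok(kept_idx)
        best = max(
            (len(s) for r in range(p + 1) for s in itertools.combinations(range(p), r) if ok(s)),
            default=0,
        )
        assert len(kept) == best


class TestSplit:
    def test_sizes(self):
        occ = pts(*[(float(i) / 100, 0.0) for i in range(10)])
        train, test = split_train_test(occ, 0.3, seed=1)
        assert len(test) == 3 and len(train) == 7

    def test_disjoint_exhaustive(self):
        occ = pts(*[(float(i) / 100, 0.0) for i in range(23)])
        train, test = split_train_test(occ, 0.3, seed=2)
        ids = set(train.ids) | set(test.ids)
        assert len(ids) == 23
        assert not set(train.ids) & set(test.ids)

    def test_fraction_zero(self):
        occ = pts((0, 0), (0.01, 0))
        train, test = split_train_test(occ, 0.0, seed=1)
        assert len(test) == 0 and len(train) == 2

    def test_seed_reproducible(self):
        occ = pts(*[(float(i) / 100, 0.0) for i in range(20)])
        a = split_train_test(occ, 0.3, seed=7)
        b = split_train_test(occ, 0.3, seed=7)
        assert a[1].ids.tolist() == b[1].ids.tolist()

    def test_invalid_fraction(self):
        with pytest.raises(InputError):
            split_train_test(pts((0, 0)), 1.0, seed=1)


def test_csv_round_trip(tmp_path):
    occ = OccurrenceSet.from_records([
        ("a", 1.5, 2.5, "wild", "field"), ("b", -3.0, 4.0, "landrace", "db"),
    ])
    p = tmp_path / "occ.csv"
    occ.to_csv(p)
    again = OccurrenceSet.from_csv(p)
    assert again.ids.tolist() == ["a", "b"]
    np.testing.assert_allclose(again.lon, occ.lon)
    assert again.class_label.tolist() == ["wild", "landrace"]
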