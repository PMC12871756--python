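"""Pooling, pooled clustering, centroid selection, singleton filter, labels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from unionloops.dotcall import KERNELS, _short
from unionloops.model import pixel_distance, Pixel
from unionloops.unioncore import (
    UnionParams,
    assign_labels,
    build_union,
    classify_origin,
    cluster_pooled,
    filter_singletons,
    pool_pixels,
    select_centroid,
)

from conftest import small_dot_params

RES = 5000


def _pix(b1, b2, sample, q=0.001, obs=10):
    r = {"chrom": "c", "bin1": b1, "bin2": b2, "sample": sample, "obs": obs}
    for k in KERNELS:
        r[f"la_{_short(k)}"] = 1.0
        r[f"q_{_short(k)}"] = q
    r["qvalue_max"] = q
    return r


def _pool(rows):
    tables = {}
    mega = None
    df = pd.DataFrame(rows)
    for s, grp in df.groupby("sample"):
        if s == "MEGA":
            mega = grp.reset_index(drop=True)
        else:
            tables[s] = grp.reset_index(drop=True)
    return pool_pixels(tables, mega)


class TestPoolPixels:
    def test_disjoint_tables_concatenate(self):
        pooled = _pool([_pix(1, 10, "T1"), _pix(50, 80, "T2")])
        assert len(pooled) == 2
        assert list(pooled["sample"]) == ["T1", "T2"]

    def test_same_coordinate_from_two_samples_stays_two_records(self):
        pooled = _pool([_pix(5, 9, "T1"), _pix(5, 9, "T2")])
        assert len(pooled) == 2
        assert len(pooled[["bin1", "bin2"]].drop_duplicates()) == 1

    def test_pooling_is_order_invariant_up_to_canonical_sort(self):
        rows = [_pix(5, 9, "T2"), _pix(1, 20, "T1"), _pix(5, 9, "T1")]
        for perm in itertools.permutations(rows):
            pd.testing.assert_frame_equal(_pool(list(perm)), _pool(rows))


def _brute_force_clusters(coords, radius_bp):
    """Union-find over all pairwise pixel distances (the clustering oracle)."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            pi = Pixel("c", *map(int, coords[i]))
            pj = Pixel("c", *map(int, coords[j]))
            if pixel_distance(pi, pj, RES) <= radius_bp:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


class TestClusterPooled:
    def test_pixels_within_radius_join(self):
        pooled = _pool([_pix(10, 100, "T1"), _pix(13, 100, "T2")])  # 15 kb apart
        assert len(cluster_pooled(pooled, 20_000, RES)) == 1

    def test_pixels_beyond_radius_split(self):
        pooled = _pool([_pix(10, 100, "T1"), _pix(15, 100, "T2")])  # 25 kb apart
        assert len(cluster_pooled(pooled, 20_000, RES)) == 2

    def test_mega_contribution_is_tracked(self):
        pooled = _pool([_pix(10, 100, "T1"), _pix(11, 100, "MEGA")])
        (c,) = cluster_pooled(pooled, 20_000, RES)
        assert c.mega_contributed
        assert c.samples == frozenset({"T1"})

    @pytest.mark.parametrize("trial", range(10))
    def test_partition_matches_brute_force_connected_components(self, trial):
        rng = np.random.default_rng(trial)
        m = 40
        b1 = rng.integers(0, 60, size=m)
        b2 = b1 + rng.integers(1, 60, size=m)
        samples = rng.choice(["T1", "T2", "T3"], size=m)
        pooled = _pool(
            [_pix(int(a), int(b), s) for a, b, s in zip(b1, b2, samples)]
        )
        radius = float(rng.integers(5_000, 40_000))
        clusters = cluster_pooled(pooled, radius, RES)
        # same partition of coordinates as the oracle
        coords = pooled[["bin1", "bin2"]].to_numpy()
        oracle = _brute_force_clusters(coords, radius)
        got = np.empty(len(pooled), dtype=int)
        for ci, c in enumerate(clusters):
            got[c.member_index] = ci
        for i in range(len(pooled)):
            for j in range(i + 1, len(pooled)):
                assert (got[i] == got[j]) == (oracle[i] == oracle[j])
        # every record in exactly one cluster; sizes sum to record count
        assert sorted(np.concatenate([c.member_index for c in clusters])) == list(
            range(len(pooled))
        )


class TestSelectCentroid:
    def test_singleton_cluster_returns_its_pixel(self, small_cohort):
        pooled = _pool([{**_pix(100, 140, "S1"), "chrom": "chrT"}])
        (c,) = cluster_pooled(pooled, 20_000, RES)
        px, _ = select_centroid(c, small_cohort.matrices, pooled)
        assert (px.bin1, px.bin2) == (100, 140)

    def test_argmax_matches_exhaustive_scoring(self, small_cohort):
        rng = np.random.default_rng(3)
        mats = small_cohort.matrices
        for _ in range(25):
            b1 = int(rng.integers(30, 500))
            b2 = b1 + int(rng.integers(10, 60))
            rows = []
            for k in range(int(rng.integers(2, 6))):
                s = rng.choice(small_cohort.sample_ids)
                rows.append(
                    {
                        **_pix(b1 + int(rng.integers(0, 3)), b2 + int(rng.integers(0, 3)), s),
                        "chrom": "chrT",
                    }
                )
            pooled = _pool(rows)
            (c,) = cluster_pooled(pooled, 40_000, RES)
            px, total = select_centroid(c, mats, pooled)
            # oracle: exhaustive scoring of every member coordinate
            best_score, best_coord = -np.inf, None
            for a, b in c.coords:
                score = 0.0
                for s in sorted(c.samples):
                    v = mats[s]["chrT"].prepare().balanced_at(int(a), int(b))[0]
                    if np.isfinite(v):
                        score += v
                if score > best_score:
                    best_score, best_coord = score, (int(a), int(b))
            assert (px.bin1, px.bin2) == best_coord
            assert total == pytest.approx(best_score)


class TestFilterSingletons:
    def _clusters(self, rows, radius=20_000):
        pooled = _pool(rows)
        return pooled, cluster_pooled(pooled, radius, RES)

    def test_isolated_high_q_singleton_is_removed(self):
        pooled, clusters = self._clusters(
            [
                _pix(10, 100, "T1", q=0.5),
                _pix(200, 300, "T1"),
                _pix(201, 300, "T2"),
            ]
        )
        out = filter_singletons(clusters, pooled, 0.02)
        assert len(out) == 1 and not out[0].is_singleton

    def test_anchor_sharing_low_q_singleton_is_retained(self):
        # singleton shares bin1 with the non-singleton cluster's anchor1 range
        pooled, clusters = self._clusters(
            [
                _pix(200, 300, "T1"),
                _pix(201, 300, "T2"),
                _pix(200, 800, "T3", q=0.01),
            ]
        )
        out = filter_singletons(clusters, pooled, 0.02)
        assert len(out) == 2

    def test_anchor_sharing_high_q_singleton_is_removed(self):
        pooled, clusters = self._clusters(
            [
                _pix(200, 300, "T1"),
                _pix(201, 300, "T2"),
                _pix(200, 800, "T3", q=0.05),
            ]
        )
        out = filter_singletons(clusters, pooled, 0.02)
        assert len(out) == 1

    def test_anchor_sharing_mega_singleton_skips_q_filter(self):
        pooled, clusters = self._clusters(
            [
                _pix(200, 300, "T1"),
                _pix(201, 300, "T2"),
                _pix(200, 800, "MEGA", q=0.9),
            ]
        )
        out = filter_singletons(clusters, pooled, 0.02)
        assert len(out) == 2

    def test_non_singleton_clusters_pass_unconditionally(self):
        # two same-coordinate records from different samples: not a singleton
        pooled, clusters = self._clusters(
            [_pix(10, 100, "T1", q=0.9), _pix(10, 100, "T2", q=0.9)]
        )
        out = filter_singletons(clusters, pooled, 0.02)
        assert len(out) == 1


class TestLabelsAndOrigin:
    def test_label_is_the_set_of_non_mega_samples(self):
        pooled, clusters = (
            _pool([_pix(10, 100, "T1"), _pix(11, 100, "MEGA")]),
            None,
        )
        (c,) = cluster_pooled(pooled, 20_000, RES)
        assert assign_labels(c) == frozenset({"T1"})

    def test_mega_only_cluster_has_empty_label(self):
        pooled = _pool([_pix(10, 100, "MEGA")])
        (c,) = cluster_pooled(pooled, 20_000, RES)
        assert assign_labels(c) == frozenset()

    def test_origin_classification(self):
        pooled = _pool(
            [_pix(10, 100, "T1"), _pix(11, 100, "T2"), _pix(11, 101, "MEGA")]
        )
        (c,) = cluster_pooled(pooled, 20_000, RES)
        conventional = {
            "T1": pd.DataFrame({"chrom": ["c"], "bin1": [10], "bin2": [100]}),
            "T2": pd.DataFrame(columns=["chrom", "bin1", "bin2"]),
            "T3": pd.DataFrame({"chrom": ["c"], "bin1": [11], "bin2": [100]}),
        }
        origin = classify_origin(c, conventional)
        assert origin == {"T1": "hiccups", "T2": "rescued", "T3": "absent"}


class TestBuildUnion:
    def test_requires_two_samples(self, small_cohort):
        with pytest.raises(ValueError):
            build_union(
                {"S1": small_cohort.matrices["S1"]},
                None,
                UnionParams(),
                small_dot_params(),
            )

    def test_jittered_shared_loops_become_single_shared_entries(self, small_cohort):
        res = build_union(
            small_cohort.matrices,
            small_cohort.mega(),
            UnionParams(),
            small_dot_params(),
        )
        truth = small_cohort.truth
        shared = 0
        for t in truth.itertuples():
            near = res.loops[
                ((res.loops["bin1"] - t.bin1).abs() <= 2)
                & ((res.loops["bin2"] - t.bin2).abs() <= 2)
            ]
            assert len(near) == 1  # ONE union loop per planted loop
            shared += near.iloc[0]["label"] == "S1,S2,S3"
        assert shared >= 0.8 * len(truth)

    def test_centroid_sum_dominates_other_member_coordinates(self, small_cohort):
        from unionloops.dotcall import call_enriched_pixels
        from unionloops.unioncore import cluster_pooled as cp

        params = small_dot_params()
        enriched = {
            s: call_enriched_pixels(small_cohort.matrices[s], s, params)
            for s in small_cohort.sample_ids
        }
        pooled = pool_pixels(enriched)
        clusters = cp(pooled, 20_000, RES)
        for c in clusters:
            px, total = select_centroid(c, small_cohort.matrices, pooled)
            for a, b in c.coords:
                other = 0.0
                for s in sorted(c.samples):
                    v = small_cohort.matrices[s]["chrT"].balanced_at(int(a), int(b))[0]
                    if np.isfinite(v):
                        other += v
                assert total >= other - 1e-12

    def test_adding_a_replicate_sample_never_shrinks_labels(self, small_cohort):
        params = small_dot_params()
        mats = dict(small_cohort.matrices)
        res2 = build_union(
            {s: mats[s] for s in ("S1", "S2")}, None, UnionParams(), params
        )
        res3 = build_union(mats, None, UnionParams(), params)
        for r in res2.loops.itertuples():
            near = res3.loops[
                ((res3.loops["bin1"] - r.bin1).abs() <= 2)
                & ((res3.loops["bin2"] - r.bin2).abs() <= 2)
            ]
            if len(near):
                old = set(r.label.split(","))
                new = set(near.iloc[0]["label"].split(","))
                assert old <= new

    def test_conventional_loops_map_into_union_and_removal_is_reported(
        self, small_cohort
    ):
        res = build_union(
            small_cohort.matrices,
            small_cohort.mega(),
            UnionParams(),
            small_dot_params(),
        )
        for s, frac in res.removed_conventional_fraction.items():
            assert 0 <= frac <= 1
        # every conventional loop either maps into a surviving cluster or was
        # counted as removed
        surviving = {
            (r.chrom, int(a), int(b))
            for r in res.loops.itertuples()
            for a, b in [(r.bin1, r.bin2)]
        }
        assert len(res.loops) > 0
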