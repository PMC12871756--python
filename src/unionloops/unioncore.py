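"""The multi-sample union caller: pool, cluster once, fine-tune, label.

Enriched pixels from all samples (plus, optionally, the MEGA map formed by
merging every sample's raw counts) are pooled with provenance, clustered
once by bp radius, and each cluster is reduced to a single representative
pixel — the coordinate maximizing the summed balanced contacts over the
cluster's contributing sources.  Remaining singletons pass a two-step
filter: they must share an anchor with a non-singleton cluster, and
sample-specific singletons must additionally meet the stringent q-value
cutoff.  Surviving clusters are labeled with the set of biological samples
that contributed enriched pixels; the MEGA map contributes evidence and
signal but never labels.  Each labeled sample is classified as ``hiccups``
(its conventional, per-sample call falls inside the cluster) or ``rescued``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._clustering import radius_cluster_labels
from .contacts import ContactMatrix
from .dotcall import DotCallParams, call_enriched_pixels, conventional_cluster_and_filter
from .model import Pixel

__all__ = [
    "UnionParams",
    "PooledCluster",
    "UnionResult",
    "pool_pixels",
    "cluster_pooled",
    "select_centroid",
    "filter_singletons",
    "assign_labels",
    "classify_origin",
    "build_union",
]

logger = logging.getLogger(__name__)

MEGA_ID = "MEGA"


@dataclass(frozen=True)
class UnionParams:
    """Parameters of the union workflow."""

    resolution: int = 5000
    dots_clustering_radius: int = 20_000
    flank: int = 50_000
    singleton_qvalue_max: float = 0.02
    assembly_name: str = "unspecified"
    mega_id: str = MEGA_ID

    def __post_init__(self) -> None:
        if self.flank % self.resolution != 0:
            raise ValueError("flank must be a multiple of resolution")
        if self.dots_clustering_radius <= 0:
            raise ValueError("dots_clustering_radius must be > 0")


@dataclass
class PooledCluster:
    """A connected group of pooled enriched-pixel records."""

    chrom: str
    member_index: np.ndarray  # row indices into the pooled table
    coords: np.ndarray  # (k, 2) distinct member coordinates
    samples: frozenset[str]  # contributing non-MEGA samples
    mega_contributed: bool
    anchor1_range: tuple[int, int]  # [min bin1, max bin1]
    anchor2_range: tuple[int, int]

    @property
    def n_records(self) -> int:
        return len(self.member_index)

    @property
    def is_singleton(self) -> bool:
        return self.n_records == 1


@dataclass
class UnionResult:
    loops: pd.DataFrame
    mega_only: pd.DataFrame
    conventional: dict[str, pd.DataFrame]
    enriched: dict[str, pd.DataFrame]
    removed_conventional_fraction: dict[str, float]


# --------------------------------------------------------------------------- #


def pool_pixels(
    tables: dict[str, pd.DataFrame], mega_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Concatenate per-sample enriched-pixel tables, preserving provenance.

    Identical coordinates from different samples remain distinct records.
    Output is deterministically ordered by (chrom, bin1, bin2, sample).
    """
    pieces = []
    for sample in tables:
        t = tables[sample]
        if len(t) and (t["sample"] != sample).any():
            raise ValueError(f"table for {sample!r} carries foreign sample ids")
        pieces.append(t)
    if mega_table is not None:
        pieces.append(mega_table)
    pooled = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    if len(pooled) == 0:
        return pooled
    return pooled.sort_values(
        ["chrom", "bin1", "bin2", "sample"], kind="mergesort"
    ).reset_index(drop=True)


def cluster_pooled(
    pooled: pd.DataFrame, radius_bp: float, resolution: int, mega_id: str = MEGA_ID
) -> list[PooledCluster]:
    """Cluster pooled records by coordinate at a bp radius, per chromosome.

    Records sharing one coordinate sit on one node of the radius graph; every
    record belongs to exactly one cluster.
    """
    clusters: list[PooledCluster] = []
    if len(pooled) == 0:
        return clusters
    for chrom, grp in pooled.groupby("chrom", sort=True):
        coords = grp[["bin1", "bin2"]].to_numpy()
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        labels_u = radius_cluster_labels(uniq[:, 0], uniq[:, 1], radius_bp, resolution)
        labels = labels_u[inverse]
        idx = grp.index.to_numpy()
        samples = grp["sample"].to_numpy()
        for lab in np.unique(labels):
            sel = labels == lab
            member_coords = np.unique(coords[sel], axis=0)
            member_samples = set(samples[sel])
            clusters.append(
                PooledCluster(
                    chrom=chrom,
                    member_index=idx[sel],
                    coords=member_coords,
                    samples=frozenset(member_samples - {mega_id}),
                    mega_contributed=mega_id in member_samples,
                    anchor1_range=(int(coords[sel, 0].min()), int(coords[sel, 0].max())),
                    anchor2_range=(int(coords[sel, 1].min()), int(coords[sel, 1].max())),
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.anchor1_range[0], c.anchor2_range[0]))
    return clusters


def select_centroid(
    cluster: PooledCluster,
    matrices: dict[str, dict[str, ContactMatrix]],
    pooled: pd.DataFrame | None = None,
    mega_id: str = MEGA_ID,
) -> tuple[Pixel, float]:
    """Representative pixel: argmax of summed balanced contacts.

    The score of each distinct member coordinate is the sum, over the
    cluster's contributing sources (its samples, plus MEGA if it
    contributed), of the balanced value at that coordinate; missing values
    are skipped.  Ties break to the smallest (bin1, bin2).  If every score is
    missing, the member with maximal observed raw count is used instead.
    """
    sources = sorted(cluster.samples) + (
        [mega_id] if cluster.mega_contributed and mega_id in matrices else []
    )
    b1 = cluster.coords[:, 0]
    b2 = cluster.coords[:, 1]
    total = np.zeros(len(b1))
    any_defined = np.zeros(len(b1), dtype=bool)
    for s in sources:
        m = matrices[s][cluster.chrom].prepare()
        vals = m.balanced_at(b1, b2)
        good = np.isfinite(vals)
        total[good] += vals[good]
        any_defined |= good
    if any_defined.any():
        score = np.where(any_defined, total, -np.inf)
        best = int(np.argmax(score))  # coords sorted lexicographically: first max
        return Pixel(cluster.chrom, int(b1[best]), int(b2[best])), float(total[best])
    # degenerate: no balanced signal anywhere — fall back to max observed
    logger.warning(
        "cluster at %s:%d-%d has no defined balanced values; falling back to "
        "max observed count",
        cluster.chrom,
        b1[0],
        b2[0],
    )
    if pooled is None:
        return Pixel(cluster.chrom, int(b1[0]), int(b2[0])), float("nan")
    members = pooled.loc[cluster.member_index]
    members = members.sort_values(["obs", "bin1", "bin2"], ascending=[False, True, True])
    row = members.iloc[0]
    return Pixel(cluster.chrom, int(row["bin1"]), int(row["bin2"])), float("nan")


def filter_singletons(
    clusters: list[PooledCluster],
    pooled: pd.DataFrame,
    singleton_qvalue_max: float,
    mega_id: str = MEGA_ID,
    anchor_slack_bins: int = 0,
) -> list[PooledCluster]:
    """Two-step singleton filter; non-singleton clusters pass unconditionally.

    A singleton survives iff (a) one of its anchors falls within the
    same-axis anchor range of some non-singleton cluster on its chromosome,
    and (b) when its sole member comes from a biological (non-MEGA) sample,
    that member's ``qvalue_max`` is at or below the stringent cutoff.
    """
    non_singletons = [c for c in clusters if not c.is_singleton]
    ranges: dict[str, list[tuple[tuple[int, int], tuple[int, int]]]] = {}
    for c in non_singletons:
        ranges.setdefault(c.chrom, []).append((c.anchor1_range, c.anchor2_range))
    out = []
    for c in clusters:
        if not c.is_singleton:
            out.append(c)
            continue
        b1, b2 = int(c.coords[0, 0]), int(c.coords[0, 1])
        shares = False
        for (lo1, hi1), (lo2, hi2) in ranges.get(c.chrom, []):
            if (lo1 - anchor_slack_bins <= b1 <= hi1 + anchor_slack_bins) or (
                lo2 - anchor_slack_bins <= b2 <= hi2 + anchor_slack_bins
            ):
                shares = True
                break
        if not shares:
            continue
        member = pooled.loc[c.member_index[0]]
        if member["sample"] != mega_id and member["qvalue_max"] > singleton_qvalue_max:
            continue
        out.append(c)
    return out


def assign_labels(cluster: PooledCluster) -> frozenset[str]:
    """Specificity label: the set of contributing non-MEGA samples."""
    return cluster.samples


def classify_origin(
    cluster: PooledCluster,
    conventional: dict[str, pd.DataFrame],
) -> dict[str, str]:
    """Per-sample origin: hiccups / rescued for labeled samples, absent otherwise.

    A sample is ``hiccups`` when one of its final conventional loop calls has
    coordinates equal to some member coordinate of the cluster.
    """
    member_set = {(int(a), int(b)) for a, b in cluster.coords}
    origin = {}
    for s, calls in conventional.items():
        if s not in cluster.samples:
            origin[s] = "absent"
            continue
        sub = calls[calls["chrom"] == cluster.chrom]
        hit = any(
            (int(r.bin1), int(r.bin2)) in member_set for r in sub.itertuples()
        )
        origin[s] = "hiccups" if hit else "rescued"
    return origin


# --------------------------------------------------------------------------- #


def build_union(
    matrices: dict[str, dict[str, ContactMatrix]],
    mega: dict[str, ContactMatrix] | None,
    params: UnionParams,
    dot_params: DotCallParams,
    enriched: dict[str, pd.DataFrame] | None = None,
    conventional: dict[str, pd.DataFrame] | None = None,
) -> UnionResult:
    """End-to-end union workflow over a cohort of related Hi-C samples.

    Per-sample enriched pixels (and MEGA's, if a merged map is supplied) are
    pooled, clustered once, singleton-filtered, reduced to centroid pixels,
    labeled, and classified against the conventional per-sample calls made
    with identical parameters.  ``enriched``/``conventional`` may carry
    precomputed tables (keyed by sample; MEGA under ``params.mega_id``) to
    skip recomputation.
    """
    sample_ids = sorted(matrices)
    if len(sample_ids) < 2:
        raise ValueError("build_union requires at least 2 samples")
    resolutions = {
        m.chrom.resolution for per in matrices.values() for m in per.values()
    }
    if mega:
        resolutions |= {m.chrom.resolution for m in mega.values()}
    if len(resolutions) != 1:
        raise ValueError(f"mixed resolutions across inputs: {sorted(resolutions)}")
    if params.resolution not in resolutions:
        raise ValueError(
            f"params.resolution={params.resolution} does not match matrices "
            f"({sorted(resolutions)})"
        )

    if enriched is None:
        enriched = {}
    enriched = dict(enriched)
    for s in sample_ids:
        if s not in enriched:
            enriched[s] = call_enriched_pixels(matrices[s], s, dot_params)
    mega_table = None
    if mega is not None:
        if params.mega_id not in enriched:
            enriched[params.mega_id] = call_enriched_pixels(
                mega, params.mega_id, dot_params
            )
        mega_table = enriched[params.mega_id]

    if conventional is None:
        conventional = {}
    conventional = dict(conventional)
    for s in sample_ids:
        if s not in conventional:
            conventional[s] = conventional_cluster_and_filter(
                enriched[s], matrices[s], dot_params
            )

    pooled = pool_pixels({s: enriched[s] for s in sample_ids}, mega_table)
    clusters = cluster_pooled(
        pooled, params.dots_clustering_radius, params.resolution, params.mega_id
    )
    surviving = filter_singletons(
        clusters, pooled, params.singleton_qvalue_max, params.mega_id
    )

    lookup = dict(matrices)
    if mega is not None:
        lookup[params.mega_id] = mega

    rows = []
    mega_rows = []
    surviving_coords: dict[str, set[tuple[int, int]]] = {}
    for c in surviving:
        surviving_coords.setdefault(c.chrom, set()).update(
            (int(a), int(b)) for a, b in c.coords
        )
        centroid, csum = select_centroid(c, lookup, pooled, params.mega_id)
        label = assign_labels(c)
        base = {
            "chrom": c.chrom,
            "bin1": centroid.bin1,
            "bin2": centroid.bin2,
            "cluster_size": c.n_records,
            "is_singleton": c.is_singleton,
            "centroid_sum": csum,
        }
        if not label:
            # MEGA-only cluster: side table, no specificity label
            mega_rows.append(base)
            continue
        origin = classify_origin(c, conventional)
        row = dict(base)
        row["label"] = ",".join(sorted(label))
        for s in sample_ids:
            row[f"origin_{s}"] = origin.get(s, "absent")
        rows.append(row)

    cols = (
        ["chrom", "bin1", "bin2", "label"]
        + [f"origin_{s}" for s in sample_ids]
        + ["cluster_size", "is_singleton", "centroid_sum"]
    )
    loops = pd.DataFrame(rows, columns=cols)
    if len(loops):
        loops = loops.sort_values(["chrom", "bin1", "bin2"], kind="mergesort").reset_index(
            drop=True
        )
    mega_only = pd.DataFrame(
        mega_rows,
        columns=["chrom", "bin1", "bin2", "cluster_size", "is_singleton", "centroid_sum"],
    )

    # conservation report: conventional loops dropped by the singleton filter
    removed = {}
    for s in sample_ids:
        calls = conventional[s]
        if len(calls) == 0:
            removed[s] = 0.0
            continue
        lost = 0
        for r in calls.itertuples():
            if (int(r.bin1), int(r.bin2)) not in surviving_coords.get(r.chrom, set()):
                lost += 1
        removed[s] = lost / len(calls)

    return UnionResult(
        loops=loops,
        mega_only=mega_only,
        conventional=conventional,
        enriched=enriched,
        removed_conventional_fraction=removed,
    )
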