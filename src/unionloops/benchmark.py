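"""Baselines and evaluation: exact-match union, refinement strategies, scoring.

The conventional baseline labels specificity by exact coordinate matches of
final per-sample loop calls.  Two alternative multi-sample refinement
strategies are provided for controlled comparison against the union caller:
the Mariner-style rule (cluster final calls, pick the member with the
maximum value in any single sample) and the intermediate rule (same
clustering, pick the member with the maximum sum of values across samples).
Truth-based scoring matches calls to planted loops greedily, nearest first,
by Chebyshev bin distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._clustering import radius_cluster_labels
from .contacts import ContactMatrix
from .model import PeakInterval

__all__ = [
    "TruthScore",
    "conventional_union",
    "mariner_style_refine",
    "intermediate_refine",
    "anchor_overlap_fraction",
    "specificity_tally",
    "evaluate_against_truth",
]


@dataclass
class TruthScore:
    recall: float
    precision: float
    median_offset_bins: float
    specificity_accuracy: float
    n_truth: int
    n_calls: int
    n_matched: int


# --------------------------------------------------------------------------- #


def conventional_union(calls_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Exact-coordinate union of final per-sample loop calls, with labels.

    Loops group iff both anchors match exactly; the label is the set of
    samples containing that exact loop (comma-joined, sorted).
    """
    pieces = []
    for sample in sorted(calls_by_sample):
        t = calls_by_sample[sample]
        if len(t) == 0:
            continue
        sub = t[["chrom", "bin1", "bin2"]].copy()
        sub["sample"] = sample
        pieces.append(sub)
    if not pieces:
        return pd.DataFrame(columns=["chrom", "bin1", "bin2", "label"])
    pooled = pd.concat(pieces, ignore_index=True)
    grouped = (
        pooled.groupby(["chrom", "bin1", "bin2"], sort=True)["sample"]
        .apply(lambda s: ",".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"sample": "label"})
    )
    return grouped


def _refine(
    calls_by_sample: dict[str, pd.DataFrame],
    matrices: dict[str, dict[str, ContactMatrix]] | None,
    radius_bp: float,
    resolution: int,
    mode: str,
) -> pd.DataFrame:
    samples = sorted(calls_by_sample)
    pieces = []
    for s in samples:
        t = calls_by_sample[s]
        if len(t) == 0:
            continue
        sub = t[["chrom", "bin1", "bin2"]].copy()
        if matrices is None:
            if "value" not in t.columns:
                raise ValueError(
                    "refinement without matrices requires a 'value' column"
                )
            sub["value"] = t["value"].to_numpy()
        sub["sample"] = s
        pieces.append(sub)
    if not pieces:
        return pd.DataFrame(columns=["chrom", "bin1", "bin2", "cluster_size"])
    pooled = pd.concat(pieces, ignore_index=True)

    rows = []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        coords = grp[["bin1", "bin2"]].to_numpy()
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        labels_u = radius_cluster_labels(uniq[:, 0], uniq[:, 1], radius_bp, resolution)

        # per distinct coordinate, value in every sample
        if matrices is not None:
            vals = np.full((len(uniq), len(samples)), np.nan)
            for si, s in enumerate(samples):
                m = matrices[s][chrom].prepare()
                v = m.balanced_at(uniq[:, 0], uniq[:, 1])
                vals[:, si] = v
        else:
            vals = np.full((len(uniq), len(samples)), np.nan)
            gi = grp.reset_index(drop=True)
            for k, row in enumerate(gi.itertuples()):
                vals[inverse[k], samples.index(row.sample)] = row.value

        with np.errstate(invalid="ignore"):
            if mode == "max_single":
                score = np.nanmax(np.where(np.isfinite(vals), vals, -np.inf), axis=1)
            else:  # max_sum
                score = np.nansum(np.where(np.isfinite(vals), vals, 0.0), axis=1)
                allnan = ~np.isfinite(vals).any(axis=1)
                score[allnan] = -np.inf
        for lab in np.unique(labels_u):
            members = np.flatnonzero(labels_u == lab)
            # uniq is lexicographically sorted, so the first max wins ties
            best = members[np.argmax(score[members])]
            rows.append(
                {
                    "chrom": chrom,
                    "bin1": int(uniq[best, 0]),
                    "bin2": int(uniq[best, 1]),
                    "cluster_size": int(
                        sum(labels_u[inverse[k]] == lab for k in range(len(inverse)))
                    ),
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "cluster_size"])
    return out.sort_values(["chrom", "bin1", "bin2"], kind="mergesort").reset_index(
        drop=True
    )


def mariner_style_refine(
    calls_by_sample: dict[str, pd.DataFrame],
    matrices: dict[str, dict[str, ContactMatrix]] | None,
    radius_bp: float,
    resolution: int,
) -> pd.DataFrame:
    """Cluster final calls; representative = max value in any single sample."""
    return _refine(calls_by_sample, matrices, radius_bp, resolution, "max_single")


def intermediate_refine(
    calls_by_sample: dict[str, pd.DataFrame],
    matrices: dict[str, dict[str, ContactMatrix]] | None,
    radius_bp: float,
    resolution: int,
) -> pd.DataFrame:
    """Cluster final calls; representative = max sum of values across samples."""
    return _refine(calls_by_sample, matrices, radius_bp, resolution, "max_sum")


# --------------------------------------------------------------------------- #


def anchor_overlap_fraction(
    loops: pd.DataFrame, peaks: list[PeakInterval], resolution: int
) -> float:
    """Fraction of loop anchors overlapping at least one peak (half-open).

    Each loop contributes two anchors (resolution-sized intervals); an anchor
    overlaps iff some peak intersects it by >= 1 bp.
    """
    if len(loops) == 0:
        return float("nan")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        sub = sorted(
            ((p.start_bp, p.end_bp) for p in peaks if p.chrom == chrom),
        )
        starts = np.array([s for s, _ in sub])
        ends = np.array([e for _, e in sub])
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    hits = 0
    total = 0
    for r in loops.itertuples():
        for b in (r.bin1, r.bin2):
            total += 1
            a_start = int(b) * resolution
            a_end = a_start + resolution
            if r.chrom not in by_chrom:
                continue
            starts, cummax_ends = by_chrom[r.chrom]
            k = np.searchsorted(starts, a_end, side="left")  # peaks with start < a_end
            if k > 0 and cummax_ends[k - 1] > a_start:
                hits += 1
    return hits / total


def specificity_tally(union_loops: pd.DataFrame) -> tuple[dict, dict]:
    """Counts of union loops per sample-subset, plus per-sample totals.

    Returns ``(subset_counts, per_sample_totals)`` where subset keys are
    frozensets of sample ids; a sample's total is the number of loops whose
    label contains it.
    """
    subset_counts: dict[frozenset, int] = {}
    totals: dict[str, int] = {}
    for lab in union_loops.get("label", pd.Series(dtype=str)):
        subset = frozenset(lab.split(","))
        subset_counts[subset] = subset_counts.get(subset, 0) + 1
        for s in subset:
            totals[s] = totals.get(s, 0) + 1
    return subset_counts, totals


def evaluate_against_truth(
    calls: pd.DataFrame, truth: pd.DataFrame, tolerance_bins: int
) -> TruthScore:
    """Greedy one-to-one matching of calls to planted loops, nearest first.

    Distance is Chebyshev in bins between the call pixel and the planted
    (base) pixel; only pairs within ``tolerance_bins`` can match.  Label
    accuracy compares the call's ``label`` to the planted ``presence`` set
    where both columns exist.
    """
    n_truth = len(truth)
    n_calls = len(calls)
    if n_truth == 0 or n_calls == 0:
        return TruthScore(0.0, 0.0, float("nan"), float("nan"), n_truth, n_calls, 0)
    pairs = []
    for t_i, t in enumerate(truth.itertuples()):
        sub = calls[calls["chrom"] == t.chrom]
        d = np.maximum(
            np.abs(sub["bin1"].to_numpy() - int(t.bin1)),
            np.abs(sub["bin2"].to_numpy() - int(t.bin2)),
        )
        for k, c_i in enumerate(sub.index):
            if d[k] <= tolerance_bins:
                pairs.append((int(d[k]), c_i, t_i))
    pairs.sort()
    used_c: set = set()
    used_t: set = set()
    matched = []
    for d, c_i, t_i in pairs:
        if c_i in used_c or t_i in used_t:
            continue
        used_c.add(c_i)
        used_t.add(t_i)
        matched.append((d, c_i, t_i))
    n_matched = len(matched)
    offsets = [d for d, _, _ in matched]
    spec_acc = float("nan")
    if "label" in calls.columns and "presence" in truth.columns and n_matched:
        correct = 0
        for _, c_i, t_i in matched:
            call_label = frozenset(str(calls.loc[c_i, "label"]).split(","))
            true_label = frozenset(str(truth.iloc[t_i]["presence"]).split(","))
            correct += call_label == true_label
        spec_acc = correct / n_matched
    return TruthScore(
        recall=n_matched / n_truth,
        precision=n_matched / n_calls,
        median_offset_bins=float(np.median(offsets)) if offsets else float("nan"),
        specificity_accuracy=spec_acc,
        n_truth=n_truth,
        n_calls=n_calls,
        n_matched=n_matched,
    )
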