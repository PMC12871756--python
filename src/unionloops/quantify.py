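"""Loop-level signal aggregation: pileups, strength, stackups, 1-D signal grids.

All windows are square snippets of the balanced contact matrix centered on a
loop pixel, of side ``2 * flank / resolution + 1`` (21 x 21 at 5 kb with a
50 kb flank).  Loop strength is the mean of the central 3 x 3 block divided
by the pooled mean of three 6 x 6 corner blocks (upper-left, upper-right,
lower-right); the lower-left corner is excluded because it sits at shorter
genomic distance, inside the loop, where background contact frequency is
inflated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, extract_snippet
from .model import Pixel

__all__ = [
    "pileup",
    "loop_strength",
    "strength_table",
    "stackup",
    "pairwise_signal_matrix",
    "zscore_matrix",
]


def _windows(loops: pd.DataFrame, m: ContactMatrix, flank_bp: int):
    for r in loops.itertuples():
        yield extract_snippet(m, Pixel(m.chrom.name, int(r.bin1), int(r.bin2)), flank_bp)


def pileup(
    loops: pd.DataFrame, m: ContactMatrix, flank_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean over the stack of loop windows.

    Returns ``(mean_window, valid_counts)``; cells with zero valid
    observations are NaN.  An empty loop list yields an all-NaN window.
    """
    m.prepare()
    side = 2 * (flank_bp // m.chrom.resolution) + 1
    acc = np.zeros((side, side))
    cnt = np.zeros((side, side), dtype=int)
    for w in _windows(loops, m, flank_bp):
        good = np.isfinite(w)
        acc[good] += w[good]
        cnt += good
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return mean, cnt


def loop_strength(
    window: np.ndarray, center_size: int = 3, corner_size: int = 6
) -> float:
    """Center-over-corner enrichment ratio of one loop window.

    ``center_size x center_size`` central block mean divided by the pooled
    mean of three ``corner_size x corner_size`` blocks at the upper-left,
    upper-right and lower-right corners (rows = upstream anchor increasing
    downward).  Returns NaN when the background is zero or all-missing.
    """
    side = window.shape[0]
    if window.shape[0] != window.shape[1] or side % 2 == 0:
        raise ValueError("window must be square with odd side")
    c = side // 2
    h = center_size // 2
    center = window[c - h : c + h + 1, c - h : c + h + 1]
    k = corner_size
    corners = [
        window[:k, :k],  # upper-left
        window[:k, side - k :],  # upper-right
        window[side - k :, side - k :],  # lower-right
    ]
    bg = np.concatenate([b.ravel() for b in corners])
    center_mean = np.nanmean(center) if np.isfinite(center).any() else np.nan
    bg_mean = np.nanmean(bg) if np.isfinite(bg).any() else np.nan
    if not np.isfinite(bg_mean) or bg_mean <= 0 or not np.isfinite(center_mean):
        return float("nan")
    return float(center_mean / bg_mean)


def strength_table(
    loops: pd.DataFrame,
    matrices: dict[str, dict[str, ContactMatrix]],
    flank_bp: int,
) -> pd.DataFrame:
    """Per-loop, per-sample strength with center/background means.

    One row per loop per sample; strength is NaN where the window is
    truncated into an undefined background (e.g. at chromosome edges).
    """
    rows = []
    for sample in sorted(matrices):
        per_chrom = matrices[sample]
        for chrom, grp in loops.groupby("chrom", sort=True):
            m = per_chrom[chrom].prepare()
            for r in grp.itertuples():
                w = extract_snippet(
                    m, Pixel(chrom, int(r.bin1), int(r.bin2)), flank_bp
                )
                s = loop_strength(w)
                side = w.shape[0]
                c, k = side // 2, 6
                center = w[c - 1 : c + 2, c - 1 : c + 2]
                bg = np.concatenate(
                    [
                        w[:k, :k].ravel(),
                        w[:k, side - k :].ravel(),
                        w[side - k :, side - k :].ravel(),
                    ]
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "bin1": int(r.bin1),
                        "bin2": int(r.bin2),
                        "sample": sample,
                        "strength": s,
                        "center_mean": float(np.nanmean(center))
                        if np.isfinite(center).any()
                        else np.nan,
                        "background_mean": float(np.nanmean(bg))
                        if np.isfinite(bg).any()
                        else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "bin1",
            "bin2",
            "sample",
            "strength",
            "center_mean",
            "background_mean",
        ],
    )


def stackup(loops: pd.DataFrame, m: ContactMatrix, flank_bp: int) -> np.ndarray:
    """Middle rows of loop windows, sorted by the mean of the middle four bins.

    Row i of the result is the middle row (the flanked upstream anchor) of
    one loop's window; rows are sorted descending by the mean of columns
    ``W//2 - 2 .. W//2 + 1`` (0-based, W = side length).
    """
    m.prepare()
    side = 2 * (flank_bp // m.chrom.resolution) + 1
    rows = np.array([w[side // 2] for w in _windows(loops, m, flank_bp)]).reshape(
        -1, side
    )
    mid = slice(side // 2 - 2, side // 2 + 2)
    with np.errstate(invalid="ignore"):
        keys = np.nanmean(rows[:, mid], axis=1) if len(rows) else np.empty(0)
    keys = np.where(np.isfinite(keys), keys, -np.inf)
    order = np.argsort(-keys, kind="stable")
    return rows[order]


def pairwise_signal_matrix(row_signal: np.ndarray, col_signal: np.ndarray) -> np.ndarray:
    """Outer sum of two per-bin 1-D signal vectors, halved.

    ``M[i, j] = (row_signal[i] + col_signal[j]) / 2`` — the pairwise average
    of e.g. CTCF coverage at the two anchors of each window cell.
    """
    r = np.asarray(row_signal, dtype=float)
    c = np.asarray(col_signal, dtype=float)
    if r.ndim != 1 or c.ndim != 1:
        raise ValueError("signals must be 1-D vectors")
    return (r[:, None] + c[None, :]) / 2.0


def zscore_matrix(matrix: np.ndarray) -> np.ndarray:
    """Element-wise z-score over defined cells (population sd).

    A constant (zero-spread) matrix returns zeros with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    good = np.isfinite(m)
    vals = m[good]
    if vals.size < 2:
        raise ValueError("need >= 2 defined cells to z-score")
    mu = vals.mean()
    sd = vals.std()  # population convention
    out = np.full(m.shape, np.nan)
    if sd == 0:
        import warnings

        warnings.warn("constant matrix: z-scores set to 0", stacklevel=2)
        out[good] = 0.0
        return out
    out[good] = (m[good] - mu) / sd
    return out
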