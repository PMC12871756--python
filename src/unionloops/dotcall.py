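"""Per-sample enriched-pixel detection and the conventional loop-call baseline.

Stage 1 scores every tested pixel against four local-expected models
(donut, lower-left, horizontal, vertical): each kernel's expected rate is

    lambda_k = E(d) * sum_footprint(B) / sum_footprint(E) / (w_i * w_j)

in raw-count units, where B is the balanced matrix, E the per-distance
expected, and w the balancing weights.  Poisson upper-tail p-values are
corrected with Benjamini-Hochberg within geometric lambda chunks (edges at
powers of 2^(1/3), everything below 1 pooled into an underflow chunk).  A
pixel is enriched iff its q-value passes the FDR level under all four
kernels.

Stage 2-3 (the conventional, single-sample branch) clusters a sample's
enriched pixels at a bp radius, takes the member with maximal balanced value
as the cluster centroid, and applies the empirical filters: centroid
enrichment ratios against donut/lower-left and horizontal/vertical, plus a
stringent q-value cutoff for singletons.

Kernel geometry follows the HiCCUPS convention: the donut covers Chebyshev
radius (p, w] minus the width-1 row and column through the center; the
lower-left kernel is the quadrant toward the diagonal (du in 1..w,
dv in -w..-1) minus its inner p x p corner; the horizontal/vertical kernels
are bands of half-width 1 with extent (p, w] along one axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammainc
from statsmodels.stats.multitest import multipletests

from ._clustering import radius_cluster_labels
from .contacts import ContactMatrix

__all__ = [
    "KERNELS",
    "DotCallParams",
    "kernel_offsets",
    "kernel_lambda",
    "score_pixels",
    "lambda_binned_fdr",
    "call_enriched_pixels",
    "conventional_cluster_and_filter",
]

KERNELS = ("donut", "lower_left", "horizontal", "vertical")


@dataclass(frozen=True)
class DotCallParams:
    """Parameters of the enriched-pixel caller and the conventional filter.

    Defaults mirror the standard HiCCUPS settings: FDR 0.1 per lambda chunk,
    10 Mb maximum anchor separation, 5 Mb scoring tiles, at most 4 missing
    cells per kernel footprint, 20 kb clustering radius.  The kernel
    half-widths default to (p, w) = (4, 7) at 5 kb resolution and (2, 5) at
    10 kb and coarser; the empirical-filter thresholds (1.75 donut/lower-left,
    1.5 horizontal/vertical, singleton q <= 0.02) follow the reference
    convention and are fully configurable.
    """

    lambda_bin_fdr: float = 0.1
    max_loci_separation: int = 10_000_000
    tile_size: int = 5_000_000
    max_nans_tolerated: int = 4
    kernel_p: int | None = None
    kernel_w: int | None = None
    clustering_radius: int = 20_000
    singleton_qvalue_max: float = 0.02
    enrichment_d_and_ll: float = 1.75
    enrichment_vh: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.lambda_bin_fdr < 1):
            raise ValueError("lambda_bin_fdr must be in (0, 1)")
        if self.clustering_radius <= 0:
            raise ValueError("clustering_radius must be > 0")
        if self.enrichment_d_and_ll < 1 or self.enrichment_vh < 1:
            raise ValueError("enrichment ratio thresholds must be >= 1")
        p, w = self.kernel_p, self.kernel_w
        if p is not None and w is not None and p >= w:
            raise ValueError("kernel_p must be < kernel_w")

    def resolved_kernels(self, resolution: int) -> tuple[int, int]:
        """Kernel half-widths (p, w), resolution-dependent unless overridden."""
        p, w = self.kernel_p, self.kernel_w
        if p is None or w is None:
            dp, dw = (4, 7) if resolution <= 5000 else (2, 5)
            p = dp if p is None else p
            w = dw if w is None else w
        if p >= w:
            raise ValueError("kernel_p must be < kernel_w")
        return p, w


# --------------------------------------------------------------------------- #
# kernel geometry


def kernel_offsets(kernel: str, p: int, w: int) -> np.ndarray:
    """Explicit (du, dv) footprint offsets of a kernel (excludes the center)."""
    offs = []
    for du in range(-w, w + 1):
        for dv in range(-w, w + 1):
            cheb = max(abs(du), abs(dv))
            if kernel == "donut":
                if p < cheb <= w and du != 0 and dv != 0:
                    offs.append((du, dv))
            elif kernel == "lower_left":
                if 1 <= du <= w and -w <= dv <= -1 and not (du <= p and dv >= -p):
                    offs.append((du, dv))
            elif kernel == "horizontal":
                if abs(du) <= 1 and p < abs(dv) <= w:
                    offs.append((du, dv))
            elif kernel == "vertical":
                if p < abs(du) <= w and abs(dv) <= 1:
                    offs.append((du, dv))
            else:
                raise ValueError(f"unknown kernel {kernel!r}")
    return np.array(offs, dtype=int)


def _kernel_rects(kernel: str, p: int, w: int):
    """Signed axis-aligned rectangles whose union-with-signs equals the kernel.

    Each entry is (du_lo, du_hi, dv_lo, dv_hi, sign), inclusive bounds.
    """
    if kernel == "donut":
        return [
            (-w, w, -w, w, +1),
            (-p, p, -p, p, -1),
            (0, 0, -w, w, -1),
            (0, 0, -p, p, +1),
            (-w, w, 0, 0, -1),
            (-p, p, 0, 0, +1),
        ]
    if kernel == "lower_left":
        return [(1, w, -w, -1, +1), (1, p, -p, -1, -1)]
    if kernel == "horizontal":
        return [(-1, 1, -w, w, +1), (-1, 1, -p, p, -1)]
    if kernel == "vertical":
        return [(-w, w, -1, 1, +1), (-p, p, -1, 1, -1)]
    raise ValueError(f"unknown kernel {kernel!r}")


def _sat(a: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero first row/column."""
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(a, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def _rect_gather(sat, li, lj, rect, nrows, ncols):
    du1, du2, dv1, dv2, sign = rect
    r1 = np.clip(li + du1, 0, nrows)
    r2 = np.clip(li + du2 + 1, 0, nrows)
    c1 = np.clip(lj + dv1, 0, ncols)
    c2 = np.clip(lj + dv2 + 1, 0, ncols)
    flat = sat.ravel()
    stride = ncols + 1
    s = (
        flat[r2 * stride + c2]
        - flat[r1 * stride + c2]
        - flat[r2 * stride + c1]
        + flat[r1 * stride + c1]
    )
    return sign * s


def _signed_corners(rects, stride):
    """Flattened SAT corner offsets (+clipping-free) for a rect decomposition."""
    corners = []
    for du1, du2, dv1, dv2, sign in rects:
        corners += [
            ((du2 + 1) * stride + dv2 + 1, sign),
            (du1 * stride + dv2 + 1, -sign),
            ((du2 + 1) * stride + dv1, -sign),
            (du1 * stride + dv1, sign),
        ]
    return corners


def _kernel_sum_fast(sat, base, corners):
    flat = sat.ravel()
    out = np.zeros(len(base))
    for off, sign in corners:
        if sign > 0:
            out += flat[base + off]
        else:
            out -= flat[base + off]
    return out


def _kernel_sum(sat, li, lj, rects, nrows, ncols, interior, base, corners):
    """Signed rect sums: offset arithmetic for interior pixels, clipped else."""
    out = np.empty(len(li))
    if interior.all():
        return _kernel_sum_fast(sat, base, corners)
    out[interior] = _kernel_sum_fast(sat, base[interior], corners)
    edge = ~interior
    acc = np.zeros(edge.sum())
    for rect in rects:
        acc += _rect_gather(sat, li[edge], lj[edge], rect, nrows, ncols)
    out[edge] = acc
    return out


def _expected_footprint_by_distance(kernel, p, w, exp, dmax):
    """Sum of E over a full (no missing cells) footprint, per pixel distance."""
    offs = kernel_offsets(kernel, p, w)
    t = offs[:, 1] - offs[:, 0]
    cnt = np.bincount(t + 2 * w, minlength=4 * w + 1)
    ds = np.arange(dmax + 1)
    ek = np.zeros(dmax + 1)
    for tt in range(-2 * w, 2 * w + 1):
        c = cnt[tt + 2 * w]
        if c:
            ek += c * exp[np.abs(ds + tt)]
    return ek


# --------------------------------------------------------------------------- #
# scoring


def kernel_lambda(
    m: ContactMatrix, pixel, kernel: str, params: DotCallParams
) -> tuple[float, int]:
    """Expected rate of one kernel at one pixel, in raw-count units.

    Returns ``(lambda_raw, n_missing_cells)``; lambda is NaN when the pixel
    is untestable (missing weights, undefined expected, or an all-missing
    footprint).  This direct per-pixel routine enumerates the footprint and
    serves small-scale queries; :func:`score_pixels` is the vectorized path.
    """
    m.prepare()
    res = m.chrom.resolution
    p, w = params.resolved_kernels(res)
    n = m.n_bins
    i, j = pixel.bin1, pixel.bin2
    wts, exp = m.weights, m.expected
    if not (np.isfinite(wts[i]) and np.isfinite(wts[j])) or not np.isfinite(exp[j - i]):
        return np.nan, 0
    offs = kernel_offsets(kernel, p, w)
    num = den = 0.0
    miss = 0
    for du, dv in offs:
        u, v = i + du, j + dv
        if not (0 <= u < n and 0 <= v < n):
            miss += 1
            continue
        e = exp[abs(v - u)]
        if not (np.isfinite(wts[u]) and np.isfinite(wts[v]) and np.isfinite(e)):
            miss += 1
            continue
        num += m.sym[u, v] * wts[u] * wts[v]
        den += e
    if den <= 0:
        return np.nan, miss
    lam_bal = exp[j - i] * num / den
    return lam_bal / (wts[i] * wts[j]), miss


def score_pixels(m: ContactMatrix, params: DotCallParams) -> pd.DataFrame:
    """Score all testable pixels of one chromosome under the four kernels.

    Tested pixels lie at bin distance in ``[kernel_w + 1,
    max_loci_separation / resolution]``, have defined weights and expected,
    and at most ``max_nans_tolerated`` missing cells in every kernel
    footprint.  Scoring proceeds in ``tile_size`` row blocks with
    ``kernel_w`` overlap, so results are independent of the tiling.

    Returns a table with columns ``chrom, bin1, bin2, obs``, per-kernel
    raw-unit rates ``la_<k>`` and Poisson upper-tail p-values ``p_<k>``.
    """
    m.prepare()
    res = m.chrom.resolution
    p, w = params.resolved_kernels(res)
    n = m.n_bins
    D = min(params.max_loci_separation // res, n - 1)
    tile_bins = max(params.tile_size // res, 1)
    wts, exp = m.weights, m.expected
    valid_bin = np.isfinite(wts)
    rects = {k: _kernel_rects(k, p, w) for k in KERNELS}
    areas = {k: len(kernel_offsets(k, p, w)) for k in KERNELS}
    ek_by_kernel = {
        k: _expected_footprint_by_distance(
            k, p, w, np.concatenate([exp, [np.nan] * (2 * w)]), D
        )
        for k in KERNELS
    }

    pieces = []
    for r0 in range(0, n, tile_bins):
        r1 = min(r0 + tile_bins, n)
        if r0 + w + 1 > n - 1:
            break
        rlo, rhi = max(r0 - w, 0), min(r1 + w, n)
        clo, chi = rlo, min(r1 - 1 + D + w + 1, n)
        rows = np.arange(rlo, rhi)
        cols = np.arange(clo, chi)

        counts = np.asarray(m.sym[rlo:rhi, clo:chi].todense(), dtype=float)
        eloc = exp[np.abs(rows[:, None] - cols[None, :])]
        vloc = (
            valid_bin[rows][:, None]
            & valid_bin[cols][None, :]
            & np.isfinite(eloc)
        )
        all_valid = bool(vloc.all())
        bal = counts * wts[rows][:, None] * wts[cols][None, :]
        bal[~vloc] = 0.0

        sat_b = _sat(bal)
        sat_e = _sat(np.where(vloc, eloc, 0.0))
        sat_v = _sat(vloc.astype(float))
        nrows, ncols = bal.shape
        stride = ncols + 1

        # tested pixels with row anchor in this tile
        i_list, j_list = [], []
        for i in range(r0, r1):
            jmax = min(i + D, n - 1)
            if i + w + 1 > jmax:
                continue
            js = np.arange(i + w + 1, jmax + 1)
            i_list.append(np.full(len(js), i))
            j_list.append(js)
        if not i_list:
            continue
        pi = np.concatenate(i_list)
        pj = np.concatenate(j_list)
        d = pj - pi
        ok = valid_bin[pi] & valid_bin[pj] & np.isfinite(exp[d])
        pi, pj, d = pi[ok], pj[ok], d[ok]
        if len(pi) == 0:
            continue
        li = pi - rlo
        lj = pj - clo
        base = li * stride + lj
        interior = (
            (li >= w) & (li < nrows - w) & (lj >= w) & (lj < ncols - w)
        )
        # interior pixels of an all-valid tile have complete footprints:
        # their expected-sum is a pure function of distance (no gather needed)
        regular = interior if all_valid else np.zeros(len(pi), dtype=bool)
        irregular = ~regular

        lam = {}
        keep = np.ones(len(pi), dtype=bool)
        for k in KERNELS:
            corners = _signed_corners(rects[k], stride)
            sb = _kernel_sum(
                sat_b, li, lj, rects[k], nrows, ncols, interior, base, corners
            )
            se = np.empty(len(pi))
            se[regular] = ek_by_kernel[k][d[regular]]
            if irregular.any():
                sv_i = np.zeros(irregular.sum())
                se_i = np.zeros(irregular.sum())
                for rect in rects[k]:
                    sv_i += _rect_gather(
                        sat_v, li[irregular], lj[irregular], rect, nrows, ncols
                    )
                    se_i += _rect_gather(
                        sat_e, li[irregular], lj[irregular], rect, nrows, ncols
                    )
                se[irregular] = se_i
                n_missing = areas[k] - np.rint(sv_i).astype(int)
                bad = n_missing > params.max_nans_tolerated
                keep[np.flatnonzero(irregular)[bad]] = False
            keep &= se > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                lam_bal = exp[d] * sb / se
            lam[k] = lam_bal / (wts[pi] * wts[pj])
        if not keep.any():
            continue
        obs = counts[li[keep], lj[keep]]
        sub = {
            "chrom": m.chrom.name,
            "bin1": pi[keep],
            "bin2": pj[keep],
            "obs": np.rint(obs).astype(int),
        }
        for k in KERNELS:
            lk = np.maximum(lam[k][keep], 0.0)
            o = sub["obs"]
            pv = np.ones(len(o))
            nz = o > 0
            pv[nz] = gammainc(o[nz], lk[nz])
            sub[f"la_{_short(k)}"] = lk
            sub[f"p_{_short(k)}"] = pv
        pieces.append(pd.DataFrame(sub))
    if not pieces:
        cols = ["chrom", "bin1", "bin2", "obs"]
        for k in KERNELS:
            cols += [f"la_{_short(k)}", f"p_{_short(k)}"]
        return pd.DataFrame(columns=cols)
    # tiles are scanned in ascending row order, so rows are already sorted
    return pd.concat(pieces, ignore_index=True)


def _short(kernel: str) -> str:
    return {"donut": "donut", "lower_left": "ll", "horizontal": "h", "vertical": "v"}[
        kernel
    ]


# --------------------------------------------------------------------------- #
# lambda-chunked FDR


def _lambda_chunks(lam: np.ndarray) -> np.ndarray:
    """Geometric lambda chunk index: edges 2^(k/3); lambda < 1 pools into -1."""
    idx = np.full(len(lam), -1, dtype=int)
    big = lam >= 1
    with np.errstate(divide="ignore"):
        idx[big] = np.ceil(3 * np.log2(lam[big]) - 1e-9).astype(int)
    idx[big] = np.maximum(idx[big], 1)  # lambda == 1 belongs to the first chunk
    return idx


def _bh_within_chunks(pvals: np.ndarray, chunks: np.ndarray) -> np.ndarray:
    q = np.empty_like(pvals)
    for c in np.unique(chunks):
        sel = chunks == c
        q[sel] = multipletests(pvals[sel], method="fdr_bh")[1]
    return q


def lambda_binned_fdr(scores: pd.DataFrame, params: DotCallParams) -> pd.DataFrame:
    """BH-correct p-values within (kernel, lambda-chunk) and keep enriched pixels.

    A pixel is enriched iff ``q <= lambda_bin_fdr`` under all four kernels.
    The returned table adds per-kernel ``q_*`` columns and ``qvalue_max``.
    """
    if len(scores) == 0:
        out = scores.copy()
        for k in KERNELS:
            out[f"q_{_short(k)}"] = pd.Series(dtype=float)
        out["qvalue_max"] = pd.Series(dtype=float)
        return out
    scores = scores.copy()
    qcols = []
    for k in KERNELS:
        s = _short(k)
        chunks = _lambda_chunks(scores[f"la_{s}"].to_numpy())
        q = _bh_within_chunks(scores[f"p_{s}"].to_numpy(), chunks)
        scores[f"q_{s}"] = q
        qcols.append(f"q_{s}")
    scores["qvalue_max"] = scores[qcols].max(axis=1)
    enriched = (scores[qcols] <= params.lambda_bin_fdr).all(axis=1)
    return scores[enriched].reset_index(drop=True)


def call_enriched_pixels(
    matrices: dict[str, ContactMatrix], sample: str, params: DotCallParams
) -> pd.DataFrame:
    """Score all chromosomes of one sample and apply the lambda-chunked FDR.

    FDR correction is applied jointly across chromosomes (one family per
    kernel and lambda chunk, genome-wide).
    """
    scored = [score_pixels(matrices[c], params) for c in sorted(matrices)]
    scored = pd.concat(scored, ignore_index=True) if scored else pd.DataFrame()
    enriched = lambda_binned_fdr(scored, params)
    enriched.insert(3, "sample", sample)
    return enriched


# --------------------------------------------------------------------------- #
# conventional clustering + empirical filtering (single-sample baseline)


def conventional_cluster_and_filter(
    pixels: pd.DataFrame,
    matrices: dict[str, ContactMatrix],
    params: DotCallParams,
) -> pd.DataFrame:
    """Cluster one sample's enriched pixels and apply the empirical filters.

    The centroid of each cluster is the member with maximal balanced value in
    this sample (ties broken by smallest ``(bin1, bin2)``).  Centroids must
    pass the enrichment ratios — observed/lambda >= ``enrichment_d_and_ll``
    against donut and lower-left, >= ``enrichment_vh`` against horizontal and
    vertical — and singletons must additionally satisfy ``qvalue_max <=
    singleton_qvalue_max``.  Failing calls are dropped.
    """
    if len(pixels) == 0:
        return pd.DataFrame(
            columns=[
                "chrom",
                "bin1",
                "bin2",
                "sample",
                "cluster_size",
                "is_singleton",
                "qvalue_max",
                "obs",
            ]
        )
    if pixels["sample"].nunique() > 1:
        raise ValueError("conventional filtering operates on a single sample")
    sample = pixels["sample"].iloc[0]
    rows = []
    for chrom, grp in pixels.groupby("chrom", sort=True):
        m = matrices[chrom].prepare()
        res = m.chrom.resolution
        grp = grp.sort_values(["bin1", "bin2"], kind="mergesort").reset_index(drop=True)
        labels = radius_cluster_labels(
            grp["bin1"].to_numpy(), grp["bin2"].to_numpy(), params.clustering_radius, res
        )
        bal = m.balanced_at(grp["bin1"].to_numpy(), grp["bin2"].to_numpy())
        score = np.where(np.isfinite(bal), bal, -np.inf)
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            best = members[np.argmax(score[members])]  # first max = smallest coords
            row = grp.iloc[best]
            obs = float(row["obs"])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios_dll = obs / np.array([row["la_donut"], row["la_ll"]])
                ratios_vh = obs / np.array([row["la_h"], row["la_v"]])
            if not (
                (ratios_dll >= params.enrichment_d_and_ll).all()
                and (ratios_vh >= params.enrichment_vh).all()
            ):
                continue
            singleton = len(members) == 1
            if singleton and row["qvalue_max"] > params.singleton_qvalue_max:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "bin1": int(row["bin1"]),
                    "bin2": int(row["bin2"]),
                    "sample": sample,
                    "cluster_size": len(members),
                    "is_singleton": singleton,
                    "qvalue_max": float(row["qvalue_max"]),
                    "obs": int(row["obs"]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "bin1",
            "bin2",
            "sample",
            "cluster_size",
            "is_singleton",
            "qvalue_max",
            "obs",
        ],
    )
    return out.sort_values(["chrom", "bin1", "bin2"], kind="mergesort").reset_index(
        drop=True
    )
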