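"""Per-chromosome contact matrices: balancing, expected, merging, snippets.

A :class:`ContactMatrix` holds raw intra-chromosomal counts as a sparse
upper-triangular matrix together with per-bin ICE balancing weights and a
per-distance expected profile.  The balanced value of a pixel is

    B[i, j] = raw[i, j] * w_i * w_j

and is missing (NaN) whenever either weight is missing.  Weights are scaled
so that the mean nonzero balanced marginal equals 1, matching the iterative
correction convention of standard Hi-C processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .model import BinnedChrom, Pixel

__all__ = [
    "ContactMatrix",
    "SampleSet",
    "ice_balance",
    "expected_by_distance",
    "merge_samples",
    "extract_snippet",
]


@dataclass
class SampleSet:
    """Ordered sample identifiers plus the optional merged-map pseudo-sample."""

    samples: list[str]
    mega_id: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if self.mega_id is not None and self.mega_id in self.samples:
            raise ValueError(f"mega_id {self.mega_id!r} collides with a sample id")

    @property
    def all_ids(self) -> list[str]:
        return self.samples + ([self.mega_id] if self.mega_id else [])


class ContactMatrix:
    """Sparse upper-triangular raw counts + balancing weights + expected.

    Parameters
    ----------
    chrom
        The binned chromosome this matrix covers.
    raw
        Sparse (or dense) square matrix of raw counts.  Any lower-triangular
        entries are folded onto the upper triangle on ingestion.
    weights, expected
        Optional precomputed balancing weights (NaN = missing) and
        per-distance expected profile; computed on demand otherwise.
    """

    def __init__(
        self,
        chrom: BinnedChrom,
        raw,
        weights: np.ndarray | None = None,
        expected: np.ndarray | None = None,
    ):
        n = chrom.n_bins
        raw = sp.coo_matrix(raw, shape=(n, n))
        if (raw.data < 0).any():
            raise ValueError("negative raw counts")
        lower = raw.row > raw.col
        r = np.where(lower, raw.col, raw.row)
        c = np.where(lower, raw.row, raw.col)
        coo = sp.coo_matrix((raw.data, (r, c)), shape=(n, n))
        coo.sum_duplicates()
        self.chrom = chrom
        self.raw = coo.tocsr()
        self.raw.sum_duplicates()
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.expected = None if expected is None else np.asarray(expected, dtype=float)
        self._sym: sp.csr_matrix | None = None

    # ------------------------------------------------------------------ #

    @property
    def n_bins(self) -> int:
        return self.chrom.n_bins

    @property
    def total(self) -> float:
        """Total raw count over the upper triangle (including the diagonal)."""
        return float(self.raw.sum())

    @property
    def sym(self) -> sp.csr_matrix:
        """Symmetrized raw counts (upper triangle mirrored below)."""
        if self._sym is None:
            upper = self.raw.tocsr()
            self._sym = (upper + sp.triu(upper, k=1).T).tocsr()
        return self._sym

    def prepare(self, max_iter: int = 1000, tol: float = 1e-4) -> "ContactMatrix":
        """Ensure balancing weights and the expected profile are computed."""
        if self.weights is None:
            self.weights = ice_balance(self, max_iter=max_iter, tol=tol)
        if self.expected is None:
            self.expected = expected_by_distance(self)
        return self

    # ------------------------------------------------------------------ #

    def balanced_at(self, bin1, bin2) -> np.ndarray:
        """Balanced values at given bin pairs (vectorized; NaN if missing)."""
        if self.weights is None:
            raise ValueError("weights not computed; call prepare() first")
        b1 = np.atleast_1d(np.asarray(bin1, dtype=int))
        b2 = np.atleast_1d(np.asarray(bin2, dtype=int))
        counts = np.asarray(self.sym[b1, b2]).ravel().astype(float)
        return counts * self.weights[b1] * self.weights[b2]

    def balanced_block(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        """Dense balanced sub-block [r0:r1) x [c0:c1), NaN where missing.

        Indices outside the chromosome are not permitted here; use
        :func:`extract_snippet` for padded windows.
        """
        if self.weights is None:
            raise ValueError("weights not computed; call prepare() first")
        block = np.asarray(self.sym[r0:r1, c0:c1].todense(), dtype=float)
        w_r = self.weights[r0:r1]
        w_c = self.weights[c0:c1]
        return block * w_r[:, None] * w_c[None, :]


def ice_balance(
    m: "ContactMatrix | sp.spmatrix",
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> np.ndarray:
    """Iterative-correction balancing weights for a contact matrix.

    Iterates ``w_i <- w_i / (marginal_i / mean marginal)`` on the symmetrized
    matrix until the coefficient of variation of nonzero balanced marginals
    drops to ``tol`` (or ``max_iter`` is reached).  Bins with zero raw
    marginal get NaN weights.  The returned weights are scaled so the mean
    nonzero balanced marginal equals 1.

    An all-zero matrix yields all-NaN weights (not an error).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if isinstance(m, ContactMatrix):
        S = m.sym
    else:
        upper = sp.csr_matrix(m)
        S = upper + sp.triu(upper, k=1).T
    n = S.shape[0]
    marg0 = np.asarray(S.sum(axis=1)).ravel()
    active = marg0 > 0
    w = np.ones(n)
    w[~active] = np.nan
    if not active.any():
        return w
    wa = np.ones(active.sum())
    Sa = S[active][:, active]
    for _ in range(max_iter):
        marg = wa * (Sa @ wa)
        mean = marg.mean()
        cv = marg.std() / mean
        if cv <= tol:
            break
        wa = wa / np.sqrt(marg / mean)
    # scale so the mean nonzero balanced marginal is 1
    marg = wa * (Sa @ wa)
    wa = wa / np.sqrt(marg.mean())
    w[active] = wa
    return w


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean balanced value per bin-distance diagonal.

    ``expected[d]`` averages the balanced values over all pixels at distance
    ``d``, counting only pixels whose two weights are both defined (the
    denominator is the number of such pairs on the diagonal, correct at
    chromosome edges).  Distances with no valid pair get NaN.
    """
    if m.weights is None:
        raise ValueError("weights not computed; call prepare() or ice_balance first")
    n = m.n_bins
    w = m.weights
    valid = np.isfinite(w)
    coo = m.raw.tocoo()
    d = coo.col - coo.row
    vals = coo.data * w[coo.row] * w[coo.col]
    keep = np.isfinite(vals)
    sums = np.bincount(d[keep], weights=vals[keep], minlength=n)
    # number of valid (both-weights-defined) pairs per diagonal
    v = valid.astype(float)
    counts = np.correlate(v, v, mode="full")[n - 1 :]
    counts = np.rint(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    expected[counts == 0] = np.nan
    return expected


def merge_samples(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of raw counts across samples (the MEGA map).

    Weights and expected are left unset so they are recomputed on the merged
    counts by :meth:`ContactMatrix.prepare`.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if m.chrom != first.chrom:
            raise ValueError(
                f"mismatched binning: {m.chrom} vs {first.chrom}"
            )
    raw = matrices[0].raw.copy()
    for m in matrices[1:]:
        raw = raw + m.raw
    return ContactMatrix(first.chrom, raw)


def extract_snippet(m: ContactMatrix, center: Pixel, flank_bp: int) -> np.ndarray:
    """Dense square window of balanced values centered on a pixel.

    The window has side ``2 * (flank_bp / resolution) + 1``; cells that fall
    outside the chromosome or touch a missing-weight bin are NaN.
    """
    res = m.chrom.resolution
    if flank_bp % res != 0:
        raise ValueError(f"flank {flank_bp} not a multiple of resolution {res}")
    if center.chrom != m.chrom.name or not (
        m.chrom.contains_bin(center.bin1) and m.chrom.contains_bin(center.bin2)
    ):
        raise ValueError(f"center pixel {center} off chromosome {m.chrom.name}")
    if m.weights is None:
        raise ValueError("weights not computed; call prepare() first")
    F = flank_bp // res
    side = 2 * F + 1
    n = m.n_bins
    out = np.full((side, side), np.nan)
    r0, r1 = center.bin1 - F, center.bin1 + F + 1
    c0, c1 = center.bin2 - F, center.bin2 + F + 1
    rr0, rr1 = max(r0, 0), min(r1, n)
    cc0, cc1 = max(c0, 0), min(c1, n)
    if rr0 < rr1 and cc0 < cc1:
        out[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = m.balanced_block(
            rr0, rr1, cc0, cc1
        )
    return out
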