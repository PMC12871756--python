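"""File formats: plain-text COO contacts, chromsizes, BED, BEDPE tables, cooler.

Two interchange routes for contact matrices are supported:

* a plain-text COO dialect — TSV with header ``chrom bin1 bin2 count`` (one
  file per sample) plus a two-column chromsizes TSV ``name length``; integer
  round-trips are bit-exact;
* single-resolution ``.cool`` and multi-resolution ``.mcool`` HDF5 files
  following the public cooler schema (``chroms``/``bins``/``pixels``/
  ``indexes`` groups, balancing weights in the bins ``weight`` column),
  written and read directly with h5py.

Loop/pixel tables serialize as BEDPE-plus TSV: the six BEDPE coordinate
columns followed by caller-specific columns.  Lines starting with ``#`` are
provenance headers and are skipped on read.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .model import BinnedChrom, PeakInterval

__all__ = [
    "read_chromsizes",
    "write_chromsizes",
    "read_coo_text",
    "write_coo_text",
    "read_bed",
    "write_bed",
    "read_bedpe_table",
    "write_bedpe_table",
    "write_cool",
    "read_cool",
    "write_mcool",
    "read_mcool",
]


# --------------------------------------------------------------------------- #
# plain-text formats


def write_chromsizes(path, chroms: list[BinnedChrom]) -> None:
    with open(path, "w") as fh:
        for c in chroms:
            fh.write(f"{c.name}\t{c.length_bp}\n")


def read_chromsizes(path, resolution: int) -> dict[str, BinnedChrom]:
    out: dict[str, BinnedChrom] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")
            out[name] = BinnedChrom(name, int(length), resolution)
    return out


def write_coo_text(path, matrices: dict[str, ContactMatrix]) -> None:
    """Write one sample's matrices (keyed by chromosome) as COO TSV."""
    frames = []
    for name in sorted(matrices):
        coo = matrices[name].raw.tocoo()
        order = np.lexsort((coo.col, coo.row))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "bin1": coo.row[order],
                    "bin2": coo.col[order],
                    "count": coo.data[order].astype(np.int64),
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "bin1", "bin2", "count"])
    )
    out.to_csv(path, sep="\t", index=False)


def read_coo_text(path, chroms: dict[str, BinnedChrom]) -> dict[str, ContactMatrix]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "bin1", "bin2", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"COO file {path} missing columns {required - set(df.columns)}")
    out: dict[str, ContactMatrix] = {}
    for name, grp in df.groupby("chrom", sort=True):
        if name not in chroms:
            raise ValueError(f"chromosome {name!r} absent from chromsizes")
        chrom = chroms[name]
        import scipy.sparse as sp

        coo = sp.coo_matrix(
            (grp["count"].to_numpy(), (grp["bin1"].to_numpy(), grp["bin2"].to_numpy())),
            shape=(chrom.n_bins, chrom.n_bins),
        )
        out[name] = ContactMatrix(chrom, coo)
    return out


def write_bed(path, peaks: list[PeakInterval]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start_bp}\t{p.end_bp}\n")


def read_bed(path) -> list[PeakInterval]:
    """Read a BED file; only the first three columns are used."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            peaks.append(PeakInterval(fields[0], int(fields[1]), int(fields[2])))
    return peaks


def write_bedpe_table(
    path, df: pd.DataFrame, resolution: int, header_lines: list[str] | None = None
) -> None:
    """Serialize a pixel/loop table (bin coordinates) as BEDPE-plus TSV.

    The table must carry ``chrom``, ``bin1``, ``bin2``; all other columns are
    appended after the six BEDPE coordinate columns.
    """
    extra = [c for c in df.columns if c not in ("chrom", "bin1", "bin2")]
    out = pd.DataFrame(
        {
            "chrom1": df["chrom"],
            "start1": df["bin1"] * resolution,
            "end1": (df["bin1"] + 1) * resolution,
            "chrom2": df["chrom"],
            "start2": df["bin2"] * resolution,
            "end2": (df["bin2"] + 1) * resolution,
        }
    )
    for c in extra:
        out[c] = df[c].to_numpy()
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_bedpe_table(path, resolution: int | None = None) -> pd.DataFrame:
    """Read a BEDPE-plus table back into bin coordinates.

    Accepts external loop tables (e.g. from other callers) with at least the
    six BEDPE coordinate columns; extra columns are preserved.  If
    ``resolution`` is None it is inferred from ``end1 - start1``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if not set(needed).issubset(df.columns):
        raise ValueError(f"BEDPE table {path} lacks coordinate columns {needed}")
    if (df["chrom1"] != df["chrom2"]).any():
        raise ValueError("inter-chromosomal records are not supported")
    if resolution is None:
        if len(df) == 0:
            raise ValueError("cannot infer resolution from an empty table")
        resolution = int(df["end1"].iloc[0] - df["start1"].iloc[0])
    out = pd.DataFrame(
        {
            "chrom": df["chrom1"],
            "bin1": df["start1"] // resolution,
            "bin2": df["start2"] // resolution,
        }
    )
    for c in df.columns:
        if c not in needed:
            out[c] = df[c].to_numpy()
    # canonical upper-triangular form
    flip = out["bin1"] > out["bin2"]
    if flip.any():
        b1 = out["bin1"].where(~flip, out["bin2"])
        b2 = out["bin2"].where(~flip, out["bin1"])
        out["bin1"], out["bin2"] = b1, b2
    return out


# --------------------------------------------------------------------------- #
# cooler HDF5 schema


def _write_cooler_group(grp: h5py.Group, matrices: dict[str, ContactMatrix]) -> None:
    names = sorted(matrices)
    chroms = [matrices[n].chrom for n in names]
    res = chroms[0].resolution
    if any(c.resolution != res for c in chroms):
        raise ValueError("mixed resolutions in one cooler group")

    g = grp.create_group("chroms")
    g.create_dataset("name", data=np.array(names, dtype="S"))
    g.create_dataset("length", data=np.array([c.length_bp for c in chroms], dtype="i8"))

    bin_chrom, bin_start, bin_end, bin_weight = [], [], [], []
    chrom_bin_offset = [0]
    for ci, c in enumerate(chroms):
        nb = c.n_bins
        starts = np.arange(nb, dtype="i8") * res
        bin_chrom.append(np.full(nb, ci, dtype="i4"))
        bin_start.append(starts)
        bin_end.append(np.minimum(starts + res, c.length_bp))
        w = matrices[names[ci]].weights
        bin_weight.append(np.full(nb, np.nan) if w is None else np.asarray(w, float))
        chrom_bin_offset.append(chrom_bin_offset[-1] + nb)
    g = grp.create_group("bins")
    g.create_dataset("chrom", data=np.concatenate(bin_chrom))
    g.create_dataset("start", data=np.concatenate(bin_start))
    g.create_dataset("end", data=np.concatenate(bin_end))
    g.create_dataset("weight", data=np.concatenate(bin_weight))

    b1, b2, cnt = [], [], []
    for ci, name in enumerate(names):
        coo = matrices[name].raw.tocoo()
        order = np.lexsort((coo.col, coo.row))
        off = chrom_bin_offset[ci]
        b1.append(coo.row[order].astype("i8") + off)
        b2.append(coo.col[order].astype("i8") + off)
        cnt.append(coo.data[order].astype("i4"))
    bin1_id = np.concatenate(b1) if b1 else np.empty(0, "i8")
    bin2_id = np.concatenate(b2) if b2 else np.empty(0, "i8")
    count = np.concatenate(cnt) if cnt else np.empty(0, "i4")
    g = grp.create_group("pixels")
    g.create_dataset("bin1_id", data=bin1_id)
    g.create_dataset("bin2_id", data=bin2_id)
    g.create_dataset("count", data=count)

    n_bins_total = chrom_bin_offset[-1]
    bin1_offset = np.searchsorted(bin1_id, np.arange(n_bins_total + 1))
    g = grp.create_group("indexes")
    g.create_dataset("chrom_offset", data=np.array(chrom_bin_offset, dtype="i8"))
    g.create_dataset("bin1_offset", data=bin1_offset.astype("i8"))

    grp.attrs["format"] = "HDF5::Cooler"
    grp.attrs["format-version"] = 3
    grp.attrs["bin-size"] = res
    grp.attrs["bin-type"] = "fixed"
    grp.attrs["nchroms"] = len(names)
    grp.attrs["nbins"] = n_bins_total
    grp.attrs["nnz"] = len(count)
    grp.attrs["storage-mode"] = "symmetric-upper"


def _read_cooler_group(grp: h5py.Group) -> dict[str, ContactMatrix]:
    import scipy.sparse as sp

    names = [s.decode() if isinstance(s, bytes) else s for s in grp["chroms/name"][:]]
    lengths = grp["chroms/length"][:]
    res = int(grp.attrs["bin-size"])
    bin_chrom = grp["bins/chrom"][:]
    weights = (
        grp["bins/weight"][:] if "weight" in grp["bins"] else np.full(len(bin_chrom), np.nan)
    )
    offsets = np.concatenate([[0], np.cumsum(np.bincount(bin_chrom, minlength=len(names)))])
    b1 = grp["pixels/bin1_id"][:]
    b2 = grp["pixels/bin2_id"][:]
    cnt = grp["pixels/count"][:]
    out: dict[str, ContactMatrix] = {}
    for ci, (name, length) in enumerate(zip(names, lengths)):
        chrom = BinnedChrom(name, int(length), res)
        lo, hi = offsets[ci], offsets[ci + 1]
        sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        coo = sp.coo_matrix(
            (cnt[sel], (b1[sel] - lo, b2[sel] - lo)), shape=(chrom.n_bins, chrom.n_bins)
        )
        w = weights[lo:hi]
        out[name] = ContactMatrix(chrom, coo, weights=None if np.all(np.isnan(w)) else w)
    return out


def write_cool(path, matrices: dict[str, ContactMatrix]) -> None:
    """Write a single-resolution cooler file (one sample, chroms keyed by name)."""
    with h5py.File(path, "w") as fh:
        _write_cooler_group(fh, matrices)


def read_cool(path) -> dict[str, ContactMatrix]:
    with h5py.File(path, "r") as fh:
        grp = fh
        if "resolutions" in fh:  # single-resolution view of an mcool
            first = sorted(fh["resolutions"], key=int)[0]
            grp = fh[f"resolutions/{first}"]
        return _read_cooler_group(grp)


def write_mcool(path, by_resolution: dict[int, dict[str, ContactMatrix]]) -> None:
    """Write a multi-resolution cooler (.mcool) file."""
    with h5py.File(path, "w") as fh:
        for res, matrices in sorted(by_resolution.items()):
            _write_cooler_group(fh.create_group(f"resolutions/{res}"), matrices)


def read_mcool(path, resolution: int | None = None) -> dict[str, ContactMatrix]:
    with h5py.File(path, "r") as fh:
        if "resolutions" not in fh:
            return _read_cooler_group(fh)
        if resolution is None:
            resolution = min(int(r) for r in fh["resolutions"])
        key = f"resolutions/{resolution}"
        if key not in fh:
            raise ValueError(f"resolution {resolution} not present in {path}")
        return _read_cooler_group(fh[key])
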