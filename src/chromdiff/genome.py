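"""Genomic coordinate system: bins, regions, overlap machinery and BED-family IO.

All coordinates are 0-based half-open, both in memory and on disk (BED
dialect).  Chromosome order follows first appearance in the chrom-sizes
input; no karyotype sorting is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Region",
    "BinTable",
    "make_bins",
    "reciprocal_overlap",
    "overlap_query",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
]

_STRANDS = {"+", "-", None}


class RegionFormatError(ValueError):
    """Raised for malformed region records, with the offending line number."""


@dataclass(frozen=True)
class Region:
    """A genomic interval [start, end) with optional name/strand/score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"degenerate region {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Region") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class BinTable:
    """Uniform-width partition of a genome into indexed bins.

    Per chromosome there are ceil(length/width) bins; the terminal bin is
    truncated at the chromosome end.  Global bin indices increase in
    (chromosome appearance order, start) order.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], width: int):
        if width <= 0:
            raise ValueError("bin width must be positive")
        if not chrom_sizes:
            raise ValueError("no chromosomes")
        for c, L in chrom_sizes.items():
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {L}")
        self.width = int(width)
        self.chrom_sizes = dict(chrom_sizes)
        self.chroms = list(chrom_sizes)
        self._nbins = {c: -(-int(L) // self.width) for c, L in chrom_sizes.items()}
        offs, tot = {}, 0
        for c in self.chroms:
            offs[c] = tot
            tot += self._nbins[c]
        self._offsets = offs
        self.n_bins = tot

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            L, n, off = self.chrom_sizes[c], self._nbins[c], self._offsets[c]
            starts = np.arange(n, dtype=np.int64) * self.width
            ends = np.minimum(starts + self.width, L)
            rows.append(
                pd.DataFrame(
                    {"chrom": c, "start": starts, "end": ends, "index": off + np.arange(n)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def nbins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def index_range(self, chrom: str) -> tuple[int, int]:
        off = self._offsets[chrom]
        return off, off + self._nbins[chrom]

    def assign(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Map (chrom, position) arrays to global bin indices.

        Positions must satisfy 0 <= pos < chromosome length; the index of the
        first offending record is reported otherwise.
        """
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(positions), dtype=np.int64)
        seen = np.zeros(len(positions), dtype=bool)
        for c in self.chroms:
            m = chroms == c
            if not m.any():
                continue
            pos = positions[m]
            bad = (pos < 0) | (pos >= self.chrom_sizes[c])
            if bad.any():
                idx = np.flatnonzero(m)[np.argmax(bad)]
                raise ValueError(
                    f"position {positions[idx]} outside chromosome {c} at record {idx}"
                )
            out[m] = self._offsets[c] + pos // self.width
            seen[m] = True
        if not seen.all():
            idx = int(np.argmax(~seen))
            raise ValueError(f"unknown chromosome {chroms[idx]!r} at record {idx}")
        return out

    def chrom_of(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index)
        bounds = np.array([self._offsets[c] for c in self.chroms] + [self.n_bins])
        which = np.searchsorted(bounds, index, side="right") - 1
        return np.asarray(self.chroms, dtype=object)[which]

    def starts(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index)
        out = np.empty(len(index), dtype=np.int64)
        for c in self.chroms:
            lo, hi = self.index_range(c)
            m = (index >= lo) & (index < hi)
            out[m] = (index[m] - lo) * self.width
        return out

    def mids(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index)
        st = self.starts(index)
        out = np.empty(len(index), dtype=np.float64)
        for c in self.chroms:
            lo, hi = self.index_range(c)
            m = (index >= lo) & (index < hi)
            out[m] = (st[m] + np.minimum(st[m] + self.width, self.chrom_sizes[c])) / 2.0
        return out

    def bin_region(self, index: int) -> Region:
        chrom = str(self.chrom_of(np.array([index]))[0])
        start = int(self.starts(np.array([index]))[0])
        end = min(start + self.width, self.chrom_sizes[chrom])
        return Region(chrom, start, end)


def make_bins(chrom_sizes: Mapping[str, int], width: int) -> BinTable:
    """Partition chromosomes into fixed-width bins with global indices."""
    return BinTable(chrom_sizes, width)


def reciprocal_overlap(a: Region, b: Region) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 0 for disjoint or trans pairs."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("zero-length region")
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def _as_region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in regions]
    )


def overlap_query(query, subject) -> list[np.ndarray]:
    """Per-query sorted indices of subjects with nonempty half-open overlap."""
    qf = _as_region_frame(query)
    sf = _as_region_frame(subject)
    trees: dict[str, IntervalTree] = {}
    if len(sf):
        for chrom, grp in sf.groupby("chrom", sort=False):
            t = IntervalTree()
            for i, s, e in zip(grp.index, grp["start"], grp["end"]):
                t.addi(int(s), int(e), int(i))
            trees[chrom] = t
    out = []
    for chrom, s, e in zip(qf.get("chrom", []), qf.get("start", []), qf.get("end", [])):
        t = trees.get(chrom)
        if t is None:
            out.append(np.array([], dtype=np.int64))
        else:
            hits = sorted(iv.data for iv in t.overlap(int(s), int(e)))
            out.append(np.array(hits, dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# IO: BED / BEDPE / chrom sizes / gene annotation
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a region table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise RegionFormatError(f"{path}: line {lineno}: fewer than 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise RegionFormatError(f"{path}: line {lineno}: {exc}") from None
            if start >= end:
                raise RegionFormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            rec = {"chrom": f[0], "start": start, "end": end}
            if len(f) > 3 and f[3] != ".":
                rec["name"] = f[3]
            if len(f) > 4 and f[4] != ".":
                rec["score"] = float(f[4])
            if len(f) > 5 and f[5] != ".":
                if f[5] not in ("+", "-"):
                    raise RegionFormatError(f"{path}: line {lineno}: bad strand {f[5]!r}")
                rec["strand"] = f[5]
            rows.append(rec)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    # BED columns are positional: fill any gap with '.'
    upto = max(_BED_COLS.index(c) for c in cols) + 1 if cols else 3
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            f = []
            for c in _BED_COLS[:upto]:
                v = row.get(c)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    f.append(".")
                elif c in ("start", "end"):
                    f.append(str(int(v)))
                else:
                    f.append(str(v))
            fh.write("\t".join(f) + "\n")


_BEDPE_CORE = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def write_bedpe(df: pd.DataFrame, path) -> None:
    """Write anchor pairs plus any extra columns; a '#' header preserves names."""
    extra = [c for c in df.columns if c not in _BEDPE_CORE]
    cols = _BEDPE_CORE + extra
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        sub = df[cols]
        for row in sub.itertuples(index=False):
            vals = []
            for c, v in zip(cols, row):
                if c in ("start1", "end1", "start2", "end2"):
                    vals.append(str(int(v)))
                else:
                    vals.append(repr(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(vals) + "\n")


def read_bedpe(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#"):
            cols = first[1:].split("\t")
            body_start = 2
        else:
            nf = len(first.split("\t"))
            cols = _BEDPE_CORE + [f"col{i}" for i in range(7, nf + 1)]
            body_start = 1
        rows = []
        lines = ([] if body_start == 2 else [first]) + fh.read().splitlines()
        for off, line in enumerate(lines):
            lineno = body_start + off
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) != len(cols):
                raise RegionFormatError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, got {len(f)}"
                )
            rows.append(f)
    df = pd.DataFrame(rows, columns=cols)
    for c in ("start1", "end1", "start2", "end2"):
        df[c] = df[c].astype(np.int64)
    for c in df.columns:
        if c in _BEDPE_CORE:
            continue
        converted = pd.to_numeric(df[c], errors="coerce")
        if not converted.isna().any():
            df[c] = converted
    for side in ("1", "2"):
        bad = df[f"start{side}"] >= df[f"end{side}"]
        if bad.any():
            raise RegionFormatError(f"{path}: anchor with start >= end")
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise RegionFormatError(f"{path}: line {lineno}: need chrom and length")
            sizes[f[0]] = int(f[1])
    if not sizes:
        raise ValueError("no chromosomes")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, L in sizes.items():
            fh.write(f"{c}\t{int(L)}\n")


_GENE_COLS = ["gene_id", "chrom", "tss", "strand"]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise RegionFormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        raise RegionFormatError(f"{path}: duplicate gene_ids")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
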