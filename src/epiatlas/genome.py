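"""Genome model, interval arithmetic, fixed-width binning and shared file I/O.

All internal coordinates are 0-based half-open (BED convention).  Inputs that
arrive 1-based (GWAS catalog positions, Bismark coverage files) are converted
at the parser boundary, never downstream.

The genome is modelled as an ordered list of chromosomes (:class:`GenomeAssembly`);
the chromosome order is stable and defines the global order of fixed-width
bins (:class:`BinIndex`).  Terminal bins may be shorter than ``bin_size`` and
are retained so that the bin-ordinal <-> coordinate mapping stays bijective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeAssembly",
    "IntervalSet",
    "BinIndex",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "bin_genome",
    "intervals_to_bins",
    "merge_bins",
    "promoter_regions",
    "split_proximal_distal",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered chromosome table: names and lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length < 1 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 1")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.index_of(chrom)]

    def index_of(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @classmethod
    def from_mapping(cls, sizes: Mapping[str, int]) -> "GenomeAssembly":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a two-column chrom-sizes TSV into a :class:`GenomeAssembly`."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeAssembly(tuple(names), tuple(lengths))


class IntervalSet:
    """A sorted set of genomic intervals with optional labels and strands.

    Backed by a pandas DataFrame with columns ``chrom``, ``start``, ``end``
    and optionally ``label`` and ``strand``.  Records are sorted by
    (chrom, start, end); overlapping records are permitted.
    """

    def __init__(self, df: pd.DataFrame, assembly: GenomeAssembly | None = None):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"IntervalSet requires columns {sorted(required)}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"empty or inverted interval at record {bad}")
        if assembly is not None:
            self._check_assembly(df, assembly)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self._df = df
        self.assembly = assembly

    @staticmethod
    def _check_assembly(df: pd.DataFrame, assembly: GenomeAssembly) -> None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in assembly:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if int(sub["end"].max()) > assembly.length_of(str(chrom)):
                raise ValueError(f"interval beyond end of {chrom}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        assembly: GenomeAssembly | None = None,
        labels: bool = False,
    ) -> "IntervalSet":
        cols = ["chrom", "start", "end"] + (["label"] if labels else [])
        df = pd.DataFrame(list(records), columns=cols)
        return cls(df, assembly)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def has_labels(self) -> bool:
        return "label" in self._df.columns

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        return self._df.itertuples(index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self._df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other._df[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    def total_length(self) -> int:
        return int((self._df["end"] - self._df["start"]).sum())

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(self._df.loc[np.asarray(mask, dtype=bool)], self.assembly)

    def merged(self) -> "IntervalSet":
        """Union of the records: overlapping or bookended intervals fused."""
        rows = []
        for chrom, sub in self._df.groupby("chrom", sort=False):
            start = end = None
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                if start is None:
                    start, end = s, e
                elif s <= end:
                    end = max(end, e)
                else:
                    rows.append((chrom, start, end))
                    start, end = s, e
            if start is not None:
                rows.append((chrom, start, end))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), self.assembly)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            out[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
            )
        return out


def read_bed(
    path: str | Path,
    has_labels: bool | None = None,
    assembly: GenomeAssembly | None = None,
) -> IntervalSet:
    """Read a BED3/BED4(+strand) file.

    ``has_labels=None`` auto-detects a 4th column; ``True`` requires one.
    Malformed lines raise with the offending line number.
    """
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if has_labels is True and len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: missing label column")
            row = [parts[0], start, end]
            if has_labels is not False and len(parts) >= 4:
                row.append(parts[3])
            if len(parts) >= 6 and parts[5] in "+-":
                row.append(parts[5])
            rows.append(row)
            n_cols = max(n_cols or 0, len(row))
    cols = ["chrom", "start", "end", "label", "strand"][: (n_cols or 3)]
    df = pd.DataFrame(rows, columns=cols)
    return IntervalSet(df, assembly)


def write_bed(intervals: IntervalSet, path: str | Path, header: str | None = None) -> None:
    """Write BED3 or BED4 (label column included when present)."""
    cols = ["chrom", "start", "end"] + (["label"] if intervals.has_labels else [])
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        intervals.df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, chrom, strand, tss, tes."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return df


@dataclass(frozen=True)
class BinIndex:
    """Partition of a genome into fixed-width, non-overlapping bins.

    Bin ordinals run over chromosomes in assembly order; the last bin of a
    chromosome may be shorter than ``bin_size``.
    """

    assembly: GenomeAssembly
    bin_size: int = 200
    _offsets: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        counts = [math.ceil(length / self.bin_size) for length in self.assembly.chrom_lengths]
        offsets = np.concatenate([[0], np.cumsum(counts)])
        object.__setattr__(self, "_offsets", offsets)

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def bins_on(self, chrom: str) -> int:
        ci = self.assembly.index_of(chrom)
        return int(self._offsets[ci + 1] - self._offsets[ci])

    def chrom_slice(self, chrom: str) -> slice:
        """Global-ordinal slice covering one chromosome."""
        ci = self.assembly.index_of(chrom)
        return slice(int(self._offsets[ci]), int(self._offsets[ci + 1]))

    def ordinal(self, chrom: str, pos: int) -> int:
        ci = self.assembly.index_of(chrom)
        if not 0 <= pos < self.assembly.chrom_lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self._offsets[ci] + pos // self.bin_size)

    def ordinals_at(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Vectorised ordinal lookup; positions must lie within their chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        ci = np.array([self.assembly.index_of(c) for c in chroms])
        lengths = np.array(self.assembly.chrom_lengths)[ci]
        if ((positions < 0) | (positions >= lengths)).any():
            raise ValueError("position outside chromosome bounds")
        return self._offsets[ci] + positions // self.bin_size

    def coordinates(self, ordinal: int) -> tuple[str, int, int]:
        """Inverse mapping: global ordinal -> (chrom, start, end)."""
        if not 0 <= ordinal < self.n_bins:
            raise IndexError(f"bin ordinal {ordinal} out of range")
        ci = int(np.searchsorted(self._offsets, ordinal, side="right") - 1)
        offset = ordinal - int(self._offsets[ci])
        chrom = self.assembly.chrom_names[ci]
        start = offset * self.bin_size
        end = min(start + self.bin_size, self.assembly.chrom_lengths[ci])
        return chrom, start, end

    def bin_starts(self) -> tuple[np.ndarray, np.ndarray]:
        """(chrom index, start) arrays for every bin in global order."""
        chrom_idx = np.repeat(
            np.arange(self.assembly.n_chroms), np.diff(self._offsets).astype(int)
        )
        within = np.arange(self.n_bins) - self._offsets[chrom_idx]
        return chrom_idx, within * self.bin_size


def bin_genome(assembly: GenomeAssembly, bin_size: int = 200) -> BinIndex:
    """Partition ``assembly`` into non-overlapping fixed-width bins."""
    return BinIndex(assembly, bin_size)


def intervals_to_bins(
    intervals: IntervalSet, bins: BinIndex, min_overlap: int = 1
) -> np.ndarray:
    """Project intervals onto the bin grid: bin=1 iff it overlaps >= ``min_overlap`` bp.

    Returns a uint8 vector over global bin ordinals.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    mask = np.zeros(bins.n_bins, dtype=np.uint8)
    bs = bins.bin_size
    asm = bins.assembly
    for chrom, sub in intervals.df.groupby("chrom", sort=False):
        if chrom not in asm:
            raise ValueError(f"interval on chromosome {chrom!r} not in assembly")
        chrom_len = asm.length_of(str(chrom))
        if int(sub["end"].max()) > chrom_len:
            raise ValueError(f"interval beyond end of {chrom}")
        base = bins.chrom_slice(str(chrom)).start
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            first = int(s) // bs
            last = (int(e) - 1) // bs
            if min_overlap == 1:
                mask[base + first : base + last + 1] = 1
            else:
                for b in range(first, last + 1):
                    b_start, b_end = b * bs, min((b + 1) * bs, chrom_len)
                    if min(int(e), b_end) - max(int(s), b_start) >= min_overlap:
                        mask[base + b] = 1
    return mask


def merge_bins(mask: np.ndarray, bins: BinIndex) -> IntervalSet:
    """Merge maximal runs of adjacent set bins into intervals (per chromosome)."""
    mask = np.asarray(mask)
    if mask.shape != (bins.n_bins,):
        raise ValueError(f"mask length {mask.shape} does not match {bins.n_bins} bins")
    rows = []
    bs = bins.bin_size
    for chrom, length in zip(bins.assembly.chrom_names, bins.assembly.chrom_lengths):
        sub = mask[bins.chrom_slice(chrom)].astype(np.int8)
        if not sub.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], sub, [0]])))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            rows.append((chrom, run_start * bs, min(run_end * bs, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df, bins.assembly)


def promoter_regions(
    genes: pd.DataFrame,
    assembly: GenomeAssembly | None = None,
    upstream: int = 2000,
    downstream: int = 500,
) -> IntervalSet:
    """Promoter windows around each TSS, strand-aware and clipped to bounds.

    ``+`` strand: [TSS-upstream, TSS+downstream); ``-`` strand mirrored.
    """
    bad = set(genes["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand value(s): {sorted(bad)}")
    tss = genes["tss"].to_numpy(dtype=np.int64)
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    start = np.maximum(start, 0)
    if assembly is not None:
        lengths = np.array([assembly.length_of(c) for c in genes["chrom"]])
        end = np.minimum(end, lengths)
    df = pd.DataFrame(
        {"chrom": genes["chrom"], "start": start, "end": end, "label": genes["gene_id"]}
    )
    return IntervalSet(df, assembly)


def split_proximal_distal(
    peaks: IntervalSet, promoters: IntervalSet
) -> tuple[IntervalSet, IntervalSet]:
    """Partition peaks into promoter-overlapping (proximal) and the rest (distal).

    Overlap rule: >= 1 bp with any promoter window.
    """
    trees = promoters.trees()
    flags = np.zeros(len(peaks), dtype=bool)
    for i, rec in enumerate(peaks.df.itertuples(index=False)):
        tree = trees.get(rec.chrom)
        if tree is not None and tree.overlaps(int(rec.start), int(rec.end)):
            flags[i] = True
    return peaks.subset(flags), peaks.subset(~flags)
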