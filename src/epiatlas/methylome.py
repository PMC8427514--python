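"""Per-CpG methylation handling and UMR/LMR hypomethylated-region calling.

Whole-genome bisulfite methylomes of normal somatic tissue are strongly
bimodal: most CpGs are highly methylated, while regulatory elements sit in
hypomethylated segments.  Hypomethylated segments are conventionally split
by CpG count into UMRs (unmethylated regions, CpG-rich, mostly promoters)
and LMRs (lowly methylated regions, CpG-poor, mostly distal regulatory
elements).

The segmentation here is deliberately simple and fully testable: candidate
regions are maximal runs of consecutive retained CpGs whose methylation
level is below a threshold, subject to a minimum run length n; n is chosen
as the smallest value whose permutation-estimated false discovery rate is
below the target.  The permutation null shuffles methylation levels across
the retained CpG positions, keeping the positional layout fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, IntervalSet

__all__ = [
    "CpGTable",
    "MethylSegConfig",
    "MethylRegion",
    "read_cpg_table",
    "write_cpg_table",
    "filter_coverage",
    "segment_hypomethylated",
    "methylation_histogram",
]


@dataclass
class CpGTable:
    """Per-CpG methylated/total read counts; positions 0-based.

    Backed by a DataFrame with columns chrom, pos, meth, total and a derived
    ``level`` column (meth/total).  Positions are strictly increasing within
    each chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "meth", "total"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"CpG table requires columns {sorted(required)}")
        df = self.df.copy()
        for col in ("pos", "meth", "total"):
            df[col] = df[col].astype(np.int64)
        if (df["meth"] > df["total"]).any() or (df["meth"] < 0).any():
            raise ValueError("need 0 <= meth <= total")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for _, sub in df.groupby("chrom", sort=False):
            if (np.diff(sub["pos"].to_numpy()) <= 0).any():
                raise ValueError("duplicate CpG positions within a chromosome")
        with np.errstate(invalid="ignore"):
            df["level"] = df["meth"] / df["total"]
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


def read_cpg_table(path: str | Path, one_based: bool = False) -> CpGTable:
    """Read a CpG counts TSV (chrom, pos, meth, total).

    Bismark coverage files are 1-based; pass ``one_based=True`` to convert.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if one_based:
        df = df.assign(pos=df["pos"] - 1)
    return CpGTable(df)


def write_cpg_table(cpgs: CpGTable, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        cpgs.df[["chrom", "pos", "meth", "total"]].to_csv(fh, sep="\t", index=False)


@dataclass
class MethylSegConfig:
    """Tuning knobs of the hypomethylated-region caller.

    min_coverage: reads per CpG required to retain it (default 5).
    meth_threshold: a CpG counts as hypomethylated below this level (0.5).
    min_cpgs: smallest run length considered (default 5).
    fdr_target: permutation FDR required of the chosen run length (0.05).
    umr_cpg_cutoff: runs with at least this many CpGs are UMRs, else LMRs (30).
    """

    min_coverage: int = 5
    meth_threshold: float = 0.5
    min_cpgs: int = 5
    fdr_target: float = 0.05
    umr_cpg_cutoff: int = 30
    n_permutations: int = 20
    seed: int = 0
    max_min_cpgs: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.meth_threshold < 1:
            raise ValueError("meth_threshold must lie in (0, 1)")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")


@dataclass
class MethylRegion:
    chrom: str
    start: int
    end: int
    klass: str  # "UMR" or "LMR"
    n_cpgs: int
    mean_methylation: float


def filter_coverage(cpgs: CpGTable, min_coverage: int = 5) -> CpGTable:
    """Keep CpGs with total coverage >= ``min_coverage`` (boundary inclusive)."""
    return CpGTable(cpgs.df[cpgs.df["total"] >= min_coverage])


def _runs(low: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first index, one-past-last index)."""
    edges = np.flatnonzero(np.diff(np.concatenate([[0], low.astype(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def _candidate_runs(df: pd.DataFrame, levels: np.ndarray, threshold: float) -> list[tuple[str, int, int]]:
    """Maximal below-threshold runs per chromosome as (chrom, i0, i1) row ranges."""
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        idx0 = sub.index[0]
        low = levels[sub.index.to_numpy()] < threshold
        for a, b in _runs(low):
            out.append((str(chrom), idx0 + a, idx0 + b))
    return out


def segment_hypomethylated(
    cpgs: CpGTable, cfg: MethylSegConfig | None = None
) -> tuple[list[MethylRegion], int, float]:
    """Call UMR/LMR regions from a coverage-filtered CpG table.

    Returns (regions, chosen min_cpgs n, achieved FDR at n).  The run-length
    cutoff n is the smallest value >= cfg.min_cpgs whose permutation FDR
    (mean permuted candidate count over observed count) is below
    cfg.fdr_target; if nothing qualifies up to cfg.max_min_cpgs the result
    is empty and a warning is issued.  Region intervals span the first to
    last CpG of the run (end exclusive at last position + 1); regions with
    >= cfg.umr_cpg_cutoff CpGs are UMRs, the rest LMRs.
    """
    cfg = cfg or MethylSegConfig()
    if cfg.n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    df = cpgs.df
    levels = df["level"].to_numpy()
    runs = _candidate_runs(df, levels, cfg.meth_threshold)
    run_lengths = np.array([b - a for _, a, b in runs], dtype=int)

    rng = np.random.default_rng(cfg.seed)
    perm_lengths = []
    for _ in range(cfg.n_permutations):
        shuffled = rng.permutation(levels)
        perm = _candidate_runs(df, shuffled, cfg.meth_threshold)
        perm_lengths.append(np.array([b - a for _, a, b in perm], dtype=int))

    chosen_n, achieved = None, np.nan
    for n in range(cfg.min_cpgs, cfg.max_min_cpgs + 1):
        observed = int((run_lengths >= n).sum())
        if observed == 0:
            continue
        null_mean = float(np.mean([(pl >= n).sum() for pl in perm_lengths]))
        fdr = null_mean / observed
        if fdr < cfg.fdr_target:
            chosen_n, achieved = n, fdr
            break
    if chosen_n is None:
        warnings.warn(
            f"no run length up to {cfg.max_min_cpgs} reaches FDR < {cfg.fdr_target}; "
            "no hypomethylated regions called"
        )
        return [], cfg.min_cpgs, achieved

    pos = df["pos"].to_numpy()
    regions = []
    for chrom, a, b in runs:
        n_cpgs = b - a
        if n_cpgs < chosen_n:
            continue
        regions.append(
            MethylRegion(
                chrom=chrom,
                start=int(pos[a]),
                end=int(pos[b - 1]) + 1,
                klass="UMR" if n_cpgs >= cfg.umr_cpg_cutoff else "LMR",
                n_cpgs=int(n_cpgs),
                mean_methylation=float(levels[a:b].mean()),
            )
        )
    return regions, chosen_n, achieved


def regions_to_intervals(
    regions: list[MethylRegion], assembly: GenomeAssembly | None = None
) -> IntervalSet:
    """UMR/LMR regions as a labeled IntervalSet (BED4-writable)."""
    df = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.klass) for r in regions],
        columns=["chrom", "start", "end", "label"],
    )
    return IntervalSet(df, assembly)


def methylation_histogram(cpgs: CpGTable, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of per-CpG methylation levels over [0, 1].

    Returns (mass per bin summing to 1, bin edges).  Methylomes of normal
    somatic tissue show a bimodal shape: a large mode near 1 and a smaller
    mode near 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(cpgs) == 0:
        raise ValueError("empty CpG table")
    counts, edges = np.histogram(cpgs.df["level"].to_numpy(), bins=n_bins, range=(0.0, 1.0))
    return counts / counts.sum(), edges
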