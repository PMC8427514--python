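"""GWAS catalog pruning and hypergeometric enrichment in enhancer states.

Trait-associated SNPs from the same study are correlated through linkage;
before testing, each study's SNPs are greedily pruned so that no two
retained SNPs lie within 1 Mb on the same chromosome (scanning in genomic
order and keeping a SNP only when no already-kept SNP is closer than the
cutoff; a distance of exactly the cutoff is kept).  Enrichment of a study's
pruned SNPs in active-enhancer territory is then scored with the
hypergeometric upper tail against the pooled pruned catalog as background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, IntervalSet

__all__ = [
    "GWASCatalog",
    "EnrichmentResult",
    "read_gwas_catalog",
    "prune_snps",
    "prune_catalog",
    "filter_studies",
    "hypergeom_sf",
    "enhancer_enrichment",
]


@dataclass
class GWASCatalog:
    """Study-grouped SNP records; positions 0-based internally."""

    df: pd.DataFrame  # columns: study, rsid, chrom, pos

    def __post_init__(self) -> None:
        required = {"study", "rsid", "chrom", "pos"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"catalog requires columns {sorted(required)}")
        df = self.df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df.sort_values(["study", "chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def studies(self) -> list[str]:
        return list(pd.unique(self.df["study"]))

    def __len__(self) -> int:
        return len(self.df)


def read_gwas_catalog(path: str | Path, one_based: bool = True) -> GWASCatalog:
    """Read a catalog TSV (study, rsid, chrom, pos); positions 1-based by default."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if one_based:
        df = df.assign(pos=df["pos"] - 1)
    return GWASCatalog(df)


def prune_snps(
    chroms: np.ndarray, positions: np.ndarray, min_dist: int = 1_000_000
) -> np.ndarray:
    """Greedy positional pruning of one study's SNPs.

    Input must be sorted by (chrom, pos).  Scanning in order, a SNP is kept
    iff no already-kept SNP on the same chromosome lies strictly closer than
    ``min_dist`` (exactly ``min_dist`` apart is kept).  Returns a boolean
    keep-mask.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    order_ok = True
    for i in range(1, len(positions)):
        if chroms[i] == chroms[i - 1] and positions[i] < positions[i - 1]:
            order_ok = False
            break
    if not order_ok:
        raise ValueError("SNPs must be sorted by (chrom, pos)")
    keep = np.zeros(len(positions), dtype=bool)
    last_kept: dict = {}
    for i, (c, p) in enumerate(zip(chroms, positions)):
        lk = last_kept.get(c)
        if lk is None or p - lk >= min_dist:
            keep[i] = True
            last_kept[c] = p
    return keep


def prune_catalog(catalog: GWASCatalog, min_dist: int = 1_000_000) -> GWASCatalog:
    """Apply per-study greedy pruning to a whole catalog."""
    parts = []
    for _, sub in catalog.df.groupby("study", sort=False):
        keep = prune_snps(sub["chrom"].to_numpy(), sub["pos"].to_numpy(), min_dist)
        parts.append(sub[keep])
    return GWASCatalog(pd.concat(parts, ignore_index=True))


def filter_studies(
    catalog: GWASCatalog,
    min_snps: int = 2,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> GWASCatalog:
    """Drop excluded chromosomes (chrY by default; chrX retained), then
    studies reporting fewer than ``min_snps`` SNPs."""
    df = catalog.df[~catalog.df["chrom"].isin(exclude_chroms)]
    sizes = df.groupby("study")["rsid"].transform("size")
    return GWASCatalog(df[sizes >= min_snps])


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed via the log-space survival function; k = 0 returns exactly 1.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    study: str
    epigenome: str
    N: int  # background (pooled pruned catalog) size
    K: int  # background SNPs inside enhancers
    n: int  # study pruned SNPs
    k: int  # study SNPs inside enhancers
    fold: float
    p: float


def _in_intervals(chroms: np.ndarray, positions: np.ndarray, intervals: IntervalSet) -> np.ndarray:
    merged = intervals.merged()
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in merged.df.groupby("chrom", sort=False):
        per_chrom[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    out = np.zeros(len(positions), dtype=bool)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        if c not in per_chrom:
            continue
        starts, ends = per_chrom[c]
        j = int(np.searchsorted(starts, p, side="right"))
        out[i] = j > 0 and ends[j - 1] > p
    return out


def enhancer_enrichment(
    catalog: GWASCatalog, enhancers: IntervalSet, epigenome: str
) -> list[EnrichmentResult]:
    """Per-study hypergeometric enrichment of pruned SNPs in enhancers.

    Background = distinct SNP positions pooled over all studies of the
    (already pruned) catalog; a SNP overlaps an enhancer iff its position
    lies inside an enhancer interval.  fold = (k/n) / (K/N).
    """
    if len(enhancers) == 0:
        raise ValueError("empty enhancer set")
    if len(catalog) == 0:
        raise ValueError("empty background catalog")
    bg = catalog.df.drop_duplicates(subset=["chrom", "pos"])
    bg_hit = _in_intervals(bg["chrom"].to_numpy(), bg["pos"].to_numpy(), enhancers)
    N, K = len(bg), int(bg_hit.sum())
    hit_lookup = {
        (c, int(p)): bool(h)
        for c, p, h in zip(bg["chrom"], bg["pos"], bg_hit)
    }
    results = []
    for study, sub in catalog.df.groupby("study", sort=False):
        keys = list(zip(sub["chrom"], sub["pos"].astype(int)))
        if any(key not in hit_lookup for key in keys):
            raise ValueError(f"study {study!r} has SNPs outside the background")
        n = len(sub)
        k = sum(hit_lookup[key] for key in keys)
        fold = (k / n) / (K / N) if K > 0 else np.nan
        results.append(
            EnrichmentResult(
                study=str(study),
                epigenome=epigenome,
                N=N,
                K=K,
                n=n,
                k=k,
                fold=float(fold),
                p=hypergeom_sf(k, K, n, N),
            )
        )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.study, r.epigenome, r.N, r.K, r.n, r.k, r.fold, r.p)
            for r in results
        ],
        columns=["study", "epigenome", "N", "K", "n", "k", "fold", "p"],
    )
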