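"""Cross-epigenome active-enhancer atlas.

Active-enhancer chromatin states (EnhA1/EnhA2 in the 18-state vocabulary)
are a strong signature of tissue identity.  This module builds the bins x
epigenomes binary presence matrix of active-enhancer occupancy, calls
bins that are active in exactly one epigenome (tissue-specific enhancers),
quantifies epigenome similarity (Pearson correlation, complete-linkage
hierarchical clustering, classical MDS), clusters enhancer regions on
H3K27ac RPKM with k-means, and links genes to enhancers within a TSS
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .chromatin import StateSegmentation
from .genome import BinIndex, IntervalSet, merge_bins

__all__ = [
    "DEFAULT_ENHANCER_STATES",
    "PresenceMatrix",
    "active_enhancer_bins",
    "build_presence_matrix",
    "specific_enhancers",
    "shared_fraction",
    "epigenome_similarity",
    "rpkm",
    "kmeans_enhancer_clusters",
    "link_genes_to_enhancers",
]

DEFAULT_ENHANCER_STATES = ("9_EnhA1", "10_EnhA2")


@dataclass
class PresenceMatrix:
    """Binary bins x epigenomes matrix of active-enhancer occupancy.

    Rows are global bin ordinals restricted to bins active in at least one
    epigenome; column order is stable.
    """

    bin_ordinals: np.ndarray
    epigenomes: tuple[str, ...]
    values: np.ndarray  # (n_rows, n_epigenomes) uint8
    bins: BinIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.bin_ordinals), len(self.epigenomes)):
            raise ValueError("presence matrix shape mismatch")
        if len(self.bin_ordinals) and (self.values.sum(axis=1) == 0).any():
            raise ValueError("presence matrix contains an all-zero row")

    def column(self, epigenome: str) -> np.ndarray:
        try:
            j = self.epigenomes.index(epigenome)
        except ValueError:
            raise KeyError(f"unknown epigenome {epigenome!r}") from None
        return self.values[:, j]

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet representation (bin ordinal, epigenome, 1)."""
        rows, cols = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "bin": self.bin_ordinals[rows],
                "epigenome": [self.epigenomes[c] for c in cols],
                "present": 1,
            }
        )


def active_enhancer_bins(
    seg: StateSegmentation,
    bins: BinIndex,
    states: tuple[str, ...] = DEFAULT_ENHANCER_STATES,
) -> np.ndarray:
    """Binary vector: 1 where the bin carries an active-enhancer state."""
    if not states:
        raise ValueError("empty enhancer state set")
    unknown = set(states) - set(seg.mnemonics)
    if unknown:
        raise ValueError(f"unknown state mnemonics: {sorted(unknown)}")
    wanted = np.array([m in states for m in seg.mnemonics])
    return wanted[seg.states].astype(np.uint8)


def build_presence_matrix(
    segs: dict[str, StateSegmentation],
    states: tuple[str, ...] = DEFAULT_ENHANCER_STATES,
) -> PresenceMatrix:
    """Stack per-epigenome active-enhancer bin vectors into a presence matrix."""
    if not segs:
        raise ValueError("no segmentations supplied")
    ids = tuple(segs.keys())
    first = segs[ids[0]].bins
    cols = []
    for eid in ids:
        seg = segs[eid]
        if seg.bins.assembly != first.assembly or seg.bins.bin_size != first.bin_size:
            raise ValueError(f"epigenome {eid!r} uses a different assembly/bin size")
        cols.append(active_enhancer_bins(seg, seg.bins, states))
    stacked = np.stack(cols, axis=1)
    keep = stacked.any(axis=1)
    return PresenceMatrix(np.flatnonzero(keep), ids, stacked[keep], first)


def specific_enhancers(pm: PresenceMatrix, target: str) -> IntervalSet:
    """Bins active only in ``target`` across the panel, merged into intervals."""
    col = pm.column(target)
    exclusive = (col == 1) & (pm.values.sum(axis=1) == 1)
    mask = np.zeros(pm.bins.n_bins, dtype=np.uint8)
    mask[pm.bin_ordinals[exclusive]] = 1
    return merge_bins(mask, pm.bins)


def shared_fraction(pm: PresenceMatrix) -> float:
    """Fraction of active bins present in every epigenome of the panel."""
    if len(pm.epigenomes) < 2:
        raise ValueError("need >= 2 epigenomes")
    if len(pm.bin_ordinals) == 0:
        raise ValueError("empty presence matrix")
    return float((pm.values.min(axis=1) == 1).mean())


def shared_fraction_regions(pm: PresenceMatrix) -> float:
    """Region-level variant: fraction of merged union regions fully shared."""
    union = np.zeros(pm.bins.n_bins, dtype=np.uint8)
    union[pm.bin_ordinals] = 1
    all_on = np.zeros(pm.bins.n_bins, dtype=np.uint8)
    all_on[pm.bin_ordinals[pm.values.min(axis=1) == 1]] = 1
    regions = merge_bins(union, pm.bins)
    if len(regions) == 0:
        raise ValueError("empty presence matrix")
    bs = pm.bins.bin_size
    shared = 0
    for rec in regions.df.itertuples(index=False):
        base = pm.bins.chrom_slice(rec.chrom).start
        sl = slice(base + rec.start // bs, base + (rec.end - 1) // bs + 1)
        if all_on[sl].all():
            shared += 1
    return shared / len(regions)


def _classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center the squared distances and eigendecompose."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.maximum(vals[order], 0.0)
    return vecs[:, order] * np.sqrt(vals)


def epigenome_similarity(pm: PresenceMatrix) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Pairwise Pearson correlation of epigenome columns, with clustering.

    Returns (correlation matrix, complete-linkage dendrogram in scipy
    linkage form on distance 1 - r, 2-D classical MDS coordinates).
    Constant columns have no defined correlation and are rejected by name.
    """
    if len(pm.epigenomes) < 3:
        raise ValueError("need >= 3 epigenomes")
    X = pm.values.astype(float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [e for e, s in zip(pm.epigenomes, sd) if s == 0]
        raise ValueError(f"constant presence column(s): {bad}")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="complete")
    coords = _classical_mds(d)
    ids = list(pm.epigenomes)
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        z,
        pd.DataFrame(coords, index=ids, columns=["mds1", "mds2"]),
    )


def rpkm(
    counts: pd.DataFrame, regions: IntervalSet, totals: dict[str, float] | pd.Series
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per region and sample.

    RPKM = count * 1e9 / (region length in bp * total mapped reads).
    """
    totals = pd.Series(totals)
    if (totals <= 0).any():
        raise ValueError("total mapped reads must be positive")
    lengths = (regions.df["end"] - regions.df["start"]).to_numpy(dtype=float)
    if len(lengths) != len(counts):
        raise ValueError("count rows do not match regions")
    out = counts.astype(float).copy()
    for col in out.columns:
        out[col] = out[col].to_numpy() * 1e9 / (lengths * float(totals[col]))
    return out


def kmeans_enhancer_clusters(
    sm: pd.DataFrame, k: int = 9, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """K-means clustering of enhancer regions on normalized signal.

    Seeded k-means++ with ``n_restarts`` initialisations keeping the best
    inertia; returned labels are 1..k ordered by descending cluster mean
    intensity (cluster 1 = hottest), so labels are comparable across runs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = sm.to_numpy(dtype=float)
    if k > len(X):
        raise ValueError("k exceeds the number of regions")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed).fit(X)
    raw = km.labels_
    means = np.array([X[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)])
    rank = np.argsort(np.argsort(-means))
    return rank[raw] + 1


def link_genes_to_enhancers(
    genes: pd.DataFrame, enhancers: IntervalSet, flank: int = 20_000
) -> tuple[pd.Series, float]:
    """Flag genes with an enhancer within +/- ``flank`` bp of the TSS.

    A gene links when any enhancer overlaps [TSS - flank, TSS + flank) by at
    least 1 bp.  Returns (per-gene boolean Series indexed by gene_id,
    linked fraction).
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    merged = enhancers.merged()
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in merged.df.groupby("chrom", sort=False):
        per_chrom[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    flags = []
    for rec in genes.itertuples(index=False):
        w0, w1 = max(int(rec.tss) - flank, 0), int(rec.tss) + flank
        hit = False
        if rec.chrom in per_chrom:
            starts, ends = per_chrom[rec.chrom]
            i = int(np.searchsorted(starts, w1))  # first enhancer starting at/after window end
            hit = i > 0 and ends[i - 1] > w0
        flags.append(hit)
    series = pd.Series(flags, index=genes["gene_id"].to_numpy(), name="linked")
    return series, float(np.mean(flags))
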