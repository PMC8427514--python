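"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: binary histone-mark
tracks emitted from a known Bernoulli-emission HMM, bimodal CpG methylomes
with planted hypomethylated regions, multi-tissue TPM matrices with planted
fold-enriched genes, panels of epigenome segmentations with planted
tissue-specific enhancer bins, and GWAS catalogs with planted
enhancer-overlap enrichment.  Generators are deterministic given their seed
and return the generating truth alongside the dataset, so recovery tests
never need simulator internals.

The default toy genome is two chromosomes of 2 Mb (20,000 bins of 200 bp),
small enough that the full demo pipeline runs in well under a minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import BinnedTrack, HMMModel, StateSegmentation
from .genome import BinIndex, GenomeAssembly, IntervalSet, bin_genome, merge_bins

__all__ = [
    "simulate_assembly",
    "example_model",
    "simulate_marks",
    "simulate_raw_tracks",
    "simulate_methylome",
    "simulate_bimodal_values",
    "simulate_expression",
    "simulate_genes",
    "simulate_epigenome_panel",
    "simulate_gwas_catalog",
]

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K36me3", "H3K27me3", "H3K9me3")


def simulate_assembly(
    n_chroms: int = 2, lengths: list[int] | None = None, bin_size: int = 200
) -> GenomeAssembly:
    """A deterministic toy assembly (default 2 chromosomes of 2 Mb)."""
    if lengths is None:
        lengths = [2_000_000] * n_chroms
    if len(lengths) != n_chroms:
        raise ValueError("lengths must match n_chroms")
    if any(length < bin_size for length in lengths):
        raise ValueError("chromosome shorter than one bin")
    return GenomeAssembly(
        tuple(f"chr{i + 1}" for i in range(n_chroms)), tuple(int(v) for v in lengths)
    )


def example_model(n_states: int = 5, self_transition: float = 0.97) -> HMMModel:
    """A well-separated reference model over the six canonical histone marks.

    The five-state default mimics the broad groups of an 18-state map:
    active promoter (1_TssA), transcription (5_Tx), active enhancer
    (9_EnhA1), Polycomb repression (15_ReprPC) and quiescent chromatin
    (18_Quies).  Larger ``n_states`` adds intermediate states with random
    but fixed emissions.
    """
    base = {
        "1_TssA": [0.95, 0.30, 0.80, 0.05, 0.02, 0.02],
        "5_Tx": [0.05, 0.10, 0.05, 0.90, 0.02, 0.02],
        "9_EnhA1": [0.10, 0.90, 0.85, 0.05, 0.02, 0.02],
        "15_ReprPC": [0.05, 0.05, 0.02, 0.02, 0.90, 0.05],
        "18_Quies": [0.02, 0.02, 0.02, 0.02, 0.02, 0.02],
    }
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    names = list(base)[:n_states]
    emissions = np.array([base[n] for n in names])
    while len(names) < n_states:
        extra_rng = np.random.default_rng(len(names))
        names.append(f"X{len(names) + 1}")
        emissions = np.vstack([emissions, extra_rng.uniform(0.02, 0.95, len(MARKS))])
    k = len(names)
    transitions = np.full((k, k), (1 - self_transition) / (k - 1))
    np.fill_diagonal(transitions, self_transition)
    return HMMModel(
        marks=MARKS,
        initial=np.full(k, 1.0 / k),
        transitions=transitions,
        emissions=emissions,
        mnemonics=tuple(names),
    )


def simulate_marks(
    model: HMMModel, assembly: GenomeAssembly, seed: int, bin_size: int = 200
) -> tuple[list[BinnedTrack], np.ndarray, BinIndex]:
    """Sample a state path from the Markov chain and emit binary mark tracks.

    Chromosomes are independent sequences.  Returns (tracks, true per-bin
    state path, bin index).
    """
    rng = np.random.default_rng(seed)
    bins = bin_genome(assembly, bin_size)
    states = np.empty(bins.n_bins, dtype=np.int32)
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transitions, axis=1)
    for chrom in assembly.chrom_names:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        u = rng.random(n)
        path = np.empty(n, dtype=np.int32)
        path[0] = np.searchsorted(cum_init, u[0])
        for t in range(1, n):
            path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t])
        states[sl] = path
    X = (rng.random((bins.n_bins, len(model.marks))) < model.emissions[states]).astype(np.uint8)
    tracks = [
        BinnedTrack(mark, X[:, m], bins, binary=True) for m, mark in enumerate(model.marks)
    ]
    return tracks, states, bins


def simulate_raw_tracks(
    binary_tracks: list[BinnedTrack],
    seed: int,
    lam_background: float = 2.0,
    lam_signal: float = 30.0,
) -> list[BinnedTrack]:
    """Raw per-bin read counts consistent with given binary calls.

    Bins called present draw counts from Poisson(lam_signal), absent bins
    from Poisson(lam_background); used to exercise the binarization step.
    """
    rng = np.random.default_rng(seed)
    out = []
    for track in binary_tracks:
        lam = np.where(track.values == 1, lam_signal, lam_background)
        out.append(BinnedTrack(track.mark, rng.poisson(lam), track.bins, binary=False))
    return out


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTruth:
    planted: IntervalSet  # intervals spanning the planted hypomethylated runs
    planted_cpg_runs: list[tuple[int, int]]  # row ranges in the emitted table


def simulate_methylome(
    assembly: GenomeAssembly,
    n_cpgs: int = 50_000,
    seed: int = 0,
    n_planted: int = 30,
    planted_width: int = 20,
    background_beta: tuple[float, float] = (9.0, 1.0),
    planted_beta: tuple[float, float] = (1.0, 9.0),
    coverage_mean: float = 22.0,
):
    """A bimodal CpG methylome with planted hypomethylated regions.

    Background CpG methylation levels follow Beta(9, 1) (highly methylated
    mode), planted regions Beta(1, 9); per-CpG coverage is Poisson with mean
    22 and methylated counts are Binomial(coverage, level).  Planted regions
    are runs of ``planted_width`` consecutive CpGs, non-overlapping and
    separated by at least one background CpG.
    """
    from .methylome import CpGTable

    rng = np.random.default_rng(seed)
    lengths = np.array(assembly.chrom_lengths, dtype=float)
    n_per = np.maximum((n_cpgs * lengths / lengths.sum()).astype(int), 1)
    frames = []
    for chrom, n in zip(assembly.chrom_names, n_per):
        pos = np.sort(
            rng.choice(assembly.length_of(chrom), size=int(n), replace=False)
        )
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    df = pd.concat(frames, ignore_index=True)
    total_rows = len(df)

    # choose planted runs of consecutive CpG rows, buffered by >= 2 rows
    needed = n_planted * (planted_width + 2)
    if needed > total_rows:
        raise ValueError("planted regions do not fit in the CpG table")
    runs: list[tuple[int, int]] = []
    taken = np.zeros(total_rows, dtype=bool)
    chrom_codes = pd.factorize(df["chrom"])[0]
    attempts = 0
    while len(runs) < n_planted:
        attempts += 1
        if attempts > 100 * n_planted:
            raise ValueError("could not place planted regions without overlap")
        a = int(rng.integers(0, total_rows - planted_width))
        b = a + planted_width
        if chrom_codes[a] != chrom_codes[b - 1]:
            continue
        if taken[max(a - 2, 0) : min(b + 2, total_rows)].any():
            continue
        taken[a:b] = True
        runs.append((a, b))
    runs.sort()

    levels = rng.beta(*background_beta, size=total_rows)
    for a, b in runs:
        levels[a:b] = rng.beta(*planted_beta, size=b - a)
    total = rng.poisson(coverage_mean, size=total_rows)
    meth = rng.binomial(total, levels)
    table = CpGTable(df.assign(meth=meth, total=total))

    pos = table.df["pos"].to_numpy()
    chroms = table.df["chrom"].to_numpy()
    truth_df = pd.DataFrame(
        [(chroms[a], int(pos[a]), int(pos[b - 1]) + 1) for a, b in runs],
        columns=["chrom", "start", "end"],
    )
    return table, MethylomeTruth(IntervalSet(truth_df, assembly), runs)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

DEFAULT_MIXTURE = (0.45, -6.0, 1.0, 0.55, 4.0, 1.5)


def simulate_bimodal_values(
    n: int,
    seed: int = 0,
    mixture: tuple[float, float, float, float, float, float] = DEFAULT_MIXTURE,
) -> tuple[np.ndarray, np.ndarray]:
    """Draws from a two-component Gaussian mixture with component labels.

    mixture = (w1, mu1, sd1, w2, mu2, sd2); component 0 is the low
    (repressed) mode, component 1 the high (expressed) mode.
    """
    w1, mu1, sd1, w2, mu2, sd2 = mixture
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < w2).astype(int)
    values = np.where(
        labels == 1, rng.normal(mu2, sd2, n), rng.normal(mu1, sd1, n)
    )
    return values, labels


@dataclass
class ExpressionTruth:
    component: np.ndarray  # 0 repressed / 1 expressed, per gene
    category: pd.Series  # planted specificity category per gene id


def simulate_expression(
    n_genes: int = 2_000,
    tissues: list[str] | None = None,
    target: str = "prostate",
    seed: int = 0,
    mixture: tuple[float, float, float, float, float, float] = DEFAULT_MIXTURE,
    planted: dict[str, int] | None = None,
    planted_fold: float = 4.5,
    subthreshold_fold: float = 3.9,
    tissue_noise_sd: float = 0.25,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Multi-tissue TPM matrix with planted specificity categories.

    Background genes draw a base log2 expression from the bimodal mixture
    and jitter it per tissue; planted genes are constructed exactly at the
    intended fold ratios (no per-tissue noise) so that rule boundaries are
    sharp: ``enriched`` genes sit at ``planted_fold`` times the highest
    other tissue, ``group`` genes place a 3-tissue group at the fold over
    the rest, ``enhanced`` genes exceed the mean (but not the max) of a
    graded background, ``subfold`` genes sit at ``subthreshold_fold`` times
    the highest other tissue, and ``low`` genes have the enriched profile
    scaled to target TPM below 1.
    """
    if tissues is None:
        tissues = [target] + [f"tissue{i:02d}" for i in range(1, 14)]
    if target not in tissues:
        raise ValueError("target must be among tissues")
    others = [t for t in tissues if t != target]
    if len(others) < 5:
        raise ValueError("need at least 6 tissues for planted categories")
    planted = dict(planted or {"enriched": 20, "group": 10, "enhanced": 10, "subfold": 10, "low": 10})
    n_planted = sum(planted.values())
    if n_planted > n_genes:
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(seed)

    base, component = simulate_bimodal_values(n_genes, seed=int(rng.integers(2**31)), mixture=mixture)
    log_m = base[:, None] + rng.normal(0.0, tissue_noise_sd, (n_genes, len(tissues)))
    tpm = np.clip(2.0**log_m - 0.01, 0.0, None)
    m = pd.DataFrame(tpm, columns=tissues, index=[f"g{i:05d}" for i in range(n_genes)])
    ti = {t: j for j, t in enumerate(tissues)}

    category = pd.Series("background", index=m.index)
    gene_rows = rng.permutation(n_genes)[:n_planted]
    cursor = 0

    def next_rows(count: int) -> np.ndarray:
        nonlocal cursor
        rows = gene_rows[cursor : cursor + count]
        cursor += count
        return rows

    for row in next_rows(planted.get("enriched", 0)):
        vals = rng.uniform(2.0, 6.0, len(others))
        m.iloc[row, [ti[t] for t in others]] = vals
        m.iloc[row, ti[target]] = planted_fold * vals.max()
        category.iloc[row] = "enriched"
        component[row] = 1
    for row in next_rows(planted.get("group", 0)):
        group = list(rng.choice(others, 2, replace=False))
        outside = [t for t in others if t not in group]
        out_vals = rng.uniform(1.0, 4.0, len(outside))
        level = planted_fold * out_vals.max()
        m.iloc[row, [ti[t] for t in outside]] = out_vals
        m.iloc[row, [ti[t] for t in group]] = level
        m.iloc[row, ti[target]] = level
        category.iloc[row] = "group"
        component[row] = 1
    for row in next_rows(planted.get("enhanced", 0)):
        vals = np.linspace(10.0, 30.0, len(others))
        m.iloc[row, [ti[t] for t in others]] = vals
        m.iloc[row, ti[target]] = planted_fold * vals.mean()
        category.iloc[row] = "enhanced"
        component[row] = 1
    for row in next_rows(planted.get("subfold", 0)):
        vals = rng.uniform(2.0, 6.0, len(others))
        m.iloc[row, [ti[t] for t in others]] = vals
        m.iloc[row, ti[target]] = subthreshold_fold * vals.max()
        category.iloc[row] = "subfold"
        component[row] = 1
    for row in next_rows(planted.get("low", 0)):
        vals = rng.uniform(0.01, 0.1, len(others))
        m.iloc[row, [ti[t] for t in others]] = vals
        m.iloc[row, ti[target]] = 0.8
        category.iloc[row] = "low"
    return m, ExpressionTruth(component, category)


def simulate_genes(
    assembly: GenomeAssembly, n_genes: int = 100, seed: int = 0
) -> pd.DataFrame:
    """A toy gene annotation (gene_id, chrom, strand, tss, tes)."""
    rng = np.random.default_rng(seed)
    rows = []
    lengths = np.array(assembly.chrom_lengths, dtype=float)
    n_per = np.maximum((n_genes * lengths / lengths.sum()).astype(int), 1)
    n_per[0] += n_genes - n_per.sum()
    g = 0
    for chrom, n in zip(assembly.chrom_names, n_per):
        chrom_len = assembly.length_of(chrom)
        tss = np.sort(rng.choice(np.arange(5_000, chrom_len - 5_000), int(n), replace=False))
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            span = int(rng.integers(2_000, 20_000))
            tes = min(t + span, chrom_len - 1) if strand == "+" else max(t - span, 0)
            rows.append((f"g{g:05d}", chrom, strand, int(t), int(tes)))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])


# ---------------------------------------------------------------------------
# epigenome panel
# ---------------------------------------------------------------------------

@dataclass
class PanelTruth:
    specific_bins: dict[str, np.ndarray]  # epigenome -> planted exclusive bin ordinals
    shared_bins: np.ndarray


def simulate_epigenome_panel(
    assembly: GenomeAssembly,
    n_epigenomes: int = 20,
    seed: int = 0,
    bin_size: int = 200,
    shared_rate: float = 0.02,
    noise_rate: float = 0.01,
    planted_specific: dict[str, int] | int = 200,
    enhancer_state: str = "9_EnhA1",
    quiescent_state: str = "18_Quies",
) -> tuple[dict[str, StateSegmentation], PanelTruth, BinIndex]:
    """A panel of epigenome segmentations with planted exclusive enhancer bins.

    Each epigenome's active-enhancer territory is a shared backbone (a
    ``shared_rate`` fraction of bins active in every epigenome) plus noise
    bins and its planted exclusive bins.  Noise bins are each assigned to at
    least two epigenomes, so the planted bins are exactly the
    single-epigenome bins of the panel — recovery tests can assert set
    equality rather than approximate overlap.
    """
    if not 0 < shared_rate < 1 or not 0 <= noise_rate < 1:
        raise ValueError("rates must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    bins = bin_genome(assembly, bin_size)
    ids = [f"E{i + 1:03d}" for i in range(n_epigenomes)]
    if isinstance(planted_specific, int):
        planted_specific = {ids[0]: planted_specific}
    unknown = set(planted_specific) - set(ids)
    if unknown:
        raise ValueError(f"planted epigenomes not in panel: {sorted(unknown)}")

    n_bins = bins.n_bins
    free = rng.permutation(n_bins)
    n_shared = int(shared_rate * n_bins)
    shared = free[:n_shared]
    cursor = n_shared
    specific: dict[str, np.ndarray] = {}
    for eid, count in planted_specific.items():
        specific[eid] = np.sort(free[cursor : cursor + count])
        cursor += count
    n_noise = int(noise_rate * n_bins)
    noise_pool = free[cursor : cursor + n_noise]

    active = {eid: np.zeros(n_bins, dtype=bool) for eid in ids}
    for eid in ids:
        active[eid][shared] = True
        if eid in specific:
            active[eid][specific[eid]] = True
    for b in noise_pool:
        members = rng.choice(n_epigenomes, size=int(rng.integers(2, min(4, n_epigenomes) + 1)), replace=False)
        for j in members:
            active[ids[j]][b] = True

    mnemonics = (enhancer_state, quiescent_state)
    segs = {
        eid: StateSegmentation(
            np.where(active[eid], 0, 1).astype(np.int32), bins, mnemonics
        )
        for eid in ids
    }
    return segs, PanelTruth(specific, np.sort(shared)), bins


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------

@dataclass
class GWASTruth:
    enriched_studies: tuple[str, ...]
    enhancers: IntervalSet
    hit_rate: dict[str, float]


def simulate_gwas_catalog(
    assembly: GenomeAssembly,
    n_studies: int = 50,
    seed: int = 0,
    snps_per_study: tuple[int, int] = (40, 120),
    enriched_studies: dict[str, float] | None = None,
    background_rate: float = 0.1,
    enhancer_coverage: float = 0.3,
    slot_size: int = 2_000_000,
    usable: int = 1_000_000,
):
    """A GWAS catalog with planted enhancer-overlap enrichment.

    The genome is divided into ``slot_size`` slots whose first ``usable`` bp
    hold SNPs; the leading ``enhancer_coverage`` fraction of each usable
    window is enhancer territory.  Each study's SNPs occupy distinct slots,
    so per-study positions are always >= 1 Mb apart and survive megabase
    pruning unchanged.  Each SNP falls inside enhancer territory with the
    study's hit rate (``background_rate`` unless listed in
    ``enriched_studies``).  Returns (catalog with 0-based positions, truth).
    """
    from .gwas import GWASCatalog

    if usable > slot_size:
        raise ValueError("usable window larger than slot")
    enriched_studies = dict(enriched_studies or {})
    if any(r <= background_rate for r in enriched_studies.values()):
        raise ValueError("enriched rate must exceed background rate")
    rng = np.random.default_rng(seed)

    slots = []  # (chrom, slot_start)
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        for s in range(0, length - usable + 1, slot_size):
            slots.append((chrom, s))
    if len(slots) < snps_per_study[1]:
        raise ValueError("genome too small for requested SNPs per study")

    enh_width = int(enhancer_coverage * usable)
    enh_rows = [(c, s, s + enh_width) for c, s in slots]
    enhancers = IntervalSet(pd.DataFrame(enh_rows, columns=["chrom", "start", "end"]), assembly)

    rows = []
    hit_rate = {}
    for i in range(n_studies):
        study = f"study{i + 1:04d}"
        rate = enriched_studies.get(study, background_rate)
        hit_rate[study] = rate
        n = int(rng.integers(snps_per_study[0], snps_per_study[1] + 1))
        chosen = rng.choice(len(slots), size=n, replace=False)
        hits = rng.random(n) < rate
        for slot_idx, hit in zip(chosen, hits):
            chrom, s = slots[slot_idx]
            if hit:
                pos = s + int(rng.integers(0, enh_width))
            else:
                pos = s + enh_width + int(rng.integers(0, usable - enh_width))
            rows.append((study, f"rs{len(rows) + 1}", chrom, pos))
    df = pd.DataFrame(rows, columns=["study", "rsid", "chrom", "pos"])
    truth = GWASTruth(tuple(enriched_studies), enhancers, hit_rate)
    return GWASCatalog(df), truth
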