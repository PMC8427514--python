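"""Chromatin-state segmentation from binarized histone-mark tracks.

The model is a hidden Markov model over fixed-width genomic bins with
conditionally independent Bernoulli emissions: given the hidden state of a
bin, each histone mark is present (1) or absent (0) with a state-specific
probability.  This is the model class used for multi-mark chromatin-state
maps (e.g. the 18-state reference epigenomes), where states such as
``1_TssA`` (active promoter), ``9_EnhA1``/``10_EnhA2`` (active enhancer) or
``18_Quies`` (quiescent) are recurrent combinations of mark presence.

Provided here:

* Poisson-background binarization of raw per-bin read counts,
* reading/writing the ChromHMM model text dialect and paired TSV tables,
* Baum-Welch training of the product-Bernoulli HMM,
* posterior decoding into a genome-wide state segmentation,
* overlap / neighborhood fold-enrichment and per-state signal summaries.

Chromosomes are treated as independent observation sequences; all
forward-backward arithmetic uses per-position scaling, never raw products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genome import BinIndex, IntervalSet

__all__ = [
    "BinnedTrack",
    "HMMModel",
    "StateSegmentation",
    "binarize_track",
    "load_chromhmm_model",
    "save_chromhmm_model",
    "train_model",
    "segment",
    "overlap_enrichment",
    "neighborhood_enrichment",
    "state_coverage",
    "aggregate_signal_by_state",
]

_PROB_FLOOR = 1e-6


@dataclass
class BinnedTrack:
    """Per-bin values for one histone mark: raw read counts or binary calls."""

    mark: str
    values: np.ndarray
    bins: BinIndex
    binary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} does not match {self.bins.n_bins} bins"
            )
        if self.binary:
            if not np.isin(self.values, [0, 1]).all():
                raise ValueError("binary track contains values outside {0,1}")
            self.values = self.values.astype(np.uint8)
        else:
            if (self.values < 0).any():
                raise ValueError("raw counts must be >= 0")


@dataclass
class HMMModel:
    """Multivariate Bernoulli-emission HMM over genomic bins.

    ``emissions[s, m]`` is the probability that mark ``m`` is present in a
    bin of state ``s``; ``transitions`` is row-stochastic; ``mnemonics``
    gives the conventional state labels (ordinal order).
    """

    marks: tuple[str, ...]
    initial: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray
    mnemonics: tuple[str, ...]
    loglik_trace: list[float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        n = self.n_states
        if self.transitions.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if self.emissions.shape != (n, len(self.marks)):
            raise ValueError("emission matrix shape mismatch")
        if len(self.mnemonics) != n or len(set(self.mnemonics)) != n:
            raise ValueError("mnemonics must be bijective with state ordinals")
        if abs(self.initial.sum() - 1.0) > 1e-6:
            raise ValueError("initial distribution does not sum to 1")
        row_err = np.abs(self.transitions.sum(axis=1) - 1.0)
        if (row_err > 1e-6).any():
            raise ValueError("transition rows do not sum to 1")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emission probabilities outside [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.initial)


@dataclass
class StateSegmentation:
    """Genome-wide per-bin state assignment with its interval representation."""

    states: np.ndarray  # state ordinal per global bin
    bins: BinIndex
    mnemonics: tuple[str, ...]
    max_posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int32)
        if self.states.shape != (self.bins.n_bins,):
            raise ValueError("state vector length does not match bin count")
        if len(self.states) and (self.states.max() >= len(self.mnemonics) or self.states.min() < 0):
            raise ValueError("state ordinal outside mnemonic table")

    def intervals(self) -> IntervalSet:
        """Adjacent same-state bins merged into labeled intervals."""
        rows = []
        bs = self.bins.bin_size
        for chrom, length in zip(
            self.bins.assembly.chrom_names, self.bins.assembly.chrom_lengths
        ):
            sub = self.states[self.bins.chrom_slice(chrom)]
            change = np.flatnonzero(np.diff(sub)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(sub)]])
            for b0, b1 in zip(starts, ends):
                rows.append(
                    (chrom, int(b0) * bs, min(int(b1) * bs, length), self.mnemonics[sub[b0]])
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        return IntervalSet(df, self.bins.assembly)

    def to_bed(self, path: str | Path, header: str | None = None) -> None:
        from .genome import write_bed

        write_bed(self.intervals(), path, header=header)

    @classmethod
    def from_intervals(
        cls, intervals: IntervalSet, bins: BinIndex, mnemonics: Sequence[str]
    ) -> "StateSegmentation":
        """Rebuild the per-bin state vector from a labeled segmentation BED.

        Intervals must tile every chromosome; each bin takes the label of the
        interval covering its start.
        """
        mnemonics = tuple(mnemonics)
        lookup = {m: i for i, m in enumerate(mnemonics)}
        states = np.full(bins.n_bins, -1, dtype=np.int32)
        bs = bins.bin_size
        for rec in intervals.df.itertuples(index=False):
            if rec.label not in lookup:
                raise ValueError(f"label {rec.label!r} not in mnemonic table")
            base = bins.chrom_slice(rec.chrom).start
            first = int(rec.start) // bs
            last = (int(rec.end) - 1) // bs
            states[base + first : base + last + 1] = lookup[rec.label]
        if (states < 0).any():
            raise ValueError("segmentation does not cover every bin")
        return cls(states, bins, mnemonics)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize_track(
    signal: BinnedTrack,
    control: BinnedTrack | None = None,
    p_threshold: float = 1e-4,
) -> BinnedTrack:
    """Call per-bin mark presence by a Poisson upper-tail test.

    The expected count in a bin is the depth-scaled control count, floored at
    the genome-wide mean signal per bin; a bin is called present (1) when the
    upper-tail probability P(X >= observed) under that expectation is at most
    ``p_threshold``.  Without a control the expectation is the global mean.
    """
    if signal.binary:
        raise ValueError("signal track is already binary")
    counts = signal.values.astype(float)
    mean_signal = counts.mean()
    if mean_signal == 0:
        warnings.warn("all-zero signal track; binarization yields all zeros")
        return BinnedTrack(signal.mark, np.zeros_like(counts, dtype=np.uint8), signal.bins, True)
    if control is None:
        lam = np.full_like(counts, mean_signal)
    else:
        if control.binary:
            raise ValueError("control track must hold raw counts")
        if control.bins is not signal.bins and control.bins != signal.bins:
            raise ValueError("signal and control must share a BinIndex")
        ctrl = control.values.astype(float)
        depth_ratio = counts.sum() / max(ctrl.sum(), 1.0)
        lam = np.maximum(ctrl * depth_ratio, mean_signal)
    # P(X >= k) = sf(k - 1); counts are integers
    pvals = stats.poisson.sf(counts - 1, lam)
    calls = (pvals <= p_threshold).astype(np.uint8)
    return BinnedTrack(signal.mark, calls, signal.bins, binary=True)


# ---------------------------------------------------------------------------
# model I/O (ChromHMM text dialect + paired TSV)
# ---------------------------------------------------------------------------

def load_chromhmm_model(path: str | Path, mnemonics: Sequence[str] | None = None) -> HMMModel:
    """Load a model from the ChromHMM text dialect.

    Recognised lines (tab-separated): ``probinit <state> <p>``,
    ``transitionprobs <from> <to> <p>``,
    ``emissionprobs <state> <mark_index> <mark_name> [<bucket>] <p>``.
    A missing initial distribution becomes uniform.  States are 1-based in
    the file.
    """
    init: dict[int, float] = {}
    trans: dict[tuple[int, int], float] = {}
    emis: dict[tuple[int, str], float] = {}
    mark_order: dict[str, int] = {}
    n_states = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            if tag == "probinit":
                s = int(parts[1])
                init[s - 1] = float(parts[2])
                n_states = max(n_states, s)
            elif tag == "transitionprobs":
                a, b = int(parts[1]), int(parts[2])
                trans[(a - 1, b - 1)] = float(parts[3])
                n_states = max(n_states, a, b)
            elif tag == "emissionprobs":
                s = int(parts[1])
                mark = parts[3]
                p = float(parts[-1])
                # ChromHMM writes one line per emission bucket (0 and 1);
                # keep the presence (bucket "1") probability.
                if len(parts) >= 6 and parts[4] == "0":
                    continue
                emis[(s - 1, mark)] = p
                mark_order.setdefault(mark, int(parts[2]))
                n_states = max(n_states, s)
    if n_states == 0:
        raise ValueError(f"{path}: no model lines found")
    marks = tuple(sorted(mark_order, key=mark_order.get))
    initial = np.full(n_states, 1.0 / n_states)
    for s, p in init.items():
        initial[s] = p
    transitions = np.zeros((n_states, n_states))
    for (a, b), p in trans.items():
        transitions[a, b] = p
    emissions = np.zeros((n_states, len(marks)))
    for (s, mark), p in emis.items():
        if p < 0 or p > 1:
            raise ValueError(f"emission probability {p} outside [0, 1]")
        emissions[s, marks.index(mark)] = p
    if np.abs(transitions.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("transition rows do not sum to 1")
    if init and abs(initial.sum() - 1.0) > 1e-6:
        raise ValueError("initial probabilities do not sum to 1")
    if mnemonics is None:
        mnemonics = tuple(str(i + 1) for i in range(n_states))
    return HMMModel(marks, initial, transitions, emissions, tuple(mnemonics))


def save_chromhmm_model(model: HMMModel, path: str | Path) -> None:
    """Write the ChromHMM text dialect (probabilities at 10 significant digits)."""
    with open(path, "w") as fh:
        for s, p in enumerate(model.initial):
            fh.write(f"probinit\t{s + 1}\t{p:.10g}\n")
        for a in range(model.n_states):
            for b in range(model.n_states):
                fh.write(f"transitionprobs\t{a + 1}\t{b + 1}\t{model.transitions[a, b]:.10g}\n")
        for s in range(model.n_states):
            for m, mark in enumerate(model.marks):
                p = model.emissions[s, m]
                fh.write(f"emissionprobs\t{s + 1}\t{m}\t{mark}\t0\t{1 - p:.10g}\n")
                fh.write(f"emissionprobs\t{s + 1}\t{m}\t{mark}\t1\t{p:.10g}\n")


def load_model_tables(
    emissions_path: str | Path, transitions_path: str | Path
) -> HMMModel:
    """Load a model from paired TSV tables.

    The emission table has one row per state (index column = mnemonic) and
    one column per mark; the transition table is states x states.
    """
    em = pd.read_csv(emissions_path, sep="\t", index_col=0)
    tr = pd.read_csv(transitions_path, sep="\t", index_col=0)
    if ((em.values < 0) | (em.values > 1)).any():
        raise ValueError("emission probabilities outside [0, 1]")
    n = len(em)
    return HMMModel(
        marks=tuple(em.columns),
        initial=np.full(n, 1.0 / n),
        transitions=tr.values.astype(float),
        emissions=em.values.astype(float),
        mnemonics=tuple(str(i) for i in em.index),
    )


# ---------------------------------------------------------------------------
# forward-backward machinery
# ---------------------------------------------------------------------------

def _stack_tracks(tracks: Sequence[BinnedTrack], marks: Sequence[str] | None = None) -> tuple[np.ndarray, tuple[str, ...], BinIndex]:
    if not tracks:
        raise ValueError("at least one mark track required")
    bins = tracks[0].bins
    by_mark = {t.mark: t for t in tracks}
    if marks is None:
        marks = tuple(t.mark for t in tracks)
    else:
        missing = [m for m in marks if m not in by_mark]
        if missing:
            raise ValueError(f"tracks missing marks: {missing}")
        marks = tuple(marks)
    for t in by_mark.values():
        if not t.binary:
            raise ValueError(f"track {t.mark!r} is not binarized")
        if t.bins.n_bins != bins.n_bins:
            raise ValueError("tracks disagree on bin index")
    X = np.stack([by_mark[m].values for m in marks], axis=1).astype(np.float64)
    return X, marks, bins


def _log_emission_likelihood(X: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """(n_bins, n_states) log P(observation | state) for binary observations."""
    E = np.clip(emissions, _PROB_FLOOR, 1 - _PROB_FLOOR)
    return X @ np.log(E).T + (1 - X) @ np.log1p(-E).T


def _forward_backward(
    loglik: np.ndarray, initial: np.ndarray, transitions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Scaled forward-backward over one observation sequence.

    Returns (gamma, xi_sum, log_likelihood, scaled_alpha, scale) where
    ``gamma[t, s]`` is the posterior state marginal and ``xi_sum`` the
    summed pairwise transition posteriors.
    """
    n, S = loglik.shape
    shift = loglik.max(axis=1, keepdims=True)
    b = np.exp(loglik - shift)  # per-position rescaled emission likelihoods
    alpha = np.empty((n, S))
    scale = np.empty(n)
    alpha[0] = initial * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ transitions) * b[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((n, S))
    beta[-1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(n - 2, -1, -1):
        w = b[t + 1] * beta[t + 1]
        beta[t] = (transitions @ w) / scale[t + 1]
        xi_sum += transitions * np.outer(alpha[t], w) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik_total = float(np.log(scale).sum() + shift.sum())
    return gamma, xi_sum, loglik_total, alpha, scale


def posterior_marginals(
    tracks: Sequence[BinnedTrack], model: HMMModel
) -> tuple[np.ndarray, float]:
    """Per-bin posterior state marginals (chromosomes independent).

    Returns (posteriors over all global bins, total log-likelihood).
    """
    X, _, bins = _stack_tracks(tracks, model.marks)
    post = np.empty((bins.n_bins, model.n_states))
    total_ll = 0.0
    for chrom in bins.assembly.chrom_names:
        sl = bins.chrom_slice(chrom)
        ll = _log_emission_likelihood(X[sl], model.emissions)
        gamma, _, ll_tot, _, _ = _forward_backward(ll, model.initial, model.transitions)
        post[sl] = gamma
        total_ll += ll_tot
    return post, total_ll


def segment(tracks: Sequence[BinnedTrack], model: HMMModel) -> StateSegmentation:
    """Posterior-decode binary mark tracks into a state segmentation.

    Each bin is assigned the state maximising its forward-backward posterior
    marginal; ties break to the lowest state ordinal.
    """
    post, _ = posterior_marginals(tracks, model)
    states = post.argmax(axis=1).astype(np.int32)
    return StateSegmentation(
        states, tracks[0].bins, model.mnemonics, max_posterior=post.max(axis=1)
    )


# ---------------------------------------------------------------------------
# Baum-Welch training
# ---------------------------------------------------------------------------

def train_model(
    tracks: Sequence[BinnedTrack],
    n_states: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    mnemonics: Sequence[str] | None = None,
) -> HMMModel:
    """Baum-Welch fit of the product-Bernoulli HMM to binary mark tracks.

    Emissions are initialised from k-means cluster means of the per-bin mark
    vectors (seeded, hence deterministic); transitions start at 0.9
    self-transition with uniform off-diagonal mass.  Iteration stops when
    the log-likelihood improves by less than ``tol`` or after ``max_iter``
    rounds.  All probabilities are clamped to [1e-6, 1-1e-6].
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    X, marks, bins = _stack_tracks(tracks)
    if bins.n_bins < n_states:
        raise ValueError("fewer bins than states")
    rng = np.random.default_rng(seed)
    sub = X if len(X) <= 100_000 else X[rng.choice(len(X), 100_000, replace=False)]
    km = KMeans(n_clusters=n_states, n_init=10, random_state=seed).fit(sub)
    emissions = np.clip(km.cluster_centers_, _PROB_FLOOR, 1 - _PROB_FLOOR)
    # order states by mean emission so initialisation is label-stable
    emissions = emissions[np.argsort(emissions.mean(axis=1))[::-1]]
    transitions = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(transitions, 0.9)
    initial = np.full(n_states, 1.0 / n_states)

    slices = [bins.chrom_slice(c) for c in bins.assembly.chrom_names]
    trace: list[float] = []
    for _ in range(max_iter):
        gamma_first = np.zeros(n_states)
        xi_total = np.zeros((n_states, n_states))
        weighted_obs = np.zeros((n_states, len(marks)))
        gamma_total = np.zeros(n_states)
        ll_total = 0.0
        for sl in slices:
            ll = _log_emission_likelihood(X[sl], emissions)
            gamma, xi_sum, ll_tot, _, _ = _forward_backward(ll, initial, transitions)
            gamma_first += gamma[0]
            xi_total += xi_sum
            weighted_obs += gamma.T @ X[sl]
            gamma_total += gamma.sum(axis=0)
            ll_total += ll_tot
        trace.append(ll_total)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        initial = np.clip(gamma_first / gamma_first.sum(), _PROB_FLOOR, None)
        initial /= initial.sum()
        transitions = xi_total / np.maximum(xi_total.sum(axis=1, keepdims=True), 1e-300)
        transitions = np.clip(transitions, _PROB_FLOOR, None)
        transitions /= transitions.sum(axis=1, keepdims=True)
        emissions = np.clip(
            weighted_obs / np.maximum(gamma_total[:, None], 1e-300),
            _PROB_FLOOR,
            1 - _PROB_FLOOR,
        )
    if mnemonics is None:
        mnemonics = tuple(f"E{i + 1}" for i in range(n_states))
    return HMMModel(marks, initial, transitions, emissions, tuple(mnemonics), loglik_trace=trace)


# ---------------------------------------------------------------------------
# enrichment and summaries
# ---------------------------------------------------------------------------

def state_coverage(seg: StateSegmentation) -> pd.Series:
    """Fraction of bins per state (sums to 1); indexed by mnemonic."""
    counts = np.bincount(seg.states, minlength=len(seg.mnemonics))
    return pd.Series(counts / counts.sum(), index=list(seg.mnemonics))


def overlap_enrichment(seg: StateSegmentation, annotation: IntervalSet) -> pd.Series:
    """Bin-resolution fold enrichment of each state in an annotation.

    fold(s) = P(bin in s and in A) / (P(bin in s) * P(bin in A)).  States
    absent from the segmentation get NaN (undefined), not zero.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    ann = intervals_mask(annotation, seg.bins)
    total = seg.bins.n_bins
    p_ann = ann.sum() / total
    folds = np.full(len(seg.mnemonics), np.nan)
    for s in range(len(seg.mnemonics)):
        in_state = seg.states == s
        n_state = int(in_state.sum())
        if n_state == 0:
            continue
        joint = int((in_state & (ann == 1)).sum())
        folds[s] = (joint / total) / ((n_state / total) * p_ann)
    return pd.Series(folds, index=list(seg.mnemonics))


def intervals_mask(intervals: IntervalSet, bins: BinIndex) -> np.ndarray:
    from .genome import intervals_to_bins

    return intervals_to_bins(intervals, bins)


def neighborhood_enrichment(
    seg: StateSegmentation,
    anchors: pd.DataFrame,
    flank: int = 2000,
    step: int = 200,
) -> pd.DataFrame:
    """State fold enrichment in signed-offset windows around anchor positions.

    ``anchors`` needs columns chrom, pos and strand; offsets are mirrored for
    minus-strand anchors (so offset +o always means "o bp downstream").
    Positions falling off-chromosome are dropped from that offset's count.
    Returns states x offsets fold matrix: P(state at anchor+o) / P(state).
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    offsets = np.arange(-flank, flank + 1, step)
    genome_p = state_coverage(seg).to_numpy()
    asm = seg.bins.assembly
    chrom_idx = np.array([asm.index_of(c) for c in anchors["chrom"]])
    lengths = np.array(asm.chrom_lengths)[chrom_idx]
    pos = anchors["pos"].to_numpy(dtype=np.int64)
    sign = np.where(anchors["strand"].to_numpy() == "-", -1, 1)
    offsets_arr = np.array([int(o) for o in offsets])
    out = np.full((len(seg.mnemonics), len(offsets)), np.nan)
    bin_offsets = seg.bins._offsets
    for j, o in enumerate(offsets_arr):
        p = pos + sign * o
        ok = (p >= 0) & (p < lengths)
        if not ok.any():
            continue
        ords = bin_offsets[chrom_idx[ok]] + p[ok] // seg.bins.bin_size
        counts = np.bincount(seg.states[ords], minlength=len(seg.mnemonics))
        frac = counts / counts.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = np.where(genome_p > 0, frac / genome_p, np.nan)
    return pd.DataFrame(out, index=list(seg.mnemonics), columns=offsets)


def aggregate_signal_by_state(
    seg: StateSegmentation,
    chroms: Sequence[str],
    positions: np.ndarray,
    values: np.ndarray,
    statistic: Literal["median", "mean"] = "median",
) -> pd.Series:
    """Per-state summary (median or mean) of positional signal values.

    Each signal position contributes to the state of its containing bin;
    states covering no positions are NaN (missing), not zero.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    ords = seg.bins.ordinals_at(chroms, positions)
    state_at = seg.states[ords]
    values = np.asarray(values, dtype=float)
    out = np.full(len(seg.mnemonics), np.nan)
    for s in range(len(seg.mnemonics)):
        sel = values[state_at == s]
        if len(sel):
            out[s] = np.median(sel) if statistic == "median" else sel.mean()
    return pd.Series(out, index=list(seg.mnemonics))
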