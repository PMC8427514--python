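"""Expression-matrix normalization, expressed/repressed calling and
tissue-specificity categories.

Genes are split into expressed and repressed classes by fitting a
two-component Gaussian mixture to mean log2(TPM + 0.01) values — the
distribution of bulk expression is strongly bimodal, with a repressed mode
far below zero and an expressed mode at positive log-TPM — and assigning a
gene to a component when its posterior probability reaches a cutoff
(default 0.9); genes between the modes stay ambiguous.

Tissue specificity follows the Human Protein Atlas fold rules on linear
TPM: a gene is tissue-enriched when the target tissue exceeds every other
tissue at least fold-fold (default 4), group-enriched when a group of 2-5
tissues including the target does so on average, and tissue-enhanced when
the target exceeds the mean of all other tissues fold-fold.  Genes not
reaching a minimum TPM in the target tissue are never called specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GMMFit",
    "log_transform",
    "quantile_normalize",
    "remove_batch",
    "fit_gmm2",
    "classify_genes",
    "tissue_specificity",
]

LOG_PSEUDOCOUNT = 0.01


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 0.01) on every entry."""
    return np.log2(m + LOG_PSEUDOCOUNT)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: every column maps onto the mean order-statistic
    profile; tied values within a column receive the mean of their tied
    reference values."""
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    X = m.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        by_rank = np.empty_like(reference)
        by_rank[order] = reference
        # average reference values across ties
        s = pd.Series(by_rank).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def remove_batch(m: pd.DataFrame, batches: list | np.ndarray | pd.Series) -> pd.DataFrame:
    """Per-gene linear batch-mean removal on a log-scale matrix.

    Each gene's per-batch mean is shifted onto its grand mean (mean over all
    columns), which is preserved exactly.  Expects >= 2 batches, each with
    >= 1 column.
    """
    batches = np.asarray(batches)
    if len(batches) != m.shape[1]:
        raise ValueError("one batch label per column required")
    uniq = pd.unique(batches)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct batches")
    X = m.to_numpy(dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    out = X.copy()
    for b in uniq:
        cols = batches == b
        out[:, cols] += grand - X[:, cols].mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


@dataclass
class GMMFit:
    """A fitted 2-component univariate Gaussian mixture.

    Component 1 is always the lower-mean (repressed) component, component 2
    the higher-mean (expressed) one, regardless of EM initialisation.
    """

    means: np.ndarray  # (2,), ascending
    sds: np.ndarray  # (2,), > 0
    weights: np.ndarray  # (2,), sum to 1
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("standard deviations must be positive")

    def posteriors(self, values: np.ndarray) -> np.ndarray:
        """(n, 2) responsibility of each component for each value."""
        values = np.asarray(values, dtype=float)[:, None]
        log_dens = (
            -0.5 * ((values - self.means) / self.sds) ** 2
            - np.log(self.sds)
            - 0.5 * np.log(2 * np.pi)
            + np.log(self.weights)
        )
        log_dens -= log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens)
        return dens / dens.sum(axis=1, keepdims=True)


def fit_gmm2(
    values: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_sd: float = 1e-6,
) -> GMMFit:
    """EM fit of a 2-component univariate Gaussian mixture.

    Deterministic initialisation: component means at the 25th and 75th
    percentiles, both sds at the pooled sd, equal weights.  ``seed`` is
    reserved for optional random restarts and does not affect the default
    deterministic path.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need >= 10 finite values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values identical")
    means = np.percentile(x, [25, 75]).astype(float)
    if means[0] == means[1]:
        means = np.array([x.min(), x.max()], dtype=float)
    sds = np.full(2, max(x.std(), min_sd))
    weights = np.array([0.5, 0.5])
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        fit = GMMFit(means, sds, weights, False)
        resp = fit.posteriors(x)
        # observed-data log-likelihood under current parameters
        comp = (
            -0.5 * ((x[:, None] - means) / sds) ** 2
            - np.log(sds)
            - 0.5 * np.log(2 * np.pi)
            + np.log(weights)
        )
        mx = comp.max(axis=1)
        ll = float((mx + np.log(np.exp(comp - mx[:, None]).sum(axis=1))).sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, min_sd**2))
    order = np.argsort(means)
    return GMMFit(means[order], sds[order], weights[order], converged, trace)


def classify_genes(
    fit: GMMFit, values: np.ndarray, cutoff: float = 0.9, gene_ids=None
) -> pd.DataFrame:
    """Assign genes to expressed/repressed/ambiguous by component posterior.

    expressed when P(high component) >= cutoff, repressed when
    P(low component) >= cutoff, otherwise ambiguous.  Cutoffs at or below
    0.5 would let the classes overlap and are rejected.
    """
    if cutoff <= 0.5:
        raise ValueError("cutoff must exceed 0.5")
    values = np.asarray(values, dtype=float)
    post = fit.posteriors(values)
    klass = np.where(
        post[:, 1] >= cutoff, "expressed", np.where(post[:, 0] >= cutoff, "repressed", "ambiguous")
    )
    if gene_ids is None:
        gene_ids = np.arange(len(values))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "klass": klass,
            "posterior": post.max(axis=1),
        }
    )


def tissue_specificity(
    m: pd.DataFrame,
    target: str,
    fold: float = 4.0,
    group_range: tuple[int, int] = (2, 5),
    min_tpm: float = 1.0,
    exhaustive_groups: bool = False,
) -> pd.DataFrame:
    """Human-Protein-Atlas-style specificity categories for one target tissue.

    ``m`` is genes x tissues of linear TPM.  Categories, tried in order:

    * ``tissue-enriched``: target >= fold x every other tissue;
    * ``group-enriched``: the smallest group of 2-5 tissues containing the
      target whose mean is >= fold x every tissue outside the group (groups
      grown greedily from the highest-expressing tissues, or exhaustively
      when ``exhaustive_groups``);
    * ``tissue-enhanced``: target >= fold x mean of all other tissues;
    * ``not-specific`` otherwise, and always when target TPM <= min_tpm.

    Returns a DataFrame (gene_id, category, group) where ``group`` lists the
    supporting tissues of a group-enriched call.
    """
    if target not in m.columns:
        raise ValueError(f"target tissue {target!r} not in matrix")
    if m.shape[1] < 3:
        raise ValueError("need >= 3 tissues")
    others = [c for c in m.columns if c != target]
    lo, hi = group_range
    rows = []
    for gene, row in m.iterrows():
        t = float(row[target])
        vals = row[others].to_numpy(dtype=float)
        if t <= min_tpm:
            rows.append((gene, "not-specific", ""))
            continue
        if t >= fold * vals.max():
            rows.append((gene, "tissue-enriched", ""))
            continue
        group = _find_group(t, vals, others, fold, lo, hi, exhaustive_groups)
        if group is not None:
            rows.append((gene, "group-enriched", ",".join([target, *group])))
            continue
        if t >= fold * vals.mean():
            rows.append((gene, "tissue-enhanced", ""))
            continue
        rows.append((gene, "not-specific", ""))
    return pd.DataFrame(rows, columns=["gene_id", "category", "group"])


def _find_group(
    target_val: float,
    other_vals: np.ndarray,
    other_names: list[str],
    fold: float,
    lo: int,
    hi: int,
    exhaustive: bool,
) -> list[str] | None:
    order = np.argsort(other_vals, kind="mergesort")[::-1]
    if not exhaustive:
        for size in range(lo, hi + 1):
            take = order[: size - 1]
            if len(take) < size - 1:
                break
            rest = order[size - 1 :]
            group_mean = (target_val + other_vals[take].sum()) / size
            outside_max = other_vals[rest].max() if len(rest) else 0.0
            if group_mean >= fold * outside_max:
                return [other_names[i] for i in take]
        return None
    from itertools import combinations

    for size in range(lo, hi + 1):
        for combo in combinations(range(len(other_vals)), size - 1):
            rest = [i for i in range(len(other_vals)) if i not in combo]
            group_mean = (target_val + other_vals[list(combo)].sum()) / size
            outside_max = other_vals[rest].max() if rest else 0.0
            if group_mean >= fold * outside_max:
                return [other_names[i] for i in combo]
    return None
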