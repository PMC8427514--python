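"""Independent reference implementations used to validate the fast paths.

These deliberately use brute force (path enumeration, draw enumeration) and
stay independent of the library code they check.
"""

import itertools

import numpy as np

from epiatlas.chromatin import BinnedTrack, HMMModel


def brute_force_posteriors(X, initial, transitions, emissions):
    """Exact posterior state marginals by enumerating every state path."""
    n, _ = X.shape
    S = len(initial)
    post = np.zeros((n, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=n):
        p = initial[path[0]]
        for t in range(1, n):
            p *= transitions[path[t - 1], path[t]]
        for t in range(n):
            e = emissions[path[t]]
            p *= np.prod(np.where(X[t] == 1, e, 1 - e))
        total += p
        for t in range(n):
            post[t, path[t]] += p
    return post / total


def enumeration_sf(k, K, n, N):
    """Exact hypergeometric upper tail by enumerating all size-n draws."""
    hits = 0
    total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in combo if i < K) >= k:
            hits += 1
    return hits / total


def random_model(rng, n_states=3, n_marks=2):
    """A random valid Bernoulli-emission HMM."""
    initial = rng.dirichlet(np.ones(n_states))
    transitions = rng.dirichlet(np.ones(n_states), size=n_states)
    emissions = rng.uniform(0.05, 0.95, (n_states, n_marks))
    return HMMModel(
        marks=tuple(f"m{i}" for i in range(n_marks)),
        initial=initial,
        transitions=transitions,
        emissions=emissions,
        mnemonics=tuple(f"S{i}" for i in range(n_states)),
    )


def tracks_from_matrix(X, bins, marks):
    return [BinnedTrack(m, X[:, j], bins, binary=True) for j, m in enumerate(marks)]
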