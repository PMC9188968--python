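"""Independent oracles used by the test suite.

These deliberately avoid the package's own recursions: posteriors and
decoded paths come from exhaustive enumeration over all K^T latent paths,
and Hungarian matching is cross-checked against brute force over all
permutations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal


def enum_posteriors(means, cov, A, pi, X):
    """Exact smoothed posteriors, log-evidence and MAP path by path enumeration."""
    means = np.asarray(means, dtype=float)
    K, T = means.shape[0], len(X)
    loglik = np.array([multivariate_normal.logpdf(X, means[k], cov) for k in range(K)]).reshape(K, T)
    with np.errstate(divide="ignore"):
        logA, logpi = np.log(A), np.log(pi)
    paths = list(itertools.product(range(K), repeat=T))
    logp = np.empty(len(paths))
    for i, path in enumerate(paths):
        lp = logpi[path[0]] + loglik[path[0], 0]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + loglik[path[t], t]
        logp[i] = lp
    logZ = float(logsumexp(logp))
    w = np.exp(logp - logZ)
    gamma = np.zeros((T, K))
    for wi, path in zip(w, paths):
        for t, s in enumerate(path):
            gamma[t, s] += wi
    map_path = np.array(paths[int(np.argmax(logp))])  # first max = lexicographically lowest
    return gamma, logZ, map_path


def brute_force_match(a_means, b_means):
    """Best label assignment by exhaustive search over all K! permutations.

    Returns perm maximizing sum_j corr(a_means[perm[j]], b_means[j]).
    """
    K = len(a_means)
    corr = np.corrcoef(np.asarray(b_means), np.asarray(a_means))[:K, K:]
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = sum(corr[j, perm[j]] for j in range(K))
        if score > best_score:
            best, best_score = perm, score
    return np.array(best)


def random_hmm_instance(rng, K, T, d=2):
    """A small random Gaussian-HMM instance plus sampled data."""
    means = rng.normal(0, 2, size=(K, d))
    W = rng.standard_normal((d, d + 2))
    cov = W @ W.T / (d + 2) + 0.5 * np.eye(d)
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    pi = rng.dirichlet(np.ones(K))
    X = rng.normal(0, 1.5, size=(T, d))
    return means, cov, A, pi, X
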