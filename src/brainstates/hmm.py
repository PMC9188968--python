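"""Variational Bayes inference for a Gaussian hidden Markov model.

The observation model is the one used for whole-brain state analyses of
task fMRI: each of K states contributes only a state-specific *mean*
activation pattern (in PC space), while a single full covariance matrix is
shared by all states, so functional connectivity is modelled at the group
level and the states are driven purely by mean activation.

Inference is variational Bayes with conjugate priors:

* Dirichlet priors on every transition row and on the initial distribution
  (sticky diagonal, parameterised by an expected dwell time),
* independent Gaussian priors on the K state means,
* a Wishart prior on the shared precision (equivalently inverse-Wishart on
  the shared covariance); a ``covariance_mode="fixed"`` variant keeps the
  covariance clamped at the empirical estimate instead.

The negative evidence lower bound ("free energy", lower is better) is used
for convergence, for comparing initialisations, and for selecting the
number of states.  Each scanning session is treated as an independent
chain: the initial distribution applies at every session start and no
transition is counted across session boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMConfig:
    """Hyperparameters and fitting options (all configurable, defaults documented)."""

    covariance_mode: str = "inferred"   # "inferred" (Wishart posterior) or "fixed"
    prior_dwell: float = 5.0            # sticky Dirichlet prior: expected dwell (timepoints)
    dirichlet_offdiag: float = 1.0
    mean_prior_sd: float = 10.0         # N(m0, sd^2 I) prior on state means
    n_init: int = 10
    max_iter: int = 500
    tol: float = 1e-5                   # relative free-energy change
    kmeans_subsample: int = 10000


@dataclass
class StateTimeCourse:
    """Posterior state probabilities for one session (rows sum to 1)."""

    gamma: np.ndarray                 # T x K
    xi_sum: np.ndarray | None = None  # K x K summed pairwise posteriors


@dataclass
class VBPosterior:
    """Posterior (and prior) hyperparameters of the variational factors."""

    alpha_trans: np.ndarray    # K x K Dirichlet rows
    alpha_init: np.ndarray     # K
    mean: np.ndarray           # K x m posterior means
    mean_cov: np.ndarray       # K x m x m posterior covariances
    wishart_dof: float         # q(Lambda) = Wishart(dof, scale); unused in fixed mode
    wishart_scale: np.ndarray  # m x m
    alpha0_trans: np.ndarray
    alpha0_init: np.ndarray
    mean0: np.ndarray
    mean_prior_prec: float
    wishart_dof0: float
    wishart_scale0: np.ndarray
    covariance_mode: str
    fixed_covariance: np.ndarray | None = None


@dataclass
class HMMParams:
    """Fitted model: point parameters plus the variational posterior."""

    K: int
    means: np.ndarray        # K x m
    covariance: np.ndarray   # m x m, shared
    transitions: np.ndarray  # K x K stochastic
    initial: np.ndarray      # K simplex
    free_energy: float
    fe_trace: np.ndarray
    config: HMMConfig
    seed: int
    converged: bool
    posterior: VBPosterior | None = None


# ---------------------------------------------------------------------------
# exact recursions (shared by VB E-step, point-parameter smoothing, Viterbi)


def _forward_backward_core(
    logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward for (possibly unnormalised) chain potentials.

    Returns smoothed posteriors gamma (T x K), summed pairwise posteriors
    xi_sum (K x K) and the log normaliser of the chain.
    """
    T, K = logB.shape
    c = logB.max(axis=1)
    B = np.exp(logB - c[:, None])
    A = np.exp(logA)
    pi = np.exp(logpi)

    alpha = np.empty((T, K))
    s = np.empty(T)
    a = pi * B[0]
    s[0] = a.sum()
    if s[0] <= 0:
        raise FloatingPointError("forward pass underflowed at t=0")
    alpha[0] = a / s[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s[t] = a.sum()
        if s[t] <= 0:
            raise FloatingPointError(f"forward pass underflowed at t={t}")
        alpha[t] = a / s[t]
    logZ = float(np.log(s).sum() + c.sum())

    beta = np.ones(K)
    gamma = np.empty((T, K))
    gamma[T - 1] = alpha[T - 1]
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = B[t + 1] * beta
        xi_sum += (alpha[t][:, None] * A * w[None, :]) / s[t + 1]
        beta = (A @ w) / s[t + 1]
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    return gamma, xi_sum, logZ


def _viterbi_core(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    delta = logpi + logB[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)  # first max -> lower state on ties
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _gaussian_loglik(X: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x_t; mu_k, Sigma) for all t, k; shared covariance."""
    L = cholesky(cov, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    m = X.shape[1]
    out = np.empty((X.shape[0], means.shape[0]))
    for k, mu in enumerate(means):
        y = solve_triangular(L, (X - mu).T, lower=True)
        out[:, k] = -0.5 * (m * _LOG2PI + logdet + (y * y).sum(axis=0))
    return out


# ---------------------------------------------------------------------------
# public point-parameter operations


def _as_sessions(scores, index_map=None) -> list[np.ndarray]:
    if index_map is not None:
        X = np.asarray(scores, dtype=float)
        return [X[sl] for sl in index_map.values()]
    if isinstance(scores, (list, tuple)):
        return [np.asarray(s, dtype=float) for s in scores]
    return [np.asarray(scores, dtype=float)]


def forward_backward(model: HMMParams, X: np.ndarray) -> tuple[StateTimeCourse, float]:
    """Exact smoothed state posteriors and log-evidence under point parameters."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("data contain NaN")
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("data dimensionality does not match the model")
    logB = _gaussian_loglik(X, model.means, model.covariance)
    with np.errstate(divide="ignore"):
        gamma, xi_sum, logZ = _forward_backward_core(
            logB, np.log(model.transitions), np.log(model.initial)
        )
    return StateTimeCourse(gamma=gamma, xi_sum=xi_sum), logZ


def viterbi(model: HMMParams, X: np.ndarray) -> np.ndarray:
    """Most probable state path (0-based labels); ties go to the lower state."""
    X = np.asarray(X, dtype=float)
    logB = _gaussian_loglik(X, model.means, model.covariance)
    with np.errstate(divide="ignore"):
        return _viterbi_core(logB, np.log(model.transitions), np.log(model.initial))


# ---------------------------------------------------------------------------
# KL divergences of the conjugate factors


def _kl_dirichlet(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0, b0 = a.sum(), b.sum()
    return float(
        gammaln(a0) - gammaln(b0)
        - (gammaln(a) - gammaln(b)).sum()
        + ((a - b) * (digamma(a) - digamma(a0))).sum()
    )


def _kl_gaussian(m: np.ndarray, V: np.ndarray, m0: np.ndarray, prec0: float) -> float:
    """KL( N(m, V) || N(m0, prec0^-1 I) )."""
    d = len(m)
    sign, logdetV = np.linalg.slogdet(V)
    diff = m - m0
    return 0.5 * float(
        prec0 * (np.trace(V) + diff @ diff) - d + d * np.log(1.0 / prec0) - logdetV
    )


def _kl_wishart(nu: float, V: np.ndarray, nu0: float, V0: np.ndarray) -> float:
    """KL( W(nu, V) || W(nu0, V0) )."""
    d = V.shape[0]
    _, logdetV = np.linalg.slogdet(V)
    _, logdetV0 = np.linalg.slogdet(V0)
    elogdet = digamma(0.5 * (nu - np.arange(d))).sum() + d * np.log(2.0) + logdetV
    logB = lambda Vx, nux, logdetVx: (
        -0.5 * nux * logdetVx - 0.5 * nux * d * np.log(2.0) - multigammaln(0.5 * nux, d)
    )
    tr = np.trace(np.linalg.solve(V0, V))
    return float(
        logB(V, nu, logdetV) - logB(V0, nu0, logdetV0)
        + 0.5 * (nu - nu0) * elogdet - 0.5 * nu * d + 0.5 * nu * tr
    )


# ---------------------------------------------------------------------------
# VB fitting


def _expected_params(post: VBPosterior) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """E[log A], E[log pi], E[Lambda], E[log det Lambda] under the posterior."""
    ElogA = digamma(post.alpha_trans) - digamma(post.alpha_trans.sum(axis=1, keepdims=True))
    Elogpi = digamma(post.alpha_init) - digamma(post.alpha_init.sum())
    if post.covariance_mode == "fixed":
        Elam = np.linalg.inv(post.fixed_covariance)
        _, logdet = np.linalg.slogdet(post.fixed_covariance)
        Elogdet = -logdet
    else:
        d = post.wishart_scale.shape[0]
        Elam = post.wishart_dof * post.wishart_scale
        _, logdetW = np.linalg.slogdet(post.wishart_scale)
        Elogdet = (
            digamma(0.5 * (post.wishart_dof - np.arange(d))).sum()
            + d * np.log(2.0) + logdetW
        )
    return ElogA, Elogpi, Elam, float(Elogdet)


def _expected_loglik(X: np.ndarray, post: VBPosterior, Elam: np.ndarray, Elogdet: float) -> np.ndarray:
    m = X.shape[1]
    L = cholesky(Elam, lower=True)  # Elam = L L^T
    out = np.empty((X.shape[0], post.mean.shape[0]))
    for k in range(post.mean.shape[0]):
        y = (X - post.mean[k]) @ L
        quad = (y * y).sum(axis=1) + np.trace(Elam @ post.mean_cov[k])
        out[:, k] = 0.5 * Elogdet - 0.5 * m * _LOG2PI - 0.5 * quad
    return out


def _free_energy_terms(post: VBPosterior) -> float:
    K = post.alpha_trans.shape[0]
    kl = _kl_dirichlet(post.alpha_init, post.alpha0_init)
    for k in range(K):
        kl += _kl_dirichlet(post.alpha_trans[k], post.alpha0_trans[k])
        kl += _kl_gaussian(post.mean[k], post.mean_cov[k], post.mean0, post.mean_prior_prec)
    if post.covariance_mode == "inferred":
        kl += _kl_wishart(
            post.wishart_dof, post.wishart_scale, post.wishart_dof0, post.wishart_scale0
        )
    return kl


def _make_priors(X: np.ndarray, K: int, config: HMMConfig) -> dict:
    m = X.shape[1]
    offdiag = config.dirichlet_offdiag
    if K > 1:
        diag = offdiag + (config.prior_dwell - 1.0) * (K - 1) * offdiag
    else:
        diag = offdiag
    alpha0 = np.full((K, K), offdiag)
    np.fill_diagonal(alpha0, diag)
    emp_cov = np.cov(X.T, ddof=1).reshape(m, m)
    nu0 = m + 2.0
    return {
        "alpha0_trans": alpha0,
        "alpha0_init": np.ones(K),
        "mean0": X.mean(axis=0),
        "mean_prior_prec": 1.0 / config.mean_prior_sd**2,
        "wishart_dof0": nu0,
        "wishart_scale0": np.linalg.inv(emp_cov) / nu0,
        "emp_cov": emp_cov,
    }


def init_model(scores, K: int, seed: int = 0, config: HMMConfig | None = None) -> VBPosterior:
    """Seeded initialisation: k-means state means on a subsample, empirical
    covariance, near-uniform sticky transitions."""
    config = config or HMMConfig()
    sessions = _as_sessions(scores)
    X = np.vstack(sessions)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the {X.shape[0]} available timepoints")
    rng = np.random.default_rng(seed)
    priors = _make_priors(X, K, config)
    m = X.shape[1]

    if K == 1:
        centers = X.mean(axis=0, keepdims=True)
    else:
        n_sub = min(config.kmeans_subsample, X.shape[0])
        sub = X[rng.choice(X.shape[0], size=n_sub, replace=False)]
        km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31 - 1)))
        km.fit(sub)
        centers = km.cluster_centers_

    emp_cov = priors.pop("emp_cov")
    post = VBPosterior(
        alpha_trans=priors["alpha0_trans"] + (config.prior_dwell * 2) * np.eye(K),
        alpha_init=np.ones(K),
        mean=centers.copy(),
        mean_cov=np.tile(1e-2 * np.eye(m), (K, 1, 1)),
        wishart_dof=priors["wishart_dof0"],
        wishart_scale=priors["wishart_scale0"].copy(),
        covariance_mode=config.covariance_mode,
        fixed_covariance=emp_cov if config.covariance_mode == "fixed" else None,
        **priors,
    )
    return post


def _m_step(post: VBPosterior, stats: dict) -> None:
    """In-place coordinate updates of q(A), q(pi), q(mu_k), q(Lambda)."""
    K, m = post.mean.shape
    post.alpha_trans = post.alpha0_trans + stats["xi_sum"]
    post.alpha_init = post.alpha0_init + stats["gamma0"]

    if post.covariance_mode == "fixed":
        Elam = np.linalg.inv(post.fixed_covariance)
    else:
        Elam = post.wishart_dof * post.wishart_scale
    b0 = post.mean_prior_prec
    for k in range(K):
        prec = b0 * np.eye(m) + stats["N"][k] * Elam
        V = np.linalg.inv(prec)
        V = 0.5 * (V + V.T)
        post.mean_cov[k] = V
        post.mean[k] = V @ (b0 * post.mean0 + Elam @ stats["gx"][k])

    if post.covariance_mode == "inferred":
        S = np.zeros((m, m))
        for k in range(K):
            mk = post.mean[k]
            S += (
                stats["xx"][k]
                - np.outer(mk, stats["gx"][k]) - np.outer(stats["gx"][k], mk)
                + stats["N"][k] * (np.outer(mk, mk) + post.mean_cov[k])
            )
        post.wishart_dof = post.wishart_dof0 + stats["N"].sum()
        Winv = np.linalg.inv(post.wishart_scale0) + S
        W = np.linalg.inv(Winv)
        post.wishart_scale = 0.5 * (W + W.T)


def _e_step(sessions: list[np.ndarray], post: VBPosterior) -> tuple[list[StateTimeCourse], dict, float]:
    ElogA, Elogpi, Elam, Elogdet = _expected_params(post)
    K, m = post.mean.shape
    stats = {
        "N": np.zeros(K),
        "gx": np.zeros((K, m)),
        "xx": np.zeros((K, m, m)),
        "xi_sum": np.zeros((K, K)),
        "gamma0": np.zeros(K),
    }
    stcs, logZ = [], 0.0
    for X in sessions:
        logB = _expected_loglik(X, post, Elam, Elogdet)
        gamma, xi, lz = _forward_backward_core(logB, ElogA, Elogpi)
        logZ += lz
        stats["N"] += gamma.sum(axis=0)
        stats["gx"] += gamma.T @ X
        for k in range(K):
            stats["xx"][k] += (X * gamma[:, k:k + 1]).T @ X
        stats["xi_sum"] += xi
        stats["gamma0"] += gamma[0]
        stcs.append(StateTimeCourse(gamma=gamma, xi_sum=xi))
    fe = -logZ + _free_energy_terms(post)
    return stcs, stats, fe


def _vb_fit_once(
    sessions: list[np.ndarray], K: int, config: HMMConfig, seed: int
) -> tuple[VBPosterior, list[StateTimeCourse], np.ndarray, bool]:
    post = init_model(sessions, K, seed=seed, config=config)
    trace = []
    converged = False
    # first M-step from a hard-assignment E-step keeps the k-means structure
    stcs, stats, _ = _e_step(sessions, post)
    _m_step(post, stats)
    for _ in range(config.max_iter):
        stcs, stats, fe = _e_step(sessions, post)
        trace.append(fe)
        if len(trace) > 1 and abs(trace[-2] - fe) <= config.tol * abs(trace[-2]):
            converged = True
            break
        _m_step(post, stats)
    return post, stcs, np.asarray(trace), converged


def _point_params(post: VBPosterior) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    means = post.mean.copy()
    if post.covariance_mode == "fixed":
        cov = post.fixed_covariance.copy()
    else:
        cov = np.linalg.inv(post.wishart_dof * post.wishart_scale)
        cov = 0.5 * (cov + cov.T)
    trans = post.alpha_trans / post.alpha_trans.sum(axis=1, keepdims=True)
    init = post.alpha_init / post.alpha_init.sum()
    return means, cov, trans, init


def fit(
    scores,
    index_map: dict[str, slice] | None = None,
    K: int = 7,
    max_iter: int | None = None,
    tol: float | None = None,
    n_init: int | None = None,
    seed: int = 0,
    config: HMMConfig | None = None,
) -> tuple[HMMParams, list[StateTimeCourse]]:
    """Fit the K-state model; best of ``n_init`` initialisations by free energy.

    ``scores`` is either a stacked matrix with ``index_map`` giving each
    session's row slice, a list of per-session matrices, or one matrix
    (single session).  Returns the fitted parameters and one
    :class:`StateTimeCourse` per session, in input order.
    """
    config = config or HMMConfig()
    if max_iter is not None:
        config.max_iter = max_iter
    if tol is not None:
        config.tol = tol
    if n_init is not None:
        config.n_init = n_init
    sessions = _as_sessions(scores, index_map)
    for X in sessions:
        if np.isnan(X).any():
            raise ValueError("data contain NaN")

    best = None
    child_seeds = np.random.SeedSequence(seed).generate_state(config.n_init)
    for s in child_seeds:
        post, stcs, trace, converged = _vb_fit_once(sessions, K, config, int(s % (2**31 - 1)))
        if best is None or trace[-1] < best[2][-1]:
            best = (post, stcs, trace, converged)
    post, stcs, trace, converged = best
    if not converged:
        warnings.warn(
            f"HMM fit (K={K}) did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    means, cov, trans, init = _point_params(post)
    params = HMMParams(
        K=K, means=means, covariance=cov, transitions=trans, initial=init,
        free_energy=float(trace[-1]), fe_trace=trace, config=config,
        seed=seed, converged=converged, posterior=post,
    )
    return params, stcs


def free_energy(model: HMMParams, scores, index_map: dict[str, slice] | None = None) -> float:
    """Negative evidence lower bound of a fitted model on the given data.

    Runs one exact E-step under the model's variational posterior; lower is
    better.
    """
    if model.posterior is None:
        raise ValueError("model carries no variational posterior")
    sessions = _as_sessions(scores, index_map)
    _, _, fe = _e_step(sessions, model.posterior)
    return fe


def select_k(
    scores,
    index_map: dict[str, slice] | None = None,
    k_range=range(4, 11),
    n_init: int | None = None,
    seed: int = 0,
    config: HMMConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Fit each candidate K and tabulate free energies; select the minimum.

    The returned table has one row per candidate; the selected K is the
    free-energy argmin, which the user may override (e.g. on neuroscientific
    grounds such as the smallest K splitting a network of interest).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rows = []
    fits = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(k_range))
    for k, s in zip(k_range, seeds):
        params, _ = fit(
            scores, index_map, K=k, n_init=n_init, seed=int(s % (2**31 - 1)),
            config=HMMConfig(**asdict(config)) if config else None,
        )
        rows.append({"k": k, "free_energy": params.free_energy, "converged": params.converged})
        fits[k] = params
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["free_energy"].idxmin(), "k"])
    return table, selected


# ---------------------------------------------------------------------------
# utilities


def match_states(a, b) -> np.ndarray:
    """Hungarian match of state labels between two models.

    Accepts fitted models or K x m mean matrices.  Returns ``perm`` with
    ``a_means[perm[j]]`` best matching ``b_means[j]`` (assignment maximising
    total Pearson correlation between matched mean vectors), so if ``b`` is
    ``a`` with states permuted by sigma, ``perm == sigma``.
    """
    a_means = a.means if isinstance(a, HMMParams) else np.asarray(a, dtype=float)
    b_means = b.means if isinstance(b, HMMParams) else np.asarray(b, dtype=float)
    if a_means.shape[0] != b_means.shape[0]:
        raise ValueError("models must have the same number of states")
    K = a_means.shape[0]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(b_means, a_means)[:K, K:]  # rows: b states, cols: a states
    corr = np.nan_to_num(corr)  # zero-variance mean vectors: neutral similarity
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm


def empty_states(stcs: list[StateTimeCourse], min_timepoints: float = 1.0) -> np.ndarray:
    """Flag states whose total expected occupancy is below a timepoint budget.

    Mirrors the behaviour that inference can effectively eliminate states:
    a state absorbing less than ``min_timepoints`` expected timepoints over
    the whole dataset is reported as empty (reporting only; the fitted
    object is untouched).
    """
    total = np.sum([s.gamma.sum(axis=0) for s in stcs], axis=0)
    return total < min_timepoints


def save_model(model: HMMParams, path) -> None:
    """Serialise a fitted model to a single JSON file."""
    payload = {
        "K": model.K,
        "means": model.means.tolist(),
        "covariance": model.covariance.tolist(),
        "transitions": model.transitions.tolist(),
        "initial": model.initial.tolist(),
        "free_energy": model.free_energy,
        "fe_trace": np.asarray(model.fe_trace).tolist(),
        "config": asdict(model.config),
        "seed": model.seed,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def load_model(path) -> HMMParams:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return HMMParams(
        K=payload["K"],
        means=np.asarray(payload["means"]),
        covariance=np.asarray(payload["covariance"]),
        transitions=np.asarray(payload["transitions"]),
        initial=np.asarray(payload["initial"]),
        free_energy=payload["free_energy"],
        fe_trace=np.asarray(payload["fe_trace"]),
        config=HMMConfig(**payload["config"]),
        seed=payload["seed"],
        converged=payload["converged"],
        posterior=None,
    )
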