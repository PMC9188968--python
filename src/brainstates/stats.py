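"""Permutation inference for occupancy measures.

All tests are permutation-based with a t-statistic or Pearson-r base:
group labels are shuffled (unpaired), paired differences are sign-flipped
(paired), or one vector is permuted against the other (correlation).  When
the permutation space is small enough to enumerate within the requested
number of permutations, enumeration is used and the p-value is exact and
seed-independent; otherwise Monte-Carlo permutations with the
``(1 + b) / (1 + B)`` convention.

Multiple comparisons are handled two ways, matching common practice for
occupancy analyses: Benjamini-Hochberg step-up FDR across a grid of
individual tests, and non-parametric combination (NPC) of partial tests
sharing one synchronised set of permutations, with family-wise error
control via the max-combined-statistic null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

_TIE_EPS = 1e-12


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    n_perm: int           # permutations actually evaluated (excl. identity if MC)
    seed: int | None
    p: float
    exact: bool           # True when the permutation space was enumerated
    null_summary: dict[str, float] = field(default_factory=dict)


@dataclass
class NPCResult:
    family: tuple
    partial_observed: np.ndarray
    partial_p: np.ndarray
    combining: str
    combined_observed: float
    p_uncorrected: float
    p_joint: float        # FWE-corrected across the declared families


def _summary(null: np.ndarray) -> dict[str, float]:
    null = null[np.isfinite(null)]  # degenerate sign-flips can yield +/-inf t
    if null.size == 0:
        return {}
    qs = np.quantile(null, [0.025, 0.5, 0.975])
    return {"q2.5": float(qs[0]), "median": float(qs[1]), "q97.5": float(qs[2])}


def _tail_count(null: np.ndarray, observed: float, alternative: str) -> int:
    if alternative == "two-sided":
        return int(np.sum(np.abs(null) >= abs(observed) - _TIE_EPS))
    if alternative == "greater":
        return int(np.sum(null >= observed - _TIE_EPS))
    if alternative == "less":
        return int(np.sum(null <= observed + _TIE_EPS))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# two-sample (unpaired) permutation t-test


def _t_from_splits(z: np.ndarray, z2: np.ndarray, idx: np.ndarray, nx: int) -> np.ndarray:
    """Pooled-variance t for each row of index matrix ``idx`` (first nx = group x)."""
    n = z.size
    ny = n - nx
    total_s, total_q = z.sum(), z2.sum()
    s1 = z[idx[:, :nx]].sum(axis=1)
    q1 = z2[idx[:, :nx]].sum(axis=1)
    s2, q2 = total_s - s1, total_q - q1
    ss1 = q1 - s1**2 / nx
    ss2 = q2 - s2**2 / ny
    sp2 = (ss1 + ss2) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (s1 / nx - s2 / ny) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def perm_test_unpaired(
    x, y, n_perm: int = 10000, seed: int = 0, alternative: str = "two-sided"
) -> PermutationResult:
    """Permutation test of a mean difference, pooled-variance t base statistic.

    Enumerates all label assignments when their number does not exceed
    ``n_perm``; otherwise uses seeded random shuffles.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    z = np.concatenate([x, y])
    z2 = z**2
    n, nx = z.size, x.size
    obs = float(_t_from_splits(z, z2, np.arange(n)[None, :], nx)[0])
    if not np.isfinite(obs):
        raise ValueError("zero pooled variance: t statistic undefined")

    total = math.comb(n, nx)
    if total <= n_perm:
        idx = np.empty((total, n), dtype=int)
        for r, chosen in enumerate(itertools.combinations(range(n), nx)):
            rest = [i for i in range(n) if i not in set(chosen)]
            idx[r] = list(chosen) + rest
        null = _t_from_splits(z, z2, idx, nx)
        p = _tail_count(null, obs, alternative) / total
        return PermutationResult("unpaired t", obs, total, None, p, True, _summary(null))

    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    null = _t_from_splits(z, z2, idx, nx)
    p = (1 + _tail_count(null, obs, alternative)) / (1 + n_perm)
    return PermutationResult("unpaired t", obs, n_perm, seed, p, False, _summary(null))


# ---------------------------------------------------------------------------
# paired (sign-flip) permutation t-test


def _paired_t(d: np.ndarray) -> np.ndarray:
    """One-sample t of each row of sign-flipped differences."""
    n = d.shape[-1]
    mean = d.mean(axis=-1)
    sd = d.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # sd == 0: infinitely strong evidence in the mean's direction (0 if mean is 0)
    t = np.where((sd == 0) & (mean > 0), np.inf, t)
    t = np.where((sd == 0) & (mean < 0), -np.inf, t)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    return t


def perm_test_paired(
    pre, post, n_perm: int = 10000, seed: int = 0, alternative: str = "two-sided"
) -> PermutationResult:
    """Sign-flip permutation test of paired differences, paired-t base statistic.

    Exhaustive over all 2^n sign patterns whenever that fits in ``n_perm``.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size or pre.size < 2:
        raise ValueError("need equal-length paired samples of size >= 2")
    d = post - pre
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    n = d.size
    obs = float(_paired_t(d[None, :])[0])

    if 2**n <= n_perm:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        null = _paired_t(signs * d)
        p = _tail_count(null, obs, alternative) / 2**n
        return PermutationResult("paired t", obs, 2**n, None, p, True, _summary(null))

    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    null = _paired_t(signs * d)
    p = (1 + _tail_count(null, obs, alternative)) / (1 + n_perm)
    return PermutationResult("paired t", obs, n_perm, seed, p, False, _summary(null))


# ---------------------------------------------------------------------------
# permutation correlation


def _standardize_vec(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError(f"{name} is constant; correlation undefined")
    return (v - v.mean()) / (sd * np.sqrt(v.size))


def perm_correlation(
    fo, symptom, n_perm: int = 10000, seed: int = 0, alternative: str = "two-sided"
) -> PermutationResult:
    """Permutation test of a Pearson correlation by shuffling the symptom vector."""
    x = np.asarray(fo, dtype=float).ravel()
    y = np.asarray(symptom, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    xs = _standardize_vec(x, "fo")
    ys = _standardize_vec(y, "symptom")
    obs = float(xs @ ys)

    n = x.size
    if math.factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))))
        null = ys[perms] @ xs
        p = _tail_count(null, obs, alternative) / len(perms)
        return PermutationResult("pearson r", obs, len(perms), None, p, True, _summary(null))

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    null = ys[perms] @ xs
    p = (1 + _tail_count(null, obs, alternative)) / (1 + n_perm)
    return PermutationResult("pearson r", obs, n_perm, seed, p, False, _summary(null))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# non-parametric combination (NPC)


def families_per_x(p: int, q: int) -> list[list[tuple[int, int]]]:
    """One family per x column, aggregating its tests across all y columns."""
    return [[(i, j) for j in range(q)] for i in range(p)]


def families_per_y(p: int, q: int) -> list[list[tuple[int, int]]]:
    """One family per y column, aggregating its tests across all x columns."""
    return [[(i, j) for i in range(p)] for j in range(q)]


def npc_combine(
    x,
    y,
    families=None,
    combining: str = "fisher",
    n_perm: int = 10000,
    seed: int = 0,
) -> list[NPCResult]:
    """Non-parametric combination of correlation partial tests.

    ``x`` (n x p, e.g. per-network occupancy) and ``y`` (n x q, e.g. symptom
    variables) share the n permutation units.  Every (x column, y column)
    pair is a partial Pearson-correlation test; one synchronised set of
    seeded row permutations of ``y`` is applied to all partials, preserving
    their dependence.  Per permutation, partial p-values are ranked within
    the joint null and combined per family (Fisher: ``-2 * sum(log p)``;
    Tippett: smallest p).  The joint p of each family comes from its
    combined-statistic null; ``p_joint`` is additionally family-wise error
    corrected via the distribution of the maximum combined statistic across
    the declared families.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("x and y must be 2-D (units x variables)")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"partial tests must share permutation units: x has {x.shape[0]}, y has {y.shape[0]}"
        )
    if combining not in ("fisher", "tippett"):
        raise ValueError(f"unknown combining function {combining!r}")
    n, p = x.shape
    q = y.shape[1]
    if families is None:
        families = families_per_x(p, q)

    xs = np.column_stack([_standardize_vec(x[:, i], f"x[:,{i}]") for i in range(p)])
    ys = np.column_stack([_standardize_vec(y[:, j], f"y[:,{j}]") for j in range(q)])

    rng = np.random.default_rng(seed)
    B = n_perm
    # stat tensor: (B+1, p, q); row 0 is the identity permutation
    stats = np.empty((B + 1, p, q))
    stats[0] = xs.T @ ys
    for b in range(1, B + 1):
        stats[b] = xs.T @ ys[rng.permutation(n)]

    absT = np.abs(stats).reshape(B + 1, p * q)
    # partial p-values within the synchronised null, per permutation
    pvals = np.empty_like(absT)
    for j in range(p * q):
        col = absT[:, j]
        srt = np.sort(col)
        pvals[:, j] = (B + 1 - np.searchsorted(srt, col - _TIE_EPS, side="left")) / (B + 1)
    pvals = pvals.reshape(B + 1, p, q)

    combined = np.empty((B + 1, len(families)))
    for g, fam in enumerate(families):
        fam_p = np.stack([pvals[:, i, j] for (i, j) in fam], axis=1)
        if combining == "fisher":
            combined[:, g] = -2.0 * np.log(fam_p).sum(axis=1)
        else:
            combined[:, g] = 1.0 - fam_p.min(axis=1)

    max_combined = combined.max(axis=1)
    results = []
    for g, fam in enumerate(families):
        c0 = combined[0, g]
        p_unc = float(np.mean(combined[:, g] >= c0 - _TIE_EPS))
        p_fwe = float(np.mean(max_combined >= c0 - _TIE_EPS))
        results.append(
            NPCResult(
                family=tuple(fam),
                partial_observed=np.array([stats[0, i, j] for (i, j) in fam]),
                partial_p=np.array([pvals[0, i, j] for (i, j) in fam]),
                combining=combining,
                combined_observed=float(c0),
                p_uncorrected=p_unc,
                p_joint=p_fwe,
            )
        )
    return results


# ---------------------------------------------------------------------------
# treatment x time interaction


def interaction_change(
    delta_ct, delta_wait, n_perm: int = 10000, seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Unpaired permutation t-test on per-subject occupancy change scores.

    Compares the amount of change between two visits across treatment arms
    (therapy vs waiting list); delegates to :func:`perm_test_unpaired`.
    """
    res = perm_test_unpaired(delta_ct, delta_wait, n_perm=n_perm, seed=seed,
                             alternative=alternative)
    res.statistic_name = "interaction (unpaired t on change scores)"
    return res
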