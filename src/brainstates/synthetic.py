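"""Synthetic cohorts of Markov-switching Gaussian brain-state time series.

The generator is the testbed for the whole pipeline: it emits parcellated
session matrices whose ground truth (state means, one shared covariance,
condition-specific transition matrices, latent state paths) is known, with
group-level occupancy effects planted by exponential tilting of transition
columns and symptom scores linearly coupled to true fractional occupancy.

The default :class:`CohortDesign` mirrors a mixed longitudinal trauma-therapy
study: 96 sessions over five groups (healthy trauma-exposed controls, PTSD
before/after cognitive therapy, and before/after a waiting list), a 40-block
trauma/neutral picture paradigm at TR 2.4 s, and three bounded DSM-IV-style
symptom-cluster scores per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import SessionRecord, write_events, write_timeseries
from .paradigm import (  # noqa: F401  (re-exported: paradigm is part of this module's surface)
    CONDITIONS,
    NO_CONDITION,
    Block,
    ParameterError,
    TaskParadigm,
    condition_labels,
    generate_paradigm,
)

ALL_LABELS = CONDITIONS + (NO_CONDITION,)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Generative model: K Gaussian states, shared covariance, per-condition chains."""

    means: np.ndarray                         # K x P
    covariance: np.ndarray                    # P x P symmetric PD
    transition_by_condition: dict[str, np.ndarray]  # label -> K x K stochastic
    initial: np.ndarray                       # K simplex

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.means.shape[0]
        if not np.allclose(self.covariance, self.covariance.T):
            raise ParameterError("covariance must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("covariance must be positive definite") from exc
        for label, A in self.transition_by_condition.items():
            A = np.asarray(A, dtype=float)
            if A.shape != (K, K):
                raise ParameterError(f"transition matrix for {label!r} is not {K}x{K}")
            if np.abs(A.sum(axis=1) - 1).max() > 1e-12:
                raise ParameterError(f"transition rows for {label!r} must sum to 1")
            self.transition_by_condition[label] = A
        if abs(self.initial.sum() - 1) > 1e-12:
            raise ParameterError("initial distribution must sum to 1")

    @property
    def K_true(self) -> int:
        return self.means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]


def default_ground_truth(
    n_states: int = 7,
    n_channels: int = 30,
    separation: float = 2.0,
    self_prob: float = 0.8,
    seed: int = 12345,
) -> GroundTruth:
    """A well-separated reference model.

    State means are ``separation`` times random orthonormal directions, so
    any two states are ``separation*sqrt(2)`` apart; the shared covariance is
    a Wishart draw with identity mean (moderate, realistic channel
    correlations); transition matrices are sticky with self-persistence
    ``self_prob`` (expected dwell ``1/(1-self_prob)`` timepoints) and are
    identical across conditions until effects are planted.
    """
    if n_states > n_channels:
        raise ParameterError("need n_channels >= n_states for orthogonal state means")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_states)))
    means = separation * Q.T
    W = rng.standard_normal((n_channels, 2 * n_channels))
    covariance = W @ W.T / (2 * n_channels)
    A = np.full((n_states, n_states), (1 - self_prob) / (n_states - 1))
    np.fill_diagonal(A, self_prob)
    return GroundTruth(
        means=means,
        covariance=covariance,
        transition_by_condition={label: A.copy() for label in ALL_LABELS},
        initial=np.full(n_states, 1.0 / n_states),
    )


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def tilt_transitions(A: np.ndarray, state: int, weight: float) -> np.ndarray:
    """Exponentially tilt transitions toward (weight>0) or away from a state.

    Multiplies the target column by exp(weight) and renormalises rows; the
    emission model is untouched, so planted occupancy effects are purely
    temporal.
    """
    B = np.asarray(A, dtype=float).copy()
    B[:, state] *= np.exp(weight)
    return B / B.sum(axis=1, keepdims=True)


def tilt_weight_for_shift(A: np.ndarray, state: int, shift: float) -> float:
    """Tilt weight whose stationary occupancy of ``state`` shifts by ``shift``."""
    base = stationary_distribution(A)[state]
    target = base + shift
    if not 0 < target < 1:
        raise ParameterError(
            f"requested occupancy shift {shift} puts state {state} outside (0,1)"
        )
    return brentq(
        lambda w: stationary_distribution(tilt_transitions(A, state, w))[state] - target,
        -12.0, 12.0,
    )


# ---------------------------------------------------------------------------
# session simulation


def simulate_session(
    gt: GroundTruth,
    paradigm: TaskParadigm,
    subject_shift: dict[str, tuple[int, float]] | None = None,
    T: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one session: latent Markov path + Gaussian observations.

    ``subject_shift`` maps a condition label to ``(state, occupancy_shift)``;
    the condition's transition matrix is tilted so its stationary occupancy
    of that state moves by the requested amount.  Returns the T x P data
    matrix and the length-T latent path (0-based state labels).
    """
    if T is None:
        T = paradigm.n_timepoints
    if T < 2:
        raise ParameterError(f"T must be >= 2, got {T}")
    if subject_shift:
        for label, (state, _) in subject_shift.items():
            if not 0 <= state < gt.K_true:
                raise ParameterError(f"effect targets state {state}, model has K={gt.K_true}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    trans = {}
    for label in ALL_LABELS:
        A = gt.transition_by_condition[label]
        if subject_shift and label in subject_shift:
            state, shift = subject_shift[label]
            A = tilt_transitions(A, state, tilt_weight_for_shift(A, state, shift))
        trans[label] = A

    # T may truncate or outrun the paradigm (timepoints past the last block are fixation)
    labels = condition_labels(paradigm, T=max(T, paradigm.n_timepoints))[:T]
    K = gt.K_true
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(K, p=gt.initial)
    u = rng.random(T)  # pre-drawn uniforms keep the path reproducible
    for t in range(1, T):
        row = trans[labels[t]][path[t - 1]]
        path[t] = int(np.searchsorted(np.cumsum(row), u[t] * row.sum()))
    L = np.linalg.cholesky(gt.covariance)
    X = gt.means[path] + rng.standard_normal((T, gt.n_channels)) @ L.T
    return X, path


# ---------------------------------------------------------------------------
# cohort design


@dataclass(frozen=True)
class OccupancyEffect:
    """Planted group-level occupancy shift on one state in one condition."""

    group: str
    condition: str
    state: int
    shift: float


@dataclass(frozen=True)
class SymptomSpec:
    """Bounded symptom score linearly coupled to true occupancy of one state.

    ``score = intercept + slope * FO_true(state) + N(0, sigma)``, truncated to
    ``bounds``.  Healthy controls get ``control_level`` plus the same noise
    instead (interview scales are near-floor in recovered/healthy samples).
    """

    name: str
    state: int
    intercept: float
    slope: float
    sigma: float
    bounds: tuple[float, float]
    control_level: float = 1.0


@dataclass
class CohortDesign:
    """Group sizes and planted effects for a synthetic mixed-design cohort."""

    n_controls: int = 15
    n_ct_pairs: int = 14        # scanned pre- and post-therapy
    n_ct_pre_only: int = 17
    n_ct_post_only: int = 16
    n_wait_pairs: int = 8       # scanned before/after a waiting list
    n_wait_pre_only: int = 4
    T: int | None = None        # timepoints per session; None = paradigm length
    effects: tuple[OccupancyEffect, ...] = (
        # untreated PTSD: reduced occupancy of the "mtDMN-like" state 0 under
        # trauma reminders and of the "dmPFC-DMN-like" state 1 under neutral
        # pictures; the waiting list leaves both deficits in place.
        OccupancyEffect("preCT", "trauma", 0, -0.05),
        OccupancyEffect("preWAIT", "trauma", 0, -0.05),
        OccupancyEffect("postWAIT", "trauma", 0, -0.05),
        OccupancyEffect("preCT", "neutral", 1, -0.05),
        OccupancyEffect("preWAIT", "neutral", 1, -0.05),
        OccupancyEffect("postWAIT", "neutral", 1, -0.05),
    )
    symptoms: tuple[SymptomSpec, ...] = (
        # DSM-IV PSS-I cluster ranges; severity falls as state-0 occupancy rises
        SymptomSpec("reexperiencing", 0, 16.0, -60.0, 2.0, (0.0, 12.0)),
        SymptomSpec("avoidance", 0, 22.0, -70.0, 2.5, (0.0, 21.0)),
        SymptomSpec("hyperarousal", 0, 18.0, -60.0, 2.0, (0.0, 18.0)),
    )

    def __post_init__(self) -> None:
        for n in (self.n_controls, self.n_ct_pairs):
            if n < 1:
                raise ParameterError("group sizes must be >= 1")

    @classmethod
    def demo(cls) -> "CohortDesign":
        """Reduced-scale design for quick end-to-end runs and tests."""
        return cls(
            n_controls=4, n_ct_pairs=4, n_ct_pre_only=2, n_ct_post_only=2,
            n_wait_pairs=3, n_wait_pre_only=1,
        )

    @property
    def n_sessions(self) -> int:
        return (
            self.n_controls + 2 * self.n_ct_pairs + self.n_ct_pre_only
            + self.n_ct_post_only + 2 * self.n_wait_pairs + self.n_wait_pre_only
        )


@dataclass
class Cohort:
    """A generated dataset plus its ground truth (for recovery tests)."""

    sessions: list[SessionRecord]
    metadata: pd.DataFrame
    paradigm: TaskParadigm
    ground_truth: GroundTruth
    latent_paths: dict[str, np.ndarray]
    true_occupancy: pd.DataFrame  # per session: empirical occupancy of each state

    def write(self, outdir) -> None:
        """Write the on-disk formats the pipeline reads (all UTF-8 TSV)."""
        outdir = Path(outdir)
        (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False,
                             lineterminator="\n")
        write_events(self.paradigm, outdir / "events.tsv")
        for rec in self.sessions:
            write_timeseries(rec, outdir / "timeseries" / f"{rec.key}.tsv")


def _subject_table(design: CohortDesign) -> list[tuple[str, str, str, str]]:
    """Enumerate (subject, session, group, paired_with) rows for the design."""
    rows = []
    sid = 0

    def nxt() -> str:
        nonlocal sid
        sid += 1
        return f"sub{sid:03d}"

    for _ in range(design.n_controls):
        rows.append((nxt(), "1", "control", "n/a"))
    for _ in range(design.n_ct_pairs):
        s = nxt()
        rows.append((s, "1", "preCT", f"{s}_2"))
        rows.append((s, "2", "postCT", f"{s}_1"))
    for _ in range(design.n_ct_pre_only):
        rows.append((nxt(), "1", "preCT", "n/a"))
    for _ in range(design.n_ct_post_only):
        rows.append((nxt(), "1", "postCT", "n/a"))
    for _ in range(design.n_wait_pairs):
        s = nxt()
        rows.append((s, "1", "preWAIT", f"{s}_2"))
        rows.append((s, "2", "postWAIT", f"{s}_1"))
    for _ in range(design.n_wait_pre_only):
        rows.append((nxt(), "1", "preWAIT", "n/a"))
    return rows


def generate_cohort(
    design: CohortDesign | None = None,
    gt: GroundTruth | None = None,
    seed: int = 0,
    outdir=None,
) -> Cohort:
    """Generate a full cohort with planted effects and coupled symptom scores.

    Deterministic given ``seed``.  If ``outdir`` is given, the on-disk
    formats (timeseries/, events.tsv, metadata.tsv) are written as well.
    """
    design = design or CohortDesign()
    gt = gt or default_ground_truth()
    for eff in design.effects:
        if not 0 <= eff.state < gt.K_true:
            raise ParameterError(
                f"effect targets state {eff.state}, model has K={gt.K_true}"
            )
    rng = np.random.default_rng(seed)
    paradigm = generate_paradigm(seed=seed)
    T = design.T or paradigm.n_timepoints
    shifts_by_group: dict[str, dict[str, tuple[int, float]]] = {}
    for eff in design.effects:
        shifts_by_group.setdefault(eff.group, {})[eff.condition] = (eff.state, eff.shift)

    sessions, paths, occ_rows, meta_rows = [], {}, [], []
    for subject, session, group, paired_with in _subject_table(design):
        X, path = simulate_session(
            gt, paradigm, subject_shift=shifts_by_group.get(group), T=T, seed=rng,
        )
        rec = SessionRecord(
            subject=subject, session=session, group=group, data=X, tr=paradigm.tr,
        )
        sessions.append(rec)
        paths[rec.key] = path
        fo_true = np.bincount(path, minlength=gt.K_true) / len(path)
        occ_rows.append([subject, session, group, *fo_true])
        meta = {
            "subject": subject, "session": session, "group": group,
            "paired_with": paired_with, "tr": paradigm.tr,
        }
        for sym in design.symptoms:
            if group == "control":
                raw = sym.control_level + rng.normal(0.0, sym.sigma)
            else:
                raw = sym.intercept + sym.slope * fo_true[sym.state] + rng.normal(0.0, sym.sigma)
            meta[sym.name] = float(np.clip(raw, *sym.bounds))
        meta_rows.append(meta)

    metadata = pd.DataFrame(meta_rows)
    true_occ = pd.DataFrame(
        occ_rows,
        columns=["subject", "session", "group"] + [f"state{k + 1}" for k in range(gt.K_true)],
    )
    cohort = Cohort(
        sessions=sessions, metadata=metadata, paradigm=paradigm,
        ground_truth=gt, latent_paths=paths, true_occupancy=true_occ,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
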