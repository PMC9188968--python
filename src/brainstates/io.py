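"""Reading, validation and preprocessing of parcellated task time series.

On-disk formats are deliberately plain: tab-delimited numeric matrices
(timepoints x parcels, one file per session, header row of parcel IDs),
BIDS-style events TSV (onset, duration, trial_type) and a cohort metadata
TSV (subject, session, group, paired_with, plus symptom columns).

Preprocessing follows the usual group-HMM pipeline: each session's parcel
time series are z-scored per parcel within session, all sessions are
concatenated in time, and PCA reduces dimensionality to the smallest number
of components explaining a target fraction of variance (default 75%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .paradigm import (
    NO_CONDITION,
    ParameterError,
    TaskParadigm,
    condition_labels,
)

GROUPS = ("control", "preCT", "postCT", "preWAIT", "postWAIT")


class LoadError(ValueError):
    """A file failed validation; the message names the file (and line)."""


@dataclass
class SessionRecord:
    """One scanning session: standardized-or-raw timepoints x parcels matrix."""

    subject: str
    session: str
    group: str
    data: np.ndarray
    tr: float
    parcels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError(
                f"session {self.key}: need a 2-D matrix with >= 2 timepoints, "
                f"got shape {self.data.shape}"
            )
        if np.isnan(self.data).any():
            raise ValueError(f"session {self.key}: data contain missing values")
        if not self.parcels:
            self.parcels = tuple(f"parcel{j + 1}" for j in range(self.data.shape[1]))

    @property
    def key(self) -> str:
        return f"{self.subject}_{self.session}"

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConditionMask:
    """Per-timepoint condition labels; 'none' marks fixation intervals."""

    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.labels == condition)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for c in pd.unique(self.labels) if c != NO_CONDITION)


@dataclass
class PCAModel:
    """Variance-threshold PCA: keep the smallest m explaining >= threshold."""

    loadings: np.ndarray        # parcels x m, orthonormal columns
    explained_ratio: np.ndarray  # length m
    threshold: float
    center: np.ndarray          # per-parcel mean of the fitted matrix

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.center) @ self.loadings


# ---------------------------------------------------------------------------
# readers / writers


def read_timeseries(
    path,
    subject: str = "unknown",
    session: str = "1",
    group: str = "control",
    tr: float = 2.4,
) -> SessionRecord:
    """Read one session's tab-delimited timepoints x parcels matrix."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas names the offending line for ragged rows
        raise LoadError(f"{path}: {exc}") from exc
    bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        raise LoadError(f"{path}: non-numeric values in column(s) {bad}")
    if frame.isna().any().any():
        row = int(np.flatnonzero(frame.isna().any(axis=1))[0])
        raise LoadError(f"{path}: missing value at data row {row + 1}")
    return SessionRecord(
        subject=subject,
        session=session,
        group=group,
        data=frame.to_numpy(dtype=float),
        tr=tr,
        parcels=tuple(frame.columns),
    )


def write_timeseries(record: SessionRecord, path) -> None:
    pd.DataFrame(record.data, columns=list(record.parcels)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_events(path, tr: float = 2.4, n_timepoints: int | None = None) -> TaskParadigm:
    """Read a BIDS-style events TSV into a TaskParadigm."""
    try:
        ev = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise LoadError(f"{path}: {exc}") from exc
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(ev.columns):
        raise LoadError(f"{path}: events table must have columns {sorted(required)}")
    try:
        return TaskParadigm.from_events(ev, tr=tr, n_timepoints=n_timepoints)
    except ParameterError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_events(paradigm: TaskParadigm, path) -> None:
    paradigm.to_events().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the cohort metadata table.

    Required columns: subject, session, group, paired_with.  Any further
    columns are treated as symptom variables.  ``paired_with`` holds the key
    (``subject_session``) of the partner session for longitudinal subjects,
    or ``n/a``.
    """
    try:
        meta = pd.read_csv(path, sep="\t", dtype={"subject": str, "session": str})
    except Exception as exc:
        raise LoadError(f"{path}: {exc}") from exc
    required = ["subject", "session", "group", "paired_with"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise LoadError(f"{path}: metadata missing column(s) {missing}")
    keys = set(meta["subject"] + "_" + meta["session"])
    for i, row in meta.iterrows():
        if row["group"] not in GROUPS:
            raise LoadError(
                f"{path}: line {i + 2}: unknown group label {row['group']!r} "
                f"(expected one of {GROUPS})"
            )
        target = row["paired_with"]
        if pd.notna(target) and target != "n/a" and target not in keys:
            raise LoadError(
                f"{path}: line {i + 2}: paired_with target {target!r} not present in table"
            )
    return meta


def load_dataset(root) -> tuple[list[SessionRecord], pd.DataFrame, TaskParadigm]:
    """Load a full on-disk dataset written by the synthetic generator/CLI.

    Expects ``root/metadata.tsv``, ``root/events.tsv`` and
    ``root/timeseries/<subject>_<session>.tsv``.
    """
    from pathlib import Path

    root = Path(root)
    meta = read_metadata(root / "metadata.tsv")
    tr = float(meta["tr"].iloc[0]) if "tr" in meta.columns else 2.4
    paradigm = read_events(root / "events.tsv", tr=tr)
    sessions = []
    for _, row in meta.iterrows():
        key = f"{row['subject']}_{row['session']}"
        path = root / "timeseries" / f"{key}.tsv"
        if not path.exists():
            raise LoadError(f"{root / 'metadata.tsv'}: session file {path} does not exist")
        sessions.append(
            read_timeseries(
                path, subject=row["subject"], session=row["session"],
                group=row["group"], tr=tr,
            )
        )
    return sessions, meta, paradigm


# ---------------------------------------------------------------------------
# preprocessing


def standardize(session: SessionRecord) -> SessionRecord:
    """Z-score each parcel within session (mean 0, unit variance, ddof=1)."""
    X = session.data
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [session.parcels[j] for j in zero]
        raise ValueError(
            f"session {session.key}: constant parcel(s) {names} cannot be standardized"
        )
    return replace(session, data=(X - X.mean(axis=0)) / sd)


def concatenate(sessions: list[SessionRecord]) -> tuple[np.ndarray, dict[str, slice]]:
    """Stack sessions in time; return the matrix and a session -> row-slice map."""
    if not sessions:
        raise ValueError("no sessions to concatenate")
    P = sessions[0].n_parcels
    for s in sessions:
        if s.n_parcels != P:
            raise ValueError(
                f"session {s.key} has {s.n_parcels} parcels, expected {P}"
            )
    index_map: dict[str, slice] = {}
    start = 0
    for s in sessions:
        index_map[s.key] = slice(start, start + s.n_timepoints)
        start += s.n_timepoints
    X = np.vstack([s.data for s in sessions])
    return X, index_map


def fit_pca(X: np.ndarray, threshold: float = 0.75) -> PCAModel:
    """PCA on the concatenated matrix keeping minimal components >= threshold.

    Component signs are made deterministic: the largest-magnitude loading of
    each retained component is positive.
    """
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    X = np.asarray(X, dtype=float)
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    m = min(m, len(cum))
    loadings = pca.components_[:m].T.copy()  # parcels x m
    for j in range(m):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PCAModel(
        loadings=loadings,
        explained_ratio=pca.explained_variance_ratio_[:m].copy(),
        threshold=threshold,
        center=pca.mean_.copy(),
    )


def condition_mask(
    paradigm: TaskParadigm,
    T: int | None = None,
    tr: float | None = None,
    shift: float = 0.0,
) -> ConditionMask:
    """Assign each timepoint its task condition ('none' during fixation)."""
    return ConditionMask(labels=condition_labels(paradigm, T=T, tr=tr, shift=shift))


def backproject(pca: PCAModel, hmm_means: np.ndarray) -> np.ndarray:
    """Project K x m state means from PC space back to parcel space (K x P).

    The result is in standardized parcel units, i.e. activation relative to
    the temporal average of each parcel.
    """
    hmm_means = np.atleast_2d(np.asarray(hmm_means, dtype=float))
    if hmm_means.shape[1] != pca.n_components:
        raise ValueError(
            f"state means have {hmm_means.shape[1]} dimensions, "
            f"PCA model has {pca.n_components} components"
        )
    return hmm_means @ pca.loadings.T
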