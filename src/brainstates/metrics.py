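"""Summary measures of state dynamics.

Fractional occupancy ("activity time") is the condition-restricted average
of the posterior state probabilities — the fraction of trauma-block or
neutral-block time a participant spends in each state.  Transition counts
are taken from the hard decoded path.  Change scores are visit-2 minus
visit-1 occupancy for longitudinally scanned subjects.

Occupancy is computed from the soft posteriors (gamma); transition counts
use the Viterbi path.  Fixation timepoints ('none') never enter occupancy
denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import StateTimeCourse
from .io import ConditionMask


def _state_cols(K: int) -> list[str]:
    return [f"state{k + 1}" for k in range(K)]


def fractional_occupancy(
    stc: StateTimeCourse | np.ndarray,
    mask: ConditionMask,
    conditions: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Per-condition fractional occupancy: mean gamma over that condition's timepoints.

    Each returned vector lies on the K-simplex (entries in [0,1], summing
    to 1).  Raises if a requested condition has no timepoints.
    """
    gamma = stc.gamma if isinstance(stc, StateTimeCourse) else np.asarray(stc, dtype=float)
    if len(mask) != gamma.shape[0]:
        raise ValueError(
            f"mask has {len(mask)} timepoints, gamma has {gamma.shape[0]}"
        )
    conditions = conditions or mask.conditions
    out = {}
    for cond in conditions:
        idx = mask.indices(cond)
        if idx.size == 0:
            raise ValueError(f"condition {cond!r} has zero timepoints")
        out[cond] = gamma[idx].mean(axis=0)
    return out


def occupancy_table(
    records,
    stcs: list[StateTimeCourse],
    mask: ConditionMask,
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Tidy table: one row per (subject, session, condition) with K fractions."""
    rows = []
    K = stcs[0].gamma.shape[1]
    for rec, stc in zip(records, stcs):
        for cond, fo in fractional_occupancy(stc, mask, conditions).items():
            rows.append({
                "subject": rec.subject, "session": rec.session,
                "group": rec.group, "condition": cond,
                **dict(zip(_state_cols(K), fo)),
            })
    return pd.DataFrame(rows)


def transition_counts(path: np.ndarray, K: int | None = None) -> np.ndarray:
    """Off-diagonal K x K transition counts of a decoded path (diagonal zero)."""
    path = np.asarray(path, dtype=int)
    K = int(path.max()) + 1 if K is None else K
    counts = np.zeros((K, K), dtype=int)
    src, dst = path[:-1], path[1:]
    keep = src != dst
    np.add.at(counts, (src[keep], dst[keep]), 1)
    return counts


def pair_count(path: np.ndarray, i: int, j: int, K: int | None = None) -> int:
    """Transitions between states i and j in either direction."""
    c = transition_counts(path, K)
    return int(c[i, j] + c[j, i])


def transition_count_table(records, paths: dict[str, np.ndarray], K: int) -> pd.DataFrame:
    """Tidy table of per-session off-diagonal transition counts."""
    rows = []
    for rec in records:
        c = transition_counts(paths[rec.key], K)
        row = {"subject": rec.subject, "session": rec.session, "group": rec.group}
        for i in range(K):
            for j in range(K):
                if i != j:
                    row[f"n_{i + 1}_to_{j + 1}"] = int(c[i, j])
        rows.append(row)
    return pd.DataFrame(rows)


def change_scores(occ: pd.DataFrame, subjects: list[str] | None = None) -> pd.DataFrame:
    """Visit-2 minus visit-1 occupancy per paired subject and condition.

    ``occ`` is an :func:`occupancy_table` result containing sessions "1" and
    "2" for the paired subjects.  Raises if a requested subject lacks either
    visit.
    """
    state_cols = [c for c in occ.columns if c.startswith("state")]
    if subjects is None:
        counts = occ.groupby("subject")["session"].nunique()
        subjects = sorted(counts[counts == 2].index)
    rows = []
    for sub in subjects:
        for cond in occ.loc[occ["subject"] == sub, "condition"].unique():
            sel = occ[(occ["subject"] == sub) & (occ["condition"] == cond)]
            v1 = sel[sel["session"] == "1"]
            v2 = sel[sel["session"] == "2"]
            if len(v1) != 1 or len(v2) != 1:
                raise ValueError(f"subject {sub!r} is not a complete pair for {cond!r}")
            delta = v2[state_cols].to_numpy()[0] - v1[state_cols].to_numpy()[0]
            rows.append({"subject": sub, "condition": cond,
                         **dict(zip(state_cols, delta))})
    return pd.DataFrame(rows)
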