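"""Block-design task paradigms.

A paradigm is an ordered sequence of stimulus blocks (trauma-related or
neutral picture series) separated by fixation intervals, sampled at the
scanner repetition time (TR).  The default settings reproduce the classic
symmetric design used for trauma-exposure studies: 20 blocks per condition,
8 pictures of 2 s per block, 8 s fixation gaps, TR = 2.4 s, giving a 16 min
session of 400 volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("trauma", "neutral")
NO_CONDITION = "none"


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


@dataclass(frozen=True)
class Block:
    """One stimulus block: half-open interval [onset, onset+duration) seconds."""

    onset: float
    duration: float
    condition: str

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class TaskParadigm:
    """Ordered, non-overlapping stimulus blocks plus acquisition geometry."""

    blocks: tuple[Block, ...]
    tr: float
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError(f"tr must be positive, got {self.tr}")
        last_end = 0.0
        for blk in self.blocks:
            if blk.duration <= 0:
                raise ParameterError(f"block duration must be positive, got {blk.duration}")
            if blk.onset < last_end - 1e-9:
                raise ParameterError(
                    f"blocks must be ordered and non-overlapping; block at {blk.onset}s "
                    f"starts before previous block end {last_end}s"
                )
            last_end = blk.end
        if self.n_timepoints * self.tr < last_end - 1e-9:
            raise ParameterError(
                f"n_timepoints*tr = {self.n_timepoints * self.tr:.3f}s does not cover "
                f"paradigm end {last_end:.3f}s"
            )

    @property
    def total_duration(self) -> float:
        """Length of the covered acquisition in seconds (last block end)."""
        return self.blocks[-1].end if self.blocks else 0.0

    def n_blocks(self, condition: str | None = None) -> int:
        if condition is None:
            return len(self.blocks)
        return sum(1 for b in self.blocks if b.condition == condition)

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table with columns onset, duration, trial_type."""
        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "trial_type": [b.condition for b in self.blocks],
            }
        )

    @classmethod
    def from_events(cls, events: pd.DataFrame, tr: float, n_timepoints: int | None = None) -> "TaskParadigm":
        blocks = tuple(
            Block(float(r.onset), float(r.duration), str(r.trial_type))
            for r in events.itertuples(index=False)
        )
        if n_timepoints is None:
            end = max((b.end for b in blocks), default=0.0)
            n_timepoints = math.ceil(end / tr - 1e-9)
        return cls(blocks=blocks, tr=tr, n_timepoints=n_timepoints)


def generate_paradigm(
    n_blocks_per_condition: int = 20,
    pictures_per_block: int = 8,
    picture_duration: float = 2.0,
    inter_block_interval: float = 8.0,
    tr: float = 2.4,
    seed: int = 0,
) -> TaskParadigm:
    """Build a pseudorandomised symmetric block design.

    Each block shows ``pictures_per_block`` pictures of ``picture_duration``
    seconds back to back, followed by an ``inter_block_interval`` fixation gap.
    Condition order is a seeded shuffle of an equal number of trauma and
    neutral blocks.  Total duration is
    ``2*n_blocks_per_condition * (block_duration + inter_block_interval)``.
    """
    if n_blocks_per_condition < 1 or pictures_per_block < 1:
        raise ParameterError("block and picture counts must be >= 1")
    for name, val in (
        ("picture_duration", picture_duration),
        ("tr", tr),
    ):
        if val <= 0:
            raise ParameterError(f"{name} must be positive, got {val}")
    if inter_block_interval < 0:
        raise ParameterError(f"inter_block_interval must be >= 0, got {inter_block_interval}")

    rng = np.random.default_rng(seed)
    labels = [CONDITIONS[0]] * n_blocks_per_condition + [CONDITIONS[1]] * n_blocks_per_condition
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    block_duration = pictures_per_block * picture_duration
    blocks = []
    onset = 0.0
    for lab in labels:
        blocks.append(Block(onset=onset, duration=block_duration, condition=lab))
        onset += block_duration + inter_block_interval
    total = onset  # includes trailing fixation interval
    n_timepoints = math.ceil(total / tr - 1e-9)
    return TaskParadigm(blocks=tuple(blocks), tr=tr, n_timepoints=n_timepoints)


def condition_labels(
    paradigm: TaskParadigm,
    T: int | None = None,
    tr: float | None = None,
    shift: float = 0.0,
) -> np.ndarray:
    """Label each timepoint with its block condition, or 'none' for fixation.

    Timepoint ``t`` (0-based, acquisition-onset convention) is assigned the
    condition of the block whose half-open interval [onset, onset+duration)
    contains ``t*tr + shift``.  ``shift`` is an optional hemodynamic delay in
    seconds (default 0).
    """
    if shift < 0:
        raise ParameterError(f"shift must be >= 0, got {shift}")
    T = paradigm.n_timepoints if T is None else T
    tr = paradigm.tr if tr is None else tr
    if T * tr < paradigm.total_duration - 1e-9:
        raise ParameterError(
            f"T*tr = {T * tr:.3f}s is shorter than the paradigm ({paradigm.total_duration:.3f}s)"
        )
    times = np.arange(T) * tr + shift
    labels = np.full(T, NO_CONDITION, dtype=object)
    for blk in paradigm.blocks:
        sel = (times >= blk.onset - 1e-9) & (times < blk.end - 1e-9)
        labels[sel] = blk.condition
    return labels
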