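"""Balanced experimental designs for the urgent flanker task.

The paradigm: each trial starts with a fixation stimulus; its offset is the
Go-signal that opens a fixed 1,000-ms response window. The target (plus
flankers) appears only after a variable *gap* (0-950 ms), so long gaps leave
little time to process the target -- this is the urgency manipulation. In the
SOA variant the flankers precede the target by a stimulus-onset asynchrony.

A design is a trial table without responses: every block contains the full
factorial of gap x congruency x target x SOA x fixation duration exactly
``trials_per_block / n_combinations`` times, in an order randomized per block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "DesignError", "build_design", "TRIAL_COLUMNS"]

#: Canonical column order of a trial table (design + response fields).
TRIAL_COLUMNS = [
    "participant", "session", "block", "trial_in_block", "is_practice",
    "congruency", "soa_ms", "gap_ms", "fixation_ms", "target",
    "response", "rt_ms", "correct", "on_time",
]

CONGRUENCY_LEVELS = ("congruent", "incongruent")
TARGET_LEVELS = ("left", "right")


class DesignError(ValueError):
    """Raised when a design specification cannot be balanced."""


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of one experiment.

    Parameters
    ----------
    n_participants, n_sessions, blocks_per_session, trials_per_block
        Sample-size structure. ``trials_per_block`` must be an exact
        multiple of the number of factor combinations.
    gap_levels_ms
        Go-signal-to-target intervals (the urgency factor), strictly
        increasing, non-negative.
    fixation_levels_ms
        Possible fixation durations preceding the Go-signal.
    soa_levels_ms
        Flanker-to-target onset asynchronies; ``(0,)`` when flankers and
        target appear together.
    deadline_ms
        Response deadline measured from the Go-signal.
    practice_blocks
        Number of leading blocks of session 1 flagged as practice.
    """

    n_participants: int = 6
    n_sessions: int = 5
    blocks_per_session: int = 9
    trials_per_block: int = 132
    gap_levels_ms: Sequence[int] = (0, 100, 200, 300, 400, 500, 600, 700, 800, 900, 950)
    fixation_levels_ms: Sequence[int] = (350, 400, 500)
    soa_levels_ms: Sequence[int] = (0,)
    congruency_levels: Sequence[str] = CONGRUENCY_LEVELS
    target_levels: Sequence[str] = TARGET_LEVELS
    deadline_ms: float = 1000.0
    practice_blocks: int = 1

    def __post_init__(self) -> None:
        gaps = np.asarray(self.gap_levels_ms)
        if np.any(gaps < 0) or np.any(np.diff(gaps) <= 0):
            raise DesignError("gap_levels_ms must be non-negative and strictly increasing")
        if self.deadline_ms <= 0:
            raise DesignError("deadline_ms must be positive")
        base = (len(self.gap_levels_ms) * len(self.congruency_levels)
                * len(self.target_levels) * len(self.soa_levels_ms))
        if self.trials_per_block % base != 0:
            raise DesignError(
                f"trials_per_block={self.trials_per_block} is not a multiple of the "
                f"{base} gap x congruency x target x SOA combinations"
            )

    @property
    def trials_per_participant(self) -> int:
        return self.n_sessions * self.blocks_per_session * self.trials_per_block

    @property
    def total_trials(self) -> int:
        return self.n_participants * self.trials_per_participant

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("gap_levels_ms", "fixation_levels_ms", "soa_levels_ms",
                  "congruency_levels", "target_levels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(**d)


def _block_cells(spec: DesignSpec) -> list[tuple]:
    """Factor combinations for one block, replicated to trials_per_block rows.

    Fixation duration joins the factorial whenever the block size allows an
    exact balance (all three experiments do: e.g. 11 x 2 x 2 x 3 = 132);
    otherwise it is cycled across replicates, which keeps its marginal counts
    as even as the block size permits.
    """
    base = list(itertools.product(
        spec.gap_levels_ms, spec.congruency_levels, spec.target_levels,
        spec.soa_levels_ms))
    full = [b + (f,) for b in base for f in spec.fixation_levels_ms]
    if spec.trials_per_block % len(full) == 0:
        return full * (spec.trials_per_block // len(full))
    reps = spec.trials_per_block // len(base)
    fix = itertools.cycle(spec.fixation_levels_ms)
    return [b + (next(fix),) for _ in range(reps) for b in base]


def build_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Generate the full randomized trial skeleton for every participant.

    Returns a table with one row per trial and empty response fields
    (``response``/``rt_ms``/``correct``/``on_time`` are NaN/None). Within
    each block every factor combination occurs equally often and the order
    is an independent permutation; the first ``practice_blocks`` blocks of
    session 1 are flagged ``is_practice`` for every participant.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDE51]))
    cells = _block_cells(spec)
    n_cell = len(cells)
    cell_arr = pd.DataFrame(cells, columns=["gap_ms", "congruency", "target",
                                            "soa_ms", "fixation_ms"])
    frames = []
    for p in range(1, spec.n_participants + 1):
        for s in range(1, spec.n_sessions + 1):
            for b in range(1, spec.blocks_per_session + 1):
                order = rng.permutation(n_cell)
                blk = cell_arr.iloc[order].reset_index(drop=True)
                blk.insert(0, "participant", f"P{p:02d}")
                blk.insert(1, "session", s)
                blk.insert(2, "block", b)
                blk.insert(3, "trial_in_block", np.arange(1, n_cell + 1))
                blk.insert(4, "is_practice", (s == 1) and (b <= spec.practice_blocks))
                frames.append(blk)
    out = pd.concat(frames, ignore_index=True)
    out["response"] = pd.Series([None] * len(out), dtype=object)
    out["rt_ms"] = np.nan
    out["correct"] = np.nan
    out["on_time"] = np.nan
    return out[TRIAL_COLUMNS]
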