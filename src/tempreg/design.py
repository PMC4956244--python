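"""Trial grids and stimulus realization for jittered-tone-sequence experiments.

Two tasks are supported: a regularity judgment on five-tone sequences whose
final tone can deviate from the isochronous grid (``exp1``), and an
audiovisual temporal-order judgment in which a flash probes the perceived
timing of the final tone (``exp2``), preceded by a single-tone practice
phase (``practice``).

All times are in milliseconds.  The base inter-onset interval (IOI) is
700 ms; per-interval jitter is uniform on ±jitter_level; the final tone's
anisochrony is defined on the nominal grid (4 × IOI + anisochrony).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASE_IOI_MS = 700.0

JITTER_LEVELS = {
    "regular": (0.0, 10.0, 20.0, 30.0),
    "irregular": (0.0, 50.0, 100.0, 150.0),
}

EXP1_ANISOCHRONIES = (
    -200.0, -150.0, -100.0, -80.0, -60.0, -40.0, -20.0, 0.0,
    20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0,
)
EXP2_ANISOCHRONIES = (-40.0, 40.0)
EXP2_SOAS = (-200.0, -120.0, -80.0, -40.0, 0.0, 40.0, 80.0, 120.0, 200.0)
PRACTICE_SOAS = (
    -350.0, -250.0, -170.0, -90.0, -20.0, 0.0,
    20.0, 90.0, 170.0, 250.0, 350.0,
)

EXPERIMENTS = ("exp1", "exp2", "practice")

#: Column order of the trial-table CSV interchange format.
GRID_COLUMNS = [
    "trial_id", "experiment", "environment", "jitter_level_ms",
    "anisochrony_ms", "soa_ms", "repetition_index",
]
SEQUENCE_COLUMNS = GRID_COLUMNS + [
    "onset_1_ms", "onset_2_ms", "onset_3_ms", "onset_4_ms", "onset_5_ms",
    "flash_onset_ms", "seed",
]


@dataclass(frozen=True)
class TrialCondition:
    """One cell of an experimental design.

    ``soa`` is the flash onset minus the final tone onset and is ``None``
    for the regularity task, which has no visual probe.  Negative
    ``anisochrony`` means the final tone is early.
    """

    experiment: str
    environment: str
    jitter_level: float
    anisochrony: float
    soa: float | None
    repetition_index: int

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.environment not in JITTER_LEVELS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.experiment == "exp1" and self.soa is not None:
            raise ValueError("exp1 trials have no visual probe (soa)")
        if self.experiment != "exp1" and self.soa is None:
            raise ValueError(f"{self.experiment} trials require an soa")
        if self.jitter_level not in JITTER_LEVELS[self.environment]:
            raise ValueError(
                f"jitter level {self.jitter_level} invalid for "
                f"{self.environment} environment"
            )


@dataclass(frozen=True)
class StimulusSequence:
    """Realized onset times for one trial.

    Five tones for the sequence tasks, one for practice; ``flash_onset``
    is present only when the trial has a visual probe.
    """

    tone_onsets: tuple[float, ...]
    flash_onset: float | None
    condition: TrialCondition
    rng_seed_record: int

    def __post_init__(self) -> None:
        onsets = np.asarray(self.tone_onsets)
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("tone onsets must be strictly increasing")


def _check_environment(environment: str) -> tuple[float, ...]:
    try:
        return JITTER_LEVELS[environment]
    except KeyError:
        raise ValueError(
            f"unknown environment {environment!r}; expected one of "
            f"{sorted(JITTER_LEVELS)}"
        ) from None


def build_exp1_grid(environment: str, repetitions: int) -> list[TrialCondition]:
    """Full cross of 4 jitter levels x 15 anisochronies x repetitions.

    Deterministic ordering (jitter, anisochrony, repetition); shuffle
    separately with :func:`shuffle_grid`.
    """
    jitters = _check_environment(environment)
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    return [
        TrialCondition("exp1", environment, j, a, None, r)
        for j in jitters
        for a in EXP1_ANISOCHRONIES
        for r in range(repetitions)
    ]


def build_exp2_grid(environment: str, repetitions: int) -> list[TrialCondition]:
    """Full cross of 4 jitter levels x 2 deviants (±40 ms) x 9 SOAs x reps."""
    jitters = _check_environment(environment)
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    return [
        TrialCondition("exp2", environment, j, a, s, r)
        for j in jitters
        for a in EXP2_ANISOCHRONIES
        for s in EXP2_SOAS
        for r in range(repetitions)
    ]


def build_practice_grid(
    repetitions: int, environment: str = "regular"
) -> list[TrialCondition]:
    """Single tone + flash at each of 11 SOAs (0, ±20, ±90, ±170, ±250, ±350)."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    _check_environment(environment)
    return [
        TrialCondition("practice", environment, 0.0, 0.0, s, r)
        for s in PRACTICE_SOAS
        for r in range(repetitions)
    ]


def shuffle_grid(
    grid: Sequence[TrialCondition], seed: int
) -> list[TrialCondition]:
    """Seeded permutation of a grid ("conditions randomly interleaved")."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(grid))
    return [grid[i] for i in order]


def realize_sequence(
    condition: TrialCondition,
    ioi: float = BASE_IOI_MS,
    rng: np.random.Generator | int | None = None,
) -> StimulusSequence:
    """Realize a condition into concrete onset times.

    The first tone is at 0; each of the next three intervals is
    ``ioi + U(-jitter, +jitter)`` drawn independently; the final tone sits
    on the nominal grid at ``4*ioi + anisochrony`` regardless of the jitter
    realized earlier, so the "expected" time point stays well defined.
    The flash, when present, is at final tone + SOA.  Practice trials are a
    single tone at 0 with the flash at the SOA.
    """
    if ioi <= 0:
        raise ValueError("ioi must be positive")
    if condition.jitter_level >= ioi:
        raise ValueError("jitter level must be smaller than the IOI")
    if isinstance(rng, np.random.Generator):
        seed_record = -1
    else:
        seed_record = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed_record)

    if condition.experiment == "practice":
        return StimulusSequence((0.0,), condition.soa, condition, seed_record)

    j = condition.jitter_level
    intervals = ioi + rng.uniform(-j, j, size=3)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    final = 4.0 * ioi + condition.anisochrony
    if final <= onsets[-1]:
        raise ValueError(
            "jitter and anisochrony produced non-increasing onsets"
        )
    tone_onsets = tuple(np.append(onsets, final))
    flash = None if condition.soa is None else final + condition.soa
    return StimulusSequence(tone_onsets, flash, condition, seed_record)


# ---------------------------------------------------------------------------
# CSV interchange


def grid_to_frame(
    grid: Iterable[TrialCondition],
    sequences: Sequence[StimulusSequence] | None = None,
) -> pd.DataFrame:
    """Tabulate conditions (and, optionally, their realized sequences)."""
    rows = []
    for i, cond in enumerate(grid):
        row = {"trial_id": i, **dataclasses.asdict(cond)}
        row["jitter_level_ms"] = row.pop("jitter_level")
        row["anisochrony_ms"] = row.pop("anisochrony")
        row["soa_ms"] = row.pop("soa")
        if sequences is not None:
            seq = sequences[i]
            for k in range(5):
                key = f"onset_{k + 1}_ms"
                row[key] = (
                    seq.tone_onsets[k] if k < len(seq.tone_onsets) else None
                )
            row["flash_onset_ms"] = seq.flash_onset
            row["seed"] = seq.rng_seed_record
        rows.append(row)
    cols = SEQUENCE_COLUMNS if sequences is not None else GRID_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def frame_to_grid(frame: pd.DataFrame) -> list[TrialCondition]:
    """Rebuild conditions from a trial table (inverse of grid_to_frame)."""
    grid = []
    for _, row in frame.iterrows():
        soa = row["soa_ms"]
        grid.append(
            TrialCondition(
                experiment=row["experiment"],
                environment=row["environment"],
                jitter_level=float(row["jitter_level_ms"]),
                anisochrony=float(row["anisochrony_ms"]),
                soa=None if pd.isna(soa) else float(soa),
                repetition_index=int(row["repetition_index"]),
            )
        )
    return grid


def write_grid(path, grid, sequences=None) -> None:
    grid_to_frame(grid, sequences).to_csv(path, index=False)


def read_grid(path) -> list[TrialCondition]:
    return frame_to_grid(pd.read_csv(path))
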