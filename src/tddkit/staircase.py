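"""Adaptive staircase protocol for tactile direction discrimination (TDD).

The test moves a probe across the skin over one of seven path lengths
(approximately logarithmic series, 3-100 mm) in a proximodistal or
distoproximal direction; the participant reports the perceived direction
(two-alternative forced choice).  The distance adapts: an incorrect answer
makes the task easier (next longer distance), three correct answers in a row
make it harder (next shorter distance).  After a fixed number of trials
(default 32, balanced between the two directions) the score is the sum,
over trials, of the position of each trial's distance in the series counted
from the shortest ("boxes to the left" on the paper scoring sheet).  The
score approximates the area under the staircase trace: higher = worse
direction discrimination.  Under the default protocol the score ranges from
18 (always correct) to 186 (always incorrect).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_SERIES",
    "DIRECTIONS",
    "StaircaseConfig",
    "Trial",
    "ScoringSheet",
    "next_state",
    "make_direction_sequence",
    "run_staircase",
    "score_sheet",
    "score_distances",
    "expected_score_dp",
]

#: Default stimulus path lengths in mm, shortest (hardest) first.
DEFAULT_SERIES: tuple[float, ...] = (3.0, 6.0, 10.0, 18.0, 32.0, 56.0, 100.0)

DIRECTIONS = ("distoproximal", "proximodistal")


@dataclass(frozen=True)
class StaircaseConfig:
    """Protocol parameters.

    ``speed_mm_s`` and ``load_g`` are stimulus metadata (10 mm/s probe speed,
    16 g vertical load in the clinical protocol); they do not enter the
    simulation or the score.
    """

    series: tuple[float, ...] = DEFAULT_SERIES
    n_trials: int = 32
    start_distance: float = 18.0
    n_correct_to_step_down: int = 3
    speed_mm_s: float = 10.0
    load_g: float = 16.0

    def __post_init__(self) -> None:
        series = tuple(float(d) for d in self.series)
        object.__setattr__(self, "series", series)
        if len(series) < 2 or any(b <= a for a, b in zip(series, series[1:])):
            raise ValueError("series must be strictly increasing with >=2 distances")
        if self.n_trials <= 0 or self.n_trials % 2:
            raise ValueError("n_trials must be a positive even number")
        if float(self.start_distance) not in series:
            raise ValueError(f"start_distance {self.start_distance} not in series")
        if self.n_correct_to_step_down < 1:
            raise ValueError("n_correct_to_step_down must be >= 1")

    @property
    def start_level(self) -> int:
        return self.series.index(float(self.start_distance))

    def level_of(self, distance: float) -> int:
        """0-based index of ``distance`` in the series ("boxes to the left")."""
        try:
            return self.series.index(float(distance))
        except ValueError:
            raise ValueError(f"distance {distance} not in series {self.series}") from None


@dataclass(frozen=True)
class Trial:
    index: int  # 1-based
    distance: float  # mm
    direction: str
    correct: bool

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class ScoringSheet:
    """One completed staircase: the trials in order plus the derived score."""

    config: StaircaseConfig
    trials: list[Trial]
    score: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def replay_ok(self) -> bool:
        """Check that the stored distances obey the adaptive update rule."""
        cfg = self.config
        level, streak = cfg.start_level, 0
        for t in self.trials:
            if cfg.level_of(t.distance) != level:
                return False
            level, streak = next_state(
                level, streak, t.correct,
                n_levels=len(cfg.series),
                n_correct_to_step_down=cfg.n_correct_to_step_down,
            )
        return True

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "config": {
                "series": list(self.config.series),
                "n_trials": self.config.n_trials,
                "start_distance": self.config.start_distance,
                "n_correct_to_step_down": self.config.n_correct_to_step_down,
                "speed_mm_s": self.config.speed_mm_s,
                "load_g": self.config.load_g,
            },
            "seed": self.seed,
            "score": self.score,
            "trials": [
                {"index": t.index, "distance_mm": t.distance,
                 "direction": t.direction, "correct": t.correct}
                for t in self.trials
            ],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScoringSheet":
        obj = json.loads(text)
        cfg = StaircaseConfig(
            series=tuple(obj["config"]["series"]),
            n_trials=obj["config"]["n_trials"],
            start_distance=obj["config"]["start_distance"],
            n_correct_to_step_down=obj["config"]["n_correct_to_step_down"],
            speed_mm_s=obj["config"].get("speed_mm_s", 10.0),
            load_g=obj["config"].get("load_g", 16.0),
        )
        trials = [Trial(t["index"], t["distance_mm"], t["direction"], t["correct"])
                  for t in obj["trials"]]
        return cls(config=cfg, trials=trials, score=obj["score"], seed=obj.get("seed"))

    def to_csv(self, path) -> None:
        """One row per trial; score and config in '#' header comment lines."""
        with open(path, "w", newline="") as fh:
            fh.write(f"# score={self.score}\n")
            fh.write(f"# series={','.join(str(d) for d in self.config.series)}\n")
            fh.write(f"# seed={self.seed}\n")
            w = csv.writer(fh)
            w.writerow(["index", "distance_mm", "direction", "correct"])
            for t in self.trials:
                w.writerow([t.index, t.distance, t.direction, int(t.correct)])


def next_state(
    level: int,
    consecutive_correct: int,
    correct: bool,
    *,
    n_levels: int = len(DEFAULT_SERIES),
    n_correct_to_step_down: int = 3,
) -> tuple[int, int]:
    """Advance the staircase state by one response.

    ``level`` indexes the distance series (0 = shortest/hardest).  An
    incorrect response moves one level up (longer, easier distance) and
    resets the correct-run counter; the counter also resets whenever the
    level steps down after ``n_correct_to_step_down`` correct responses in a
    row.  Both ends of the series clamp.
    """
    if not 0 <= level < n_levels:
        raise ValueError(f"level {level} outside [0, {n_levels})")
    if not 0 <= consecutive_correct < n_correct_to_step_down:
        raise ValueError(
            f"consecutive_correct {consecutive_correct} outside "
            f"[0, {n_correct_to_step_down})")
    if not correct:
        return min(level + 1, n_levels - 1), 0
    streak = consecutive_correct + 1
    if streak == n_correct_to_step_down:
        return max(level - 1, 0), 0
    return level, streak


def make_direction_sequence(
    n_trials: int,
    seed: int | np.random.Generator,
    *,
    max_run: int | None = None,
) -> list[str]:
    """Balanced pseudo-random direction order: a seeded shuffle of
    n/2 distoproximal + n/2 proximodistal trials.

    ``max_run`` optionally rejects shuffles containing a run of more than
    that many identical directions (off by default; the clinical protocol
    states only that the order is pseudo-random).
    """
    if n_trials <= 0 or n_trials % 2:
        raise ValueError("n_trials must be a positive even number")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.repeat([0, 1], n_trials // 2)
    while True:
        order = rng.permutation(base)
        if max_run is None:
            break
        runs = np.diff(np.flatnonzero(np.diff(np.r_[2, order, 2])))
        if runs.max() <= max_run:
            break
    return [DIRECTIONS[i] for i in order]


def _check_observer(observer: Callable[[float], float], series: Sequence[float]) -> list[float]:
    probs = []
    for d in series:
        p = float(observer(d))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"observer returned P={p} at distance {d}; must lie in [0,1]")
        probs.append(p)
    return probs


def run_staircase(
    observer: Callable[[float], float],
    config: StaircaseConfig = StaircaseConfig(),
    seed: int | None = 0,
    *,
    max_run: int | None = None,
) -> ScoringSheet:
    """Simulate one full staircase for a stochastic observer.

    ``observer(distance_mm)`` returns the probability of a correct direction
    judgement at that path length.  Direction scheduling and distance
    adaptation use independent streams spawned from ``seed``; responses
    depend on distance only (the protocol treats directions symmetrically).
    """
    _check_observer(observer, config.series)
    ss = np.random.SeedSequence(seed)
    dir_rng, resp_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    directions = make_direction_sequence(config.n_trials, dir_rng, max_run=max_run)

    trials: list[Trial] = []
    level, streak = config.start_level, 0
    for i in range(config.n_trials):
        d = config.series[level]
        correct = bool(resp_rng.random() < float(observer(d)))
        trials.append(Trial(index=i + 1, distance=d, direction=directions[i], correct=correct))
        level, streak = next_state(
            level, streak, correct,
            n_levels=len(config.series),
            n_correct_to_step_down=config.n_correct_to_step_down,
        )
    sheet = ScoringSheet(config=config, trials=trials, score=0, seed=seed)
    sheet.score = score_sheet(sheet)
    return sheet


def score_distances(distances: Sequence[float], series: Sequence[float] = DEFAULT_SERIES) -> int:
    """Sum of 0-based series indices of the visited distances."""
    series = tuple(float(d) for d in series)
    total = 0
    for d in distances:
        if float(d) not in series:
            raise ValueError(f"distance {d} not in series {series}")
        total += series.index(float(d))
    return total


def score_sheet(sheet: ScoringSheet) -> int:
    """TDD score of a completed sheet: each trial contributes the number of
    boxes to the left of its distance column, i.e. its 0-based series index.
    Correct and incorrect trials are scored identically; only the distances
    visited matter."""
    return score_distances([t.distance for t in sheet.trials], sheet.config.series)


def expected_score_dp(
    observer: Callable[[float], float],
    config: StaircaseConfig = StaircaseConfig(),
) -> float:
    """Exact expected score by forward dynamic programming.

    Propagates the probability distribution over (level, correct-run counter)
    across trials; no sampling.  Serves as an independent oracle for
    Monte-Carlo simulations of :func:`run_staircase`.
    """
    probs = _check_observer(observer, config.series)
    n_levels = len(config.series)
    k = config.n_correct_to_step_down
    # state[l, c] = P(being at level l with correct-run counter c before the trial)
    state = np.zeros((n_levels, k))
    state[config.start_level, 0] = 1.0
    expected = 0.0
    levels = np.arange(n_levels, dtype=float)
    for _ in range(config.n_trials):
        expected += float((state.sum(axis=1) * levels).sum())
        nxt = np.zeros_like(state)
        for lvl in range(n_levels):
            p = probs[lvl]
            for c in range(k):
                m = state[lvl, c]
                if m == 0.0:
                    continue
                # incorrect: step up (clamped), counter reset
                nxt[min(lvl + 1, n_levels - 1), 0] += m * (1.0 - p)
                if c + 1 == k:  # run complete: step down (clamped), reset
                    nxt[max(lvl - 1, 0), 0] += m * p
                else:
                    nxt[lvl, c + 1] += m * p
        state = nxt
    return expected
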