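"""Experimental design generation for the 3 x 3 x 2 gratitude/joy paradigm.

The task crosses benefactor intention (strong / weak / no) with benefit value
(high / low / zero); on every trial the subject rates both gratitude and joy,
so emotion is a within-trial factor carried by the two rating screens.  Each
trial is a 3 s scenario screen followed by two rating screens whose durations
sum to 12 s, with three 0.5 s fixations, giving a fixed 16.5 s trial span.
Runs hold 20 trials (18 condition trials -- two per factorial cell -- plus 2
null trials) presented pseudo-randomly so that no two consecutive condition
trials share an intention level or a value level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

INTENTION_LEVELS = ("strong", "weak", "no")
VALUE_LEVELS = ("high", "low", "zero")
EMOTIONS = ("gratitude", "joy")
RATING_ORDERS = ("gratitude_first", "joy_first")

#: run-wise rating-order sequences; "A" = gratitude rated first
ORDER_SCHEMES = {
    "A-B-B-A-A-B": ("gratitude_first", "joy_first", "joy_first",
                    "gratitude_first", "gratitude_first", "joy_first"),
    "B-A-A-B-B-A": ("joy_first", "gratitude_first", "gratitude_first",
                    "joy_first", "joy_first", "gratitude_first"),
}

STIM_DURATION = 3.0
FIXATION_DURATION = 0.5
RATING_TOTAL = 12.0
#: admissible (first rating, second rating) duration splits in seconds
RATING_SPLITS = ((8.0, 4.0), (7.0, 5.0), (6.0, 6.0), (5.0, 7.0), (4.0, 8.0))
TRIAL_SPAN = 16.5

INTENTION_PERCENT_RANGE = {"strong": (95, 100), "weak": (7, 12), "no": (0, 0)}
VALUE_AMOUNT_RANGE = {"high": (800, 1200), "low": (80, 120), "zero": (0, 0)}

#: 1/0/-1 modulator codes for the ordinal factor levels
INTENTION_CODE = {"strong": 1, "weak": 0, "no": -1}
VALUE_CODE = {"high": 1, "low": 0, "zero": -1}

DEFAULT_TR = 2.3
DEFAULT_N_VOLUMES = 145
N_TRIALS_PER_RUN = 20
N_NULL_PER_RUN = 2
TRIALS_PER_CELL_PER_RUN = 2
N_RUNS = 6


def condition_name(emotion: str, intention: str, value: str) -> str:
    return f"{emotion}_{intention}_{value}"


def condition_names() -> list[str]:
    """The 18 Model-1 condition regressor names (emotion x intention x value)."""
    return [condition_name(e, i, v)
            for e in EMOTIONS for i in INTENTION_LEVELS for v in VALUE_LEVELS]


@dataclass(frozen=True)
class TrialEvent:
    """One trial: timing plus factorial cell assignment (None for nulls)."""
    run_index: int
    trial_index: int
    onset: float
    is_null: bool
    intention_level: str | None
    intention_percent: int
    value_level: str | None
    value_amount: int
    rating_order: str
    rating1_duration: float
    rating2_duration: float
    stim_duration: float = STIM_DURATION
    fixation_duration: float = FIXATION_DURATION

    @property
    def span(self) -> float:
        return (self.stim_duration + 3 * self.fixation_duration
                + self.rating1_duration + self.rating2_duration)

    @property
    def rating1_onset(self) -> float:
        return self.onset + self.stim_duration + self.fixation_duration

    @property
    def rating2_onset(self) -> float:
        return self.rating1_onset + self.rating1_duration + self.fixation_duration

    def rating_onset(self, emotion: str) -> float:
        """Onset of the rating screen for ``emotion`` given the run's order."""
        first = self.rating_order == ("gratitude_first" if emotion == "gratitude"
                                      else "joy_first")
        return self.rating1_onset if first else self.rating2_onset

    def rating_duration(self, emotion: str) -> float:
        first = self.rating_order == ("gratitude_first" if emotion == "gratitude"
                                      else "joy_first")
        return self.rating1_duration if first else self.rating2_duration


@dataclass(frozen=True)
class RunSchedule:
    run_index: int
    rating_order: str
    trials: tuple[TrialEvent, ...]
    tr: float = DEFAULT_TR
    n_volumes: int = DEFAULT_N_VOLUMES

    @property
    def run_duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def condition_trials(self) -> tuple[TrialEvent, ...]:
        return tuple(t for t in self.trials if not t.is_null)


@dataclass(frozen=True)
class SubjectDesign:
    subject_id: int
    order_scheme: str
    runs: tuple[RunSchedule, ...]


class ScheduleError(RuntimeError):
    """Raised when no trial ordering satisfies the adjacency constraints."""


def _search_sequence(cells: list[tuple[str, str]], rng: np.random.Generator,
                     node_budget: int) -> list[tuple[str, str]] | None:
    """Randomized backtracking over orderings of ``cells`` such that no two
    consecutive entries share an intention or a value level."""
    counts: dict[tuple[str, str], int] = {}
    for c in cells:
        counts[c] = counts.get(c, 0) + 1
    distinct = list(counts)
    n = len(cells)
    seq: list[tuple[str, str]] = []
    nodes = 0

    def extend() -> bool:
        nonlocal nodes
        if len(seq) == n:
            return True
        nodes += 1
        if nodes > node_budget:
            return False
        prev = seq[-1] if seq else None
        candidates = [c for c in distinct if counts[c] > 0
                      and (prev is None
                           or (c[0] != prev[0] and c[1] != prev[1]))]
        rng.shuffle(candidates)
        for c in candidates:
            counts[c] -= 1
            seq.append(c)
            if extend():
                return True
            seq.pop()
            counts[c] += 1
        return False

    return seq if extend() else None


def generate_run_schedule(run_index: int, rating_order: str, seed,
                          trials_per_cell: int = TRIALS_PER_CELL_PER_RUN,
                          n_null: int = N_NULL_PER_RUN,
                          tr: float = DEFAULT_TR,
                          n_volumes: int = DEFAULT_N_VOLUMES,
                          balanced_rating_durations: bool = False,
                          max_restarts: int = 100) -> RunSchedule:
    """Generate one pseudo-randomized run.

    The 9 factorial cells each appear ``trials_per_cell`` times; null trials
    are inserted at uniformly random positions and the adjacency constraint
    (no repeated intention or value level) is enforced between consecutive
    condition trials, skipping over nulls.  Trials tile consecutively at
    16.5 s from t = 0.

    Raises
    ------
    ScheduleError
        If no constraint-satisfying ordering is found within the retry
        budget (signals an infeasible cell configuration).
    """
    if rating_order not in RATING_ORDERS:
        raise ValueError(f"unknown rating order {rating_order!r}")
    rng = np.random.default_rng(seed)
    cells = [(i, v) for i in INTENTION_LEVELS for v in VALUE_LEVELS
             for _ in range(trials_per_cell)]
    seq = None
    for _ in range(max_restarts):
        seq = _search_sequence(cells, rng, node_budget=20_000)
        if seq is not None:
            break
    if seq is None:
        raise ScheduleError(
            f"no admissible trial ordering found in {max_restarts} restarts")

    n_trials = len(cells) + n_null
    null_positions = set(rng.choice(n_trials, size=n_null, replace=False).tolist())

    if balanced_rating_durations:
        reps = -(-n_trials // len(RATING_SPLITS))
        splits = list(RATING_SPLITS) * reps
        rng.shuffle(splits)
        splits = splits[:n_trials]
    else:
        splits = [RATING_SPLITS[k] for k in
                  rng.integers(0, len(RATING_SPLITS), size=n_trials)]

    trials = []
    it = iter(seq)
    for pos in range(n_trials):
        onset = pos * TRIAL_SPAN
        r1, r2 = splits[pos]
        if pos in null_positions:
            trials.append(TrialEvent(
                run_index=run_index, trial_index=pos + 1, onset=onset,
                is_null=True, intention_level=None, intention_percent=0,
                value_level=None, value_amount=0, rating_order=rating_order,
                rating1_duration=r1, rating2_duration=r2))
        else:
            intent, value = next(it)
            lo, hi = INTENTION_PERCENT_RANGE[intent]
            pct = int(rng.integers(lo, hi + 1))
            lo, hi = VALUE_AMOUNT_RANGE[value]
            amt = int(rng.integers(lo, hi + 1))
            trials.append(TrialEvent(
                run_index=run_index, trial_index=pos + 1, onset=onset,
                is_null=False, intention_level=intent, intention_percent=pct,
                value_level=value, value_amount=amt, rating_order=rating_order,
                rating1_duration=r1, rating2_duration=r2))
    return RunSchedule(run_index=run_index, rating_order=rating_order,
                       trials=tuple(trials), tr=tr, n_volumes=n_volumes)


def generate_subject_design(subject_id: int, order_scheme: str, seed,
                            n_runs: int = N_RUNS, **run_kwargs) -> SubjectDesign:
    """Generate all runs for one subject.

    ``n_runs`` < 6 truncates the scheme (one real participant completed only
    four runs).
    """
    if order_scheme not in ORDER_SCHEMES:
        raise ValueError(f"unknown order scheme {order_scheme!r}")
    orders = ORDER_SCHEMES[order_scheme][:n_runs]
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    run_seeds = ss.spawn(len(orders))
    runs = tuple(
        generate_run_schedule(r + 1, orders[r], run_seeds[r], **run_kwargs)
        for r in range(len(orders)))
    return SubjectDesign(subject_id=subject_id, order_scheme=order_scheme,
                         runs=runs)


def generate_study(n_subjects: int = 30, seed=0, n_runs: int = N_RUNS,
                   incomplete_subject: int | None = None,
                   incomplete_n_runs: int = 4,
                   **run_kwargs) -> list[SubjectDesign]:
    """Generate a cohort; the two rating-order schemes alternate across
    subjects so they are evenly distributed."""
    schemes = list(ORDER_SCHEMES)
    subj_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    designs = []
    for s in range(1, n_subjects + 1):
        nr = incomplete_n_runs if s == incomplete_subject else n_runs
        designs.append(generate_subject_design(
            s, schemes[(s - 1) % 2], subj_seeds[s - 1], n_runs=nr,
            **run_kwargs))
    return designs


def validate_run_schedule(run: RunSchedule,
                          trials_per_cell: int = TRIALS_PER_CELL_PER_RUN,
                          n_null: int = N_NULL_PER_RUN) -> list[str]:
    """Independent re-check of every schedule constraint from raw fields.

    Returns a list of human-readable violations (empty when valid).  This
    deliberately recomputes everything from the trial records rather than
    trusting the generator.
    """
    problems = []
    n_expected = 9 * trials_per_cell + n_null
    if len(run.trials) != n_expected:
        problems.append(f"expected {n_expected} trials, got {len(run.trials)}")
    nulls = [t for t in run.trials if t.is_null]
    if len(nulls) != n_null:
        problems.append(f"expected {n_null} null trials, got {len(nulls)}")

    for t in run.trials:
        if abs(t.span - TRIAL_SPAN) > 1e-9:
            problems.append(f"trial {t.trial_index} span {t.span} != {TRIAL_SPAN}")
        if abs(t.stim_duration - STIM_DURATION) > 1e-9:
            problems.append(f"trial {t.trial_index} stim duration {t.stim_duration}")
        if abs(t.fixation_duration - FIXATION_DURATION) > 1e-9:
            problems.append(f"trial {t.trial_index} fixation {t.fixation_duration}")
        if (t.rating1_duration, t.rating2_duration) not in RATING_SPLITS:
            problems.append(
                f"trial {t.trial_index} rating split "
                f"({t.rating1_duration},{t.rating2_duration}) not admissible")
        if t.is_null:
            if t.intention_level is not None or t.value_level is not None:
                problems.append(f"null trial {t.trial_index} carries levels")
        else:
            lo, hi = INTENTION_PERCENT_RANGE[t.intention_level]
            if not lo <= t.intention_percent <= hi:
                problems.append(
                    f"trial {t.trial_index} percent {t.intention_percent} "
                    f"outside [{lo},{hi}] for {t.intention_level}")
            lo, hi = VALUE_AMOUNT_RANGE[t.value_level]
            if not lo <= t.value_amount <= hi:
                problems.append(
                    f"trial {t.trial_index} amount {t.value_amount} "
                    f"outside [{lo},{hi}] for {t.value_level}")

    for k, t in enumerate(run.trials):
        if abs(t.onset - k * TRIAL_SPAN) > 1e-9:
            problems.append(f"trial {t.trial_index} onset {t.onset} off grid")

    cond = run.condition_trials
    counts: dict[tuple[str, str], int] = {}
    for t in cond:
        counts[(t.intention_level, t.value_level)] = \
            counts.get((t.intention_level, t.value_level), 0) + 1
    for i, v in itertools.product(INTENTION_LEVELS, VALUE_LEVELS):
        if counts.get((i, v), 0) != trials_per_cell:
            problems.append(f"cell ({i},{v}) count {counts.get((i, v), 0)} "
                            f"!= {trials_per_cell}")

    for a, b in zip(cond, cond[1:]):
        if a.intention_level == b.intention_level:
            problems.append(
                f"consecutive condition trials {a.trial_index},{b.trial_index} "
                f"share intention {a.intention_level}")
        if a.value_level == b.value_level:
            problems.append(
                f"consecutive condition trials {a.trial_index},{b.trial_index} "
                f"share value {a.value_level}")

    last_offset = run.trials[-1].onset + run.trials[-1].span if run.trials else 0.0
    if run.n_volumes * run.tr < last_offset - 1e-9:
        problems.append(
            f"run too short: {run.n_volumes} x {run.tr} s < {last_offset} s")
    return problems


def validate_subject_design(design: SubjectDesign) -> list[str]:
    """Whole-subject validation: per-run checks plus the rating-order scheme
    and the per-subject cell balance (trials_per_cell x n_runs per cell)."""
    problems = []
    orders = ORDER_SCHEMES[design.order_scheme]
    for k, run in enumerate(design.runs):
        problems += [f"run {run.run_index}: {p}"
                     for p in validate_run_schedule(run)]
        if run.rating_order != orders[k]:
            problems.append(
                f"run {run.run_index} rating order {run.rating_order} "
                f"!= scheme {orders[k]}")
    counts: dict[tuple[str, str], int] = {}
    for run in design.runs:
        for t in run.condition_trials:
            counts[(t.intention_level, t.value_level)] = \
                counts.get((t.intention_level, t.value_level), 0) + 1
    per_cell = TRIALS_PER_CELL_PER_RUN * len(design.runs)
    for cell, c in counts.items():
        if c != per_cell:
            problems.append(f"subject cell {cell} count {c} != {per_cell}")
    return problems
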