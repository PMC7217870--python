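"""Synthetic ordinal emotion ratings.

Each non-null trial yields a gratitude and a joy rating on a 3-point scale
(weakly/moderately/strongly -> 1/2/3).  Ratings are produced by a latent
Gaussian model: a cell mean (grand mean + factor main effects + an
emotion-specific difference), a subject random intercept, and residual noise,
discretized at two cut-points.  The latent cell means are available in closed
form, which gives an analytic oracle for the empirical cell means as the
residual SD shrinks.

The default effect structure reproduces the qualitative behavioral pattern
the pipeline is built to detect: gratitude exceeds joy only when benefactor
intention is strong and benefit value is low or zero, on top of strong main
effects of both appraisal factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (EMOTIONS, INTENTION_CODE, INTENTION_LEVELS, VALUE_CODE,
                     VALUE_LEVELS, SubjectDesign, condition_name)

#: gratitude-minus-joy latent difference per (intention, value) cell;
#: rows strong/weak/no, columns high/low/zero
_DEFAULT_EMOTION_DIFF = np.array([
    [0.00, 0.24, 0.37],
    [0.00, 0.00, 0.00],
    [0.00, 0.00, 0.00],
])


@dataclass
class RatingEffectParams:
    """Effect structure of the latent rating model (1-3 rating scale).

    ``emotion_diff[i, v]`` is the gratitude-minus-joy latent mean difference
    in cell (intention i, value v); the emotion main effect and the
    emotion-by-factor interaction weights are its standard sum-to-zero
    decomposition, exposed as properties.
    """
    grand_mean: float = 1.95
    intention_main: np.ndarray = field(
        default_factory=lambda: np.array([0.45, -0.05, -0.40]))
    value_main: np.ndarray = field(
        default_factory=lambda: np.array([0.55, 0.00, -0.55]))
    emotion_diff: np.ndarray = field(
        default_factory=lambda: _DEFAULT_EMOTION_DIFF.copy())
    subject_sd: float = 0.20
    residual_sd: float = 0.50
    cutpoints: tuple[float, float] = (1.5, 2.5)
    nonresponse_rate: float = 0.02

    @property
    def emotion_main(self) -> float:
        """Gratitude-minus-joy difference averaged over all cells."""
        return float(np.mean(self.emotion_diff))

    @property
    def emotion_by_intention(self) -> np.ndarray:
        return self.emotion_diff.mean(axis=1) - self.emotion_main

    @property
    def emotion_by_value(self) -> np.ndarray:
        return self.emotion_diff.mean(axis=0) - self.emotion_main

    @property
    def three_way(self) -> np.ndarray:
        d = self.emotion_diff
        return (d - self.emotion_main
                - self.emotion_by_intention[:, None]
                - self.emotion_by_value[None, :])

    def latent_cell_means(self) -> np.ndarray:
        """Closed-form latent means, shape (2 emotions, 3 intentions, 3 values),
        emotion axis ordered (gratitude, joy)."""
        base = (self.grand_mean
                + np.asarray(self.intention_main)[:, None]
                + np.asarray(self.value_main)[None, :])
        half = np.asarray(self.emotion_diff) / 2.0
        return np.stack([base + half, base - half])

    def check(self) -> None:
        means = self.latent_cell_means()
        if means.min() < 1.0 - 1e-9 or means.max() > 3.0 + 1e-9:
            raise ValueError("latent cell means fall outside the 1-3 scale")
        if not 0.0 <= self.nonresponse_rate < 1.0:
            raise ValueError("nonresponse_rate must be in [0, 1)")
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("cutpoints must be increasing")


@dataclass(frozen=True)
class RatingRecord:
    subject_id: int
    run_index: int
    trial_index: int
    gratitude: int | None
    joy: int | None


def _discretize(latent: float, cutpoints: tuple[float, float]) -> int:
    if latent < cutpoints[0]:
        return 1
    if latent < cutpoints[1]:
        return 2
    return 3


def generate_ratings(design: SubjectDesign, params: RatingEffectParams,
                     seed) -> list[RatingRecord]:
    """Draw one gratitude and one joy rating for every non-null trial.

    The latent value is the closed-form cell mean plus a per-subject
    intercept (shared by both emotions) and i.i.d. residual noise per
    rating; each rating is independently missing with
    ``params.nonresponse_rate``.
    """
    params.check()
    rng = np.random.default_rng(seed)
    subj_intercept = rng.normal(0.0, params.subject_sd)
    means = params.latent_cell_means()
    i_idx = {lv: k for k, lv in enumerate(INTENTION_LEVELS)}
    v_idx = {lv: k for k, lv in enumerate(VALUE_LEVELS)}
    records = []
    for run in design.runs:
        for t in run.condition_trials:
            vals: dict[str, int | None] = {}
            for e_k, emotion in enumerate(EMOTIONS):
                if rng.random() < params.nonresponse_rate:
                    vals[emotion] = None
                    continue
                latent = (means[e_k, i_idx[t.intention_level],
                                v_idx[t.value_level]]
                          + subj_intercept
                          + rng.normal(0.0, params.residual_sd))
                vals[emotion] = _discretize(latent, params.cutpoints)
            records.append(RatingRecord(
                subject_id=design.subject_id, run_index=run.run_index,
                trial_index=t.trial_index, gratitude=vals["gratitude"],
                joy=vals["joy"]))
    return records


def generate_study_ratings(designs: list[SubjectDesign],
                           params: RatingEffectParams,
                           seed) -> list[RatingRecord]:
    seeds = np.random.SeedSequence(seed).spawn(len(designs))
    out: list[RatingRecord] = []
    for d, s in zip(designs, seeds):
        out.extend(generate_ratings(d, params, s))
    return out


def ratings_frame(designs: list[SubjectDesign],
                  records: list[RatingRecord]) -> pd.DataFrame:
    """Tidy trial table merging condition levels with ratings.

    Columns: subject, run, trial, intention, value, intention_percent,
    value_amount, gratitude, joy (NaN where missing).
    """
    trial_info = {}
    for d in designs:
        for run in d.runs:
            for t in run.condition_trials:
                trial_info[(d.subject_id, run.run_index, t.trial_index)] = t
    rows = []
    for r in records:
        t = trial_info[(r.subject_id, r.run_index, r.trial_index)]
        rows.append({
            "subject": r.subject_id, "run": r.run_index, "trial": r.trial_index,
            "intention": t.intention_level, "value": t.value_level,
            "intention_percent": t.intention_percent,
            "value_amount": t.value_amount,
            "gratitude": np.nan if r.gratitude is None else r.gratitude,
            "joy": np.nan if r.joy is None else r.joy,
        })
    return pd.DataFrame(rows)


def rating_lookup(records: list[RatingRecord]
                  ) -> dict[tuple[int, int, int], RatingRecord]:
    return {(r.subject_id, r.run_index, r.trial_index): r for r in records}
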