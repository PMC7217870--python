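"""First-level GLMs.

Two subject-level models are built from the rating-screen events:

* **Model 1** — one boxcar regressor per emotion x intention x value cell
  (18 condition regressors), HRF-convolved, plus unconvolved nuisance
  columns (run-constant rating-order indicator, six motion parameters) and
  per-run intercepts.
* **Model 2** — per emotion, an unmodulated rating-event regressor followed
  by four parametric modulators in a fixed order (emotion rating, intention
  linear, intention quadratic, value linear), each mean-centered and
  serially orthogonalized against the earlier ones before convolution, so
  that later modulators carry only unique variance.  Intention and value
  are coded 1/0/-1 for strong/weak/no and high/low/zero; the quadratic
  term is the square of the linear code (1/0/1) before centering.

Runs are concatenated into a single matrix with per-run intercepts.
Fitting is ordinary least squares per in-mask voxel; a rank-deficient
matrix falls back to the minimum-norm (pseudo-inverse) solution with a
warning.  Note the run-constant rating-order indicator is collinear with
the run intercepts by construction, so full Model 1/2 matrices take that
path; condition and modulator coefficients remain uniquely determined
because the deficiency lives entirely in the nuisance subspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import (EMOTIONS, INTENTION_CODE, VALUE_CODE, SubjectDesign,
                     condition_name, condition_names)
from .images import VoxelGrid, VoxelMap
from .ratings import RatingRecord, rating_lookup

MODULATOR_ORDER = ("emotion_rating", "intention_linear",
                   "intention_quadratic", "value_linear")


# --------------------------------------------------------------------------
# hemodynamic response
# --------------------------------------------------------------------------

def _gamma_pdf(t: np.ndarray, shape: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp((shape - 1) * np.log(t[pos]) - t[pos] - gammaln(shape))
    return out


def canonical_hrf(tr: float, oversampling: int = 16,
                  time_length: float = 32.0) -> np.ndarray:
    """Double-gamma canonical hemodynamic response.

    Positive lobe peaking near 5 s, undershoot near 15-16 s, normalized to
    unit peak, sampled on the oversampled grid dt = tr / oversampling used
    for convolution.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0, time_length, dt)
    h = _gamma_pdf(t, 6.0) - _gamma_pdf(t, 16.0) / 6.0
    return h / h.max()


def _convolve_events(onsets, durations, amplitudes, n_volumes: int, tr: float,
                     oversampling: int, kernel: np.ndarray) -> np.ndarray:
    """Boxcar events -> HRF-convolved regressor sampled at volume onsets."""
    dt = tr / oversampling
    n_fine = n_volumes * oversampling
    fine = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        fine[max(a, 0):min(b, n_fine)] += amp
    conv = np.convolve(fine, kernel)[:n_fine]
    return conv[::oversampling]


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

def rating_events(design: SubjectDesign,
                  records: list[RatingRecord] | None = None,
                  drop_missing: bool = True) -> pd.DataFrame:
    """One row per rating-screen event of every non-null trial.

    Columns: run, trial, emotion, onset, duration, intention, value,
    rating (NaN when unavailable), rating_order.  When ``records`` are
    given and ``drop_missing`` is set, trials where either rating is
    missing are removed entirely (both emotions), matching the behavioral
    exclusion rule.
    """
    lookup = rating_lookup(records) if records is not None else {}
    rows = []
    for run in design.runs:
        for t in run.condition_trials:
            rec = lookup.get((design.subject_id, run.run_index, t.trial_index))
            g = rec.gratitude if rec else None
            j = rec.joy if rec else None
            if drop_missing and records is not None and (g is None or j is None):
                continue
            for emotion, rating in (("gratitude", g), ("joy", j)):
                rows.append({
                    "run": run.run_index, "trial": t.trial_index,
                    "emotion": emotion, "onset": t.rating_onset(emotion),
                    "duration": t.rating_duration(emotion),
                    "intention": t.intention_level, "value": t.value_level,
                    "rating": np.nan if rating is None else float(rating),
                    "rating_order": run.rating_order,
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list[str]
    tr: float
    run_volumes: list[int]
    modulator_order: tuple[str, ...] = ()
    orthogonalized: bool = False
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names do not match matrix columns")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def _nuisance_columns(design: SubjectDesign, motion, include_rating_order):
    """Run-constant rating-order indicator (+1 gratitude first, -1 joy
    first) and per-run-centered motion columns, stacked across runs."""
    cols, names = [], []
    if include_rating_order:
        order = np.concatenate([
            np.full(run.n_volumes,
                    1.0 if run.rating_order == "gratitude_first" else -1.0)
            for run in design.runs])
        cols.append(order)
        names.append("rating_order")
    if motion is not None:
        if len(motion) != len(design.runs):
            raise ValueError("one motion array per run required")
        centered = [np.asarray(m, float) - np.asarray(m, float).mean(axis=0)
                    for m in motion]
        mot = np.concatenate(centered, axis=0)
        for k in range(mot.shape[1]):
            cols.append(mot[:, k])
            names.append(f"motion_{k + 1}")
    return cols, names


def _intercept_columns(design: SubjectDesign):
    total = sum(run.n_volumes for run in design.runs)
    cols, names = [], []
    start = 0
    for run in design.runs:
        c = np.zeros(total)
        c[start:start + run.n_volumes] = 1.0
        cols.append(c)
        names.append(f"intercept_run{run.run_index}")
        start += run.n_volumes
    return cols, names


def build_model1(design: SubjectDesign,
                 records: list[RatingRecord] | None = None,
                 motion=None, include_rating_order: bool = True,
                 include_run_intercepts: bool = True,
                 oversampling: int = 16,
                 drop_missing: bool = True) -> DesignMatrix:
    """Model 1: 18 condition regressors (rating events labeled by cell and
    emotion) plus nuisance columns and run intercepts."""
    events = rating_events(design, records, drop_missing=drop_missing)
    tr = design.runs[0].tr
    kernel = canonical_hrf(tr, oversampling)
    cond_names = condition_names()
    cols = {name: [] for name in cond_names}
    for run in design.runs:
        ev = events[events["run"] == run.run_index]
        for name in cond_names:
            emotion, intention, value = name.split("_")
            sel = ev[(ev["emotion"] == emotion)
                     & (ev["intention"] == intention)
                     & (ev["value"] == value)]
            cols[name].append(_convolve_events(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                np.ones(len(sel)), run.n_volumes, tr, oversampling, kernel))
    matrix_cols = [np.concatenate(cols[name]) for name in cond_names]
    names = list(cond_names)
    empty = [n for n, c in zip(names, matrix_cols) if not np.any(c)]
    if empty:
        warnings.warn(f"conditions with no events dropped: {empty}")
        keep = [k for k, n in enumerate(names) if n not in empty]
        matrix_cols = [matrix_cols[k] for k in keep]
        names = [names[k] for k in keep]

    ncols, nnames = _nuisance_columns(design, motion, include_rating_order)
    matrix_cols += ncols
    names += nnames
    if include_run_intercepts:
        icols, inames = _intercept_columns(design)
        matrix_cols += icols
        names += inames
    return DesignMatrix(
        matrix=np.column_stack(matrix_cols), names=names, tr=tr,
        run_volumes=[r.n_volumes for r in design.runs], dropped=empty)


def modulator_values(events: pd.DataFrame) -> np.ndarray:
    """Raw (uncentered) modulator values per event, columns in
    MODULATOR_ORDER: recorded rating, intention 1/0/-1, its square, value
    1/0/-1."""
    intent = events["intention"].map(INTENTION_CODE).to_numpy(float)
    value = events["value"].map(VALUE_CODE).to_numpy(float)
    rating = events["rating"].to_numpy(float)
    return np.column_stack([rating, intent, intent ** 2, value])


def serially_orthogonalize(values: np.ndarray,
                           tol: float = 1e-12) -> np.ndarray:
    """Mean-center each column, then residualize column k against columns
    1..k-1 (already orthogonalized) in order.

    Centering is the residualization against the unmodulated onset column
    (a constant over events).  Columns that become numerically zero are
    left as zeros; the caller decides whether to drop them.
    """
    v = np.asarray(values, dtype=float).copy()
    v -= v.mean(axis=0, keepdims=True)
    for k in range(v.shape[1]):
        for j in range(k):
            denom = v[:, j] @ v[:, j]
            if denom > tol:
                v[:, k] -= (v[:, k] @ v[:, j]) / denom * v[:, j]
        if np.linalg.norm(v[:, k]) < np.sqrt(tol):
            v[:, k] = 0.0
    return v


def build_model2(design: SubjectDesign, records: list[RatingRecord],
                 motion=None, include_rating_order: bool = True,
                 include_run_intercepts: bool = True,
                 oversampling: int = 16,
                 orthogonalize: bool = True) -> DesignMatrix:
    """Model 2: per emotion an unmodulated rating-event regressor plus the
    four serially orthogonalized parametric modulators; nuisance columns as
    in Model 1.  Trials with either rating missing are dropped."""
    events = rating_events(design, records, drop_missing=True)
    tr = design.runs[0].tr
    kernel = canonical_hrf(tr, oversampling)
    matrix_cols, names, dropped = [], [], []

    for emotion in EMOTIONS:
        ev = events[events["emotion"] == emotion].sort_values(["run", "onset"])
        raw = modulator_values(ev)
        mods = serially_orthogonalize(raw) if orthogonalize \
            else raw - raw.mean(axis=0, keepdims=True)
        keep = []
        for k, mname in enumerate(MODULATOR_ORDER):
            if not np.any(mods[:, k]):
                dropped.append(f"{emotion}_x_{mname}")
                warnings.warn(
                    f"constant modulator {mname} for {emotion} dropped")
            else:
                keep.append(k)

        onset_col, mod_cols = [], {k: [] for k in keep}
        for run in design.runs:
            in_run = (ev["run"] == run.run_index).to_numpy()
            onsets = ev["onset"].to_numpy()[in_run]
            durs = ev["duration"].to_numpy()[in_run]
            onset_col.append(_convolve_events(
                onsets, durs, np.ones(in_run.sum()), run.n_volumes, tr,
                oversampling, kernel))
            for k in keep:
                mod_cols[k].append(_convolve_events(
                    onsets, durs, mods[in_run, k], run.n_volumes, tr,
                    oversampling, kernel))
        matrix_cols.append(np.concatenate(onset_col))
        names.append(f"{emotion}_onset")
        for k in keep:
            matrix_cols.append(np.concatenate(mod_cols[k]))
            names.append(f"{emotion}_x_{MODULATOR_ORDER[k]}")

    ncols, nnames = _nuisance_columns(design, motion, include_rating_order)
    matrix_cols += ncols
    names += nnames
    if include_run_intercepts:
        icols, inames = _intercept_columns(design)
        matrix_cols += icols
        names += inames
    return DesignMatrix(
        matrix=np.column_stack(matrix_cols), names=names, tr=tr,
        run_volumes=[r.n_volumes for r in design.runs],
        modulator_order=MODULATOR_ORDER, orthogonalized=orthogonalize,
        dropped=dropped)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class GlmFit:
    betas: np.ndarray           # (n_regressors, n_in_mask_voxels)
    names: list[str]
    residuals: np.ndarray       # (n_timepoints, n_in_mask_voxels)
    sigma2: np.ndarray          # (n_in_mask_voxels,)
    df: int
    mask: np.ndarray
    grid: VoxelGrid

    def beta_map(self, name: str) -> VoxelMap:
        data = np.full(self.grid.shape, np.nan)
        data[self.mask] = self.betas[self.names.index(name)]
        return VoxelMap(data=data, grid=self.grid, mask=self.mask)

    def residual_volumes(self) -> np.ndarray:
        out = np.zeros(self.grid.shape + (self.residuals.shape[0],))
        out[self.mask] = self.residuals.T
        return out


def fit_glm(bold, X: DesignMatrix, mask) -> GlmFit:
    """Ordinary least squares per in-mask voxel.

    ``bold`` may be a 4D array (x, y, z, t) or a list of per-run 4D arrays
    (concatenated along time in run order to match the design matrix).
    """
    if isinstance(bold, (list, tuple)):
        bold = np.concatenate(list(bold), axis=3)
    bold = np.asarray(bold, dtype=float)
    if isinstance(mask, VoxelMap):
        grid, mask_arr = mask.grid, mask.data.astype(bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        grid = VoxelGrid(mask_arr.shape)
    if bold.shape[:3] != tuple(grid.shape):
        raise ValueError("bold and mask grids differ")
    if bold.shape[3] != X.n_timepoints:
        raise ValueError(
            f"bold has {bold.shape[3]} volumes, design {X.n_timepoints}")

    Y = bold[mask_arr].T                      # (T, V)
    rank = int(np.linalg.matrix_rank(X.matrix))
    if rank < X.matrix.shape[1]:
        warnings.warn("rank-deficient design matrix; "
                      "using minimum-norm least squares")
    B, *_ = np.linalg.lstsq(X.matrix, Y, rcond=None)
    resid = Y - X.matrix @ B
    df = X.n_timepoints - rank
    sigma2 = (resid ** 2).sum(axis=0) / max(df, 1)
    return GlmFit(betas=B, names=list(X.names), residuals=resid,
                  sigma2=sigma2, df=df, mask=mask_arr, grid=grid)


def contrast_image(fit: GlmFit, weights) -> VoxelMap:
    """Weighted sum of beta maps.

    ``weights`` is either a full-length vector over regressors or a dict
    mapping regressor names to weights (unnamed regressors get 0).
    """
    if isinstance(weights, dict):
        unknown = set(weights) - set(fit.names)
        if unknown:
            raise ValueError(f"unknown regressors in contrast: {sorted(unknown)}")
        w = np.array([weights.get(n, 0.0) for n in fit.names])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != len(fit.names):
            raise ValueError("weight vector length mismatch")
    values = w @ fit.betas
    data = np.full(fit.grid.shape, np.nan)
    data[fit.mask] = values
    return VoxelMap(data=data, grid=fit.grid, mask=fit.mask)
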