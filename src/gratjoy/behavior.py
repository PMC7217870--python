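"""Behavioral analysis: cell means, fully within-subject factorial ANOVA,
and planned paired comparisons.

The ANOVA uses the classical fully-within decomposition for a complete
subject x cell table of cell means: the sum of squares of every effect is
obtained by inclusion-exclusion of marginal means, and each effect is
tested against its effect-by-subject interaction mean square, so for a
3-level factor with 30 subjects the test has (2, 58) degrees of freedom.
Partial eta squared is SS_effect / (SS_effect + SS_error).  No sphericity
correction is applied by default; Greenhouse-Geisser adjusted p-values are
available as an option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def subject_cell_means(ratings: pd.DataFrame,
                       drop_incomplete_subjects: bool = False
                       ) -> pd.DataFrame:
    """Per-subject mean rating per (emotion, intention, value) cell.

    ``ratings`` is the tidy trial table (columns subject, intention, value,
    gratitude, joy).  Trials where either rating is missing are excluded
    from both emotions' aggregation before averaging.  Cells with no
    surviving trials are flagged (``n_trials`` 0, mean NaN); subjects with
    any empty cell can optionally be dropped.
    """
    complete = ratings.dropna(subset=["gratitude", "joy"])
    long = complete.melt(
        id_vars=["subject", "intention", "value"],
        value_vars=["gratitude", "joy"], var_name="emotion",
        value_name="rating")
    grouped = (long.groupby(["subject", "emotion", "intention", "value"])
               ["rating"].agg(["mean", "count"])
               .rename(columns={"count": "n_trials"}))

    subjects = sorted(ratings["subject"].unique())
    full_index = pd.MultiIndex.from_product(
        [subjects, sorted(long["emotion"].unique()),
         sorted(long["intention"].unique()), sorted(long["value"].unique())],
        names=["subject", "emotion", "intention", "value"])
    out = grouped.reindex(full_index).reset_index()
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    out["empty"] = out["n_trials"] == 0
    if drop_incomplete_subjects:
        bad = out.loc[out["empty"], "subject"].unique()
        out = out[~out["subject"].isin(bad)].reset_index(drop=True)
    return out


def _pivot_complete(data: pd.DataFrame, dv: str, within: list[str],
                    subject: str) -> tuple[np.ndarray, list[list]]:
    levels = [list(pd.unique(data[f])) for f in within]
    subjects = list(pd.unique(data[subject]))
    shape = (len(subjects),) + tuple(len(lv) for lv in levels)
    arr = np.full(shape, np.nan)
    s_idx = {s: k for k, s in enumerate(subjects)}
    l_idx = [{lv: k for k, lv in enumerate(lvs)} for lvs in levels]
    for _, row in data.iterrows():
        idx = (s_idx[row[subject]],) + tuple(
            l_idx[f][row[within[f]]] for f in range(len(within)))
        if not np.isnan(arr[idx]):
            raise ValueError("duplicate observation for a subject x cell; "
                             "aggregate to cell means first")
        arr[idx] = row[dv]
    if np.isnan(arr).any():
        raise ValueError("incomplete subject x cell table")
    return arr, levels


def _deviation(arr: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion deviation for the margin spanned by ``axes``
    (broadcast to the full array shape)."""
    all_axes = tuple(range(arr.ndim))
    dev = np.zeros_like(arr)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            collapse = tuple(a for a in all_axes if a not in sub)
            m = arr.mean(axis=collapse, keepdims=True)
            dev = dev + ((-1) ** (len(axes) - r)) * m
    return dev


def _gg_epsilon(arr: np.ndarray, factor_axes: tuple[int, ...],
                levels: list[list]) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by
    ``factor_axes``, from the covariance of orthonormal contrast scores."""
    keep = (0,) + factor_axes
    collapse = tuple(a for a in range(arr.ndim) if a not in keep)
    y = arr.mean(axis=collapse) if collapse else arr
    n = y.shape[0]
    y = y.reshape(n, -1)
    basis = np.ones((1, 1))
    for a in factor_axes:
        l = len(levels[a - 1])
        q, _ = np.linalg.qr(np.eye(l) - 1.0 / l)
        basis = np.kron(basis, q[:, :l - 1])
    z = y @ basis
    sigma = np.cov(z, rowvar=False)
    sigma = np.atleast_2d(sigma)
    df = sigma.shape[0]
    eps = np.trace(sigma) ** 2 / (df * np.trace(sigma @ sigma))
    return float(np.clip(eps, 1.0 / df, 1.0))


def rm_anova(data: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject",
             greenhouse_geisser: bool = False) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA on a complete cell-mean table.

    Returns one row per effect (every main effect and interaction of the
    ``within`` factors) with F, numerator/denominator df, p, partial eta
    squared and the underlying sums of squares.  With
    ``greenhouse_geisser``, adds the epsilon and the adjusted p.
    """
    arr, levels = _pivot_complete(data, dv, within, subject)
    n_subj = arr.shape[0]
    factor_axes = tuple(range(1, len(within) + 1))

    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(factor_axes, r):
            dev = _deviation(arr, combo)
            ss = float((dev ** 2).sum())
            dev_err = _deviation(arr, (0,) + combo)
            ss_err = float((dev_err ** 2).sum())
            df1 = int(np.prod([len(levels[a - 1]) - 1 for a in combo]))
            df2 = df1 * (n_subj - 1)
            ms, ms_err = ss / df1, ss_err / df2
            f = ms / ms_err if ms_err > 0 else np.inf
            row = {
                "effect": " x ".join(within[a - 1] for a in combo),
                "F": f, "df1": df1, "df2": df2,
                "p": float(stats.f.sf(f, df1, df2)),
                "partial_eta_sq": ss / (ss + ss_err) if ss + ss_err > 0 else np.nan,
                "SS": ss, "SS_error": ss_err,
            }
            if greenhouse_geisser:
                eps = _gg_epsilon(arr, combo, levels)
                row["gg_epsilon"] = eps
                row["p_gg"] = float(stats.f.sf(f, df1 * eps, df2 * eps))
            rows.append(row)
    return pd.DataFrame(rows)


def decomposition_ss(data: pd.DataFrame, dv: str, within: list[str],
                     subject: str = "subject") -> dict[str, float]:
    """Every SS component of the within-subject decomposition (including
    the subject term and all error strata), plus the corrected total.
    The components sum exactly to the total on any complete table."""
    arr, _ = _pivot_complete(data, dv, within, subject)
    all_axes = tuple(range(arr.ndim))
    out = {}
    for r in range(1, arr.ndim + 1):
        for combo in itertools.combinations(all_axes, r):
            name = ":".join("subject" if a == 0 else within[a - 1]
                            for a in combo)
            out[name] = float((_deviation(arr, combo) ** 2).sum())
    out["total"] = float(((arr - arr.mean()) ** 2).sum())
    return out


@dataclass(frozen=True)
class PairedResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


def _match(cell_means: pd.DataFrame, cells) -> pd.DataFrame:
    sel = np.zeros(len(cell_means), dtype=bool)
    for cell in cells:
        m = np.ones(len(cell_means), dtype=bool)
        for key, val in cell.items():
            m &= (cell_means[key] == val).to_numpy()
        sel |= m
    return cell_means[sel]


def paired_comparison(cell_means: pd.DataFrame, cells_a, cells_b) -> PairedResult:
    """Paired t-test between two cell sets, averaged within subject first.

    ``cells_a`` / ``cells_b`` are lists of dicts over any of
    emotion/intention/value; each subject's matching cell means are
    averaged before the classical paired t with df = n - 1.
    """
    a = _match(cell_means, cells_a).groupby("subject")["mean"].mean()
    b = _match(cell_means, cells_b).groupby("subject")["mean"].mean()
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("paired comparison needs at least 2 subjects")
    diff = (a.loc[common] - b.loc[common]).to_numpy()
    n = len(diff)
    t, p = stats.ttest_rel(a.loc[common], b.loc[common])
    return PairedResult(t=float(t), df=n - 1, p=float(p),
                        mean_diff=float(diff.mean()), n=n)


def collapsed_emotion_comparisons(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Gratitude-vs-joy paired tests in the four collapsed cells obtained
    by averaging low with zero value and weak with no intention."""
    collapsed = {"strong": ["strong"], "weak/no": ["weak", "no"]}
    values = {"high": ["high"], "low/zero": ["low", "zero"]}
    rows = []
    for i_name, i_levels in collapsed.items():
        for v_name, v_levels in values.items():
            cells_g = [{"emotion": "gratitude", "intention": i, "value": v}
                       for i in i_levels for v in v_levels]
            cells_j = [{"emotion": "joy", "intention": i, "value": v}
                       for i in i_levels for v in v_levels]
            res = paired_comparison(cell_means, cells_g, cells_j)
            rows.append({"intention": i_name, "value": v_name,
                         "t": res.t, "df": res.df, "p": res.p,
                         "mean_diff": res.mean_diff})
    return pd.DataFrame(rows)
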