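"""Leave-one-participant-out decoding of gratitude vs joy from
modulation-slope beta maps.

Each subject contributes one unsmoothed beta map per emotion; in-mask
voxels are the features.  Every fold holds out both samples of one
subject, then — on the training set only — min-max scales each feature to
[0, 1], retains features whose gratitude-minus-joy paired t across the
training subjects has p < 0.05, and trains a linear SVM (C = 1).  Accuracy
is the fraction of the 2n held-out predictions that are correct;
specificity and sensitivity are the fractions of gratitude and joy samples
correctly classified.  Chance is assessed by rerunning the whole
cross-validation under permuted labels; localization uses the mean
absolute SVM weight of features selected in every fold, reported as
clusters of at least 5 voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.svm import SVC

from .images import VoxelGrid, VoxelMap

GRATITUDE, JOY = 1, -1
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class FeatureMatrix:
    X: np.ndarray                # (n_samples, n_features)
    labels: np.ndarray           # +1 gratitude, -1 joy
    subjects: np.ndarray         # subject id per sample
    voxel_index: np.ndarray      # (n_features, 3) grid coordinates
    grid: VoxelGrid
    mask: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subjects))


def assemble_features(beta_maps_g: dict, beta_maps_j: dict,
                      mask) -> FeatureMatrix:
    """Stack per-subject gratitude and joy beta maps into samples x
    in-mask-voxel features (deterministic C-order voxel ordering)."""
    if isinstance(mask, VoxelMap):
        grid, mask_arr = mask.grid, mask.data.astype(bool)
    else:
        mask_arr = np.asarray(mask, bool)
        grid = VoxelGrid(mask_arr.shape)
    subjects = sorted(beta_maps_g)
    missing = [s for s in subjects if s not in beta_maps_j] + \
              [s for s in beta_maps_j if s not in beta_maps_g]
    if missing:
        raise ValueError(f"subjects missing a map: {sorted(set(missing))}")
    rows, labels, subj = [], [], []
    for s in subjects:
        for m, lab in ((beta_maps_g[s], GRATITUDE), (beta_maps_j[s], JOY)):
            if tuple(m.grid.shape) != tuple(grid.shape):
                raise ValueError(f"subject {s}: map grid mismatch")
            rows.append(m.data[mask_arr])
            labels.append(lab)
            subj.append(s)
    return FeatureMatrix(
        X=np.asarray(rows, float), labels=np.asarray(labels),
        subjects=np.asarray(subj), voxel_index=np.argwhere(mask_arr),
        grid=grid, mask=mask_arr)


# --------------------------------------------------------------------------
# fold-wise building blocks
# --------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    min_: np.ndarray
    range_: np.ndarray
    zero_range: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        safe = np.where(self.zero_range, 1.0, self.range_)
        out = (X - self.min_) / safe
        out[:, self.zero_range] = 0.0
        return out


def scale_features(train: np.ndarray, test: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    """Per-feature min-max scaling fit on the training set and applied
    unchanged to the test set (test values may leave [0, 1]); zero-range
    features map to 0 and are flagged."""
    mn = train.min(axis=0)
    rg = train.max(axis=0) - mn
    scaler = FeatureScaler(min_=mn, range_=rg, zero_range=rg == 0)
    return scaler.transform(train), scaler.transform(test), scaler


def select_features(train: np.ndarray, subjects: np.ndarray,
                    labels: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Paired two-tailed t-test per feature across the training subjects'
    gratitude-minus-joy differences; keep p < alpha.  Features constant
    over the whole training set are dropped beforehand (their paired
    statistic is undefined)."""
    uniq, counts = np.unique(subjects, return_counts=True)
    if np.all(counts == 2):
        # fast path: sort each subject's pair adjacent, gratitude first
        order = np.lexsort((-labels, subjects))
        xo, lo = train[order], labels[order]
        # pairs are intact (one sample per label) only when the sorted
        # labels read (gratitude, joy); permuted labelings may break some
        # pairs, which then drop out of the test
        intact = (lo[0::2] == GRATITUDE) & (lo[1::2] == JOY)
        diffs = xo[0::2][intact] - xo[1::2][intact]
    else:
        rows = []
        for s in uniq:
            g = train[(subjects == s) & (labels == GRATITUDE)]
            j = train[(subjects == s) & (labels == JOY)]
            if len(g) == 1 and len(j) == 1:
                rows.append(g[0] - j[0])
        diffs = np.asarray(rows)
    if len(diffs) < 2:
        raise ValueError("feature selection needs at least 2 intact "
                         "training pairs")
    constant = np.ptp(train, axis=0) == 0
    n = len(diffs)
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    keep = np.zeros(train.shape[1], bool)
    finite = np.isfinite(t)
    keep[finite] = p[finite] < alpha
    # zero-variance nonzero-mean differences are infinitely significant
    keep[~finite & (sd == 0) & (mean != 0)] = True
    keep[constant] = False
    return keep


def train_linear_classifier(train: np.ndarray, labels: np.ndarray,
                            C: float = 1.0) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM; weights oriented so positive decision
    values mean gratitude."""
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(kernel="linear", C=C)
    clf.fit(train, labels)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    if clf.classes_[1] != GRATITUDE:   # orient toward gratitude
        w, b = -w, -b
    return w, b


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class FoldResult:
    held_out: object
    selected: np.ndarray         # boolean over all features
    scaler: FeatureScaler
    weights: np.ndarray          # over selected features
    bias: float
    decision: np.ndarray         # decision values for the 2 held-out samples
    true_labels: np.ndarray
    predictions: np.ndarray
    empty_selection: bool = False


@dataclass
class CVResult:
    folds: list[FoldResult]
    accuracy: float
    specificity: float
    sensitivity: float
    n_subjects: int
    permutation_p: float | None = None
    n_permutations: int | None = None


def _run_fold(features: FeatureMatrix, labels: np.ndarray, subject,
              C: float, alpha: float) -> FoldResult:
    test_idx = features.subjects == subject
    train_idx = ~test_idx
    Xtr, Xte = features.X[train_idx], features.X[test_idx]
    ytr = labels[train_idx]
    Xtr, Xte, scaler = scale_features(Xtr, Xte)
    try:
        selected = select_features(Xtr, features.subjects[train_idx], ytr,
                                   alpha=alpha)
    except ValueError:
        # a permuted labeling can leave too few intact pairs to test
        selected = np.zeros(Xtr.shape[1], bool)
    if len(np.unique(ytr)) < 2:
        selected = np.zeros_like(selected)  # degenerate single-class training
    empty = not selected.any()
    if empty:
        w = np.zeros(0)
        b = 0.0
        decision = np.zeros(Xte.shape[0])
    else:
        w, b = train_linear_classifier(Xtr[:, selected], ytr, C=C)
        decision = Xte[:, selected] @ w + b
    # decision value exactly 0 predicts gratitude (deterministic tie-break)
    predictions = np.where(decision >= 0, GRATITUDE, JOY)
    return FoldResult(held_out=subject, selected=selected, scaler=scaler,
                      weights=w, bias=b, decision=decision,
                      true_labels=labels[test_idx], predictions=predictions,
                      empty_selection=empty)


def _aggregate(folds: list[FoldResult], n_subjects: int) -> CVResult:
    truth = np.concatenate([f.true_labels for f in folds])
    pred = np.concatenate([f.predictions for f in folds])
    correct = pred == truth
    g = truth == GRATITUDE
    return CVResult(
        folds=folds, accuracy=float(correct.mean()),
        specificity=float(correct[g].mean()),
        sensitivity=float(correct[~g].mean()),
        n_subjects=n_subjects)


def run_lopo_cv(features: FeatureMatrix, C: float = 1.0,
                alpha: float = 0.05,
                labels: np.ndarray | None = None) -> CVResult:
    """Leave-one-participant-out cross-validation.

    Every fold removes one subject's two samples, then scales, selects and
    trains on the remaining subjects only.  ``labels`` overrides the
    stored sample labels (used by the permutation test).
    """
    if features.n_subjects < 3:
        raise ValueError("LOPO-CV needs at least 3 subjects")
    labels = features.labels if labels is None else np.asarray(labels)
    folds = [_run_fold(features, labels, s, C, alpha)
             for s in np.unique(features.subjects)]
    if any(f.empty_selection for f in folds):
        warnings.warn("some folds selected no features; "
                      "their predictions fall back to the tie-break")
    return _aggregate(folds, features.n_subjects)


# --------------------------------------------------------------------------
# permutation inference
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    p: float
    observed: float
    null_accuracies: np.ndarray
    n_permutations: int
    scheme: str


def _permute_labels(labels, subjects, rng, scheme: str) -> np.ndarray:
    lab = np.asarray(labels).copy()
    if scheme == "global":
        rng.shuffle(lab)
    elif scheme == "within_subject":
        for s in np.unique(subjects):
            idx = np.flatnonzero(subjects == s)
            if rng.random() < 0.5:
                lab[idx] = lab[idx][::-1]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return lab


def permutation_test(features: FeatureMatrix,
                     observed_accuracy: float | None = None,
                     n_perm: int = 1000, seed=0, C: float = 1.0,
                     alpha: float = 0.05, scheme: str = "global",
                     conservative: bool = False,
                     training_only: bool = False) -> PermutationResult:
    """Permutation null for the cross-validated accuracy.

    By default every permutation relabels the whole sample set and reruns
    the complete cross-validation (including per-fold scaling and
    selection); ``scheme='within_subject'`` flips each subject's pair
    instead, and ``training_only`` relabels only the training samples of
    each fold (leaving test labels intact).  The p-value is the fraction
    of permutations whose accuracy strictly exceeds the observed one; the
    safeguarded (count + 1) / (n + 1) variant counts ties as exceedances.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if observed_accuracy is None:
        observed_accuracy = run_lopo_cv(features, C=C, alpha=alpha).accuracy
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = _permute_labels(features.labels, features.subjects, rng, scheme)
        if training_only:
            folds = []
            for s in np.unique(features.subjects):
                lab = perm.copy()
                test = features.subjects == s
                lab[test] = features.labels[test]
                folds.append(_run_fold(features, lab, s, C, alpha))
            null[k] = _aggregate(folds, features.n_subjects).accuracy
        else:
            null[k] = run_lopo_cv(features, C=C, alpha=alpha,
                                  labels=perm).accuracy
    if conservative:
        p = (np.sum(null >= observed_accuracy) + 1) / (n_perm + 1)
    else:
        p = np.sum(null > observed_accuracy) / n_perm
    return PermutationResult(p=float(p), observed=float(observed_accuracy),
                             null_accuracies=null, n_permutations=n_perm,
                             scheme=scheme)


# --------------------------------------------------------------------------
# weight localization
# --------------------------------------------------------------------------

@dataclass
class WeightMap:
    map: VoxelMap
    consensus: np.ndarray        # boolean over features
    clusters: pd.DataFrame


def consensus_weight_map(folds: list[FoldResult], grid: VoxelGrid,
                         voxel_index: np.ndarray, mask: np.ndarray,
                         min_cluster: int = 5,
                         connectivity: int = 26) -> WeightMap:
    """Mean absolute SVM weight over features selected in *every* fold,
    mapped back to the voxel grid; clusters below ``min_cluster`` voxels
    are omitted from the table."""
    consensus = np.logical_and.reduce([f.selected for f in folds])
    if not consensus.any():
        warnings.warn("no feature was selected in every fold")
    n_feat = consensus.size
    acc = np.zeros(n_feat)
    for f in folds:
        w_full = np.zeros(n_feat)
        w_full[f.selected] = np.abs(f.weights)
        acc += w_full
    mean_abs = np.where(consensus, acc / len(folds), 0.0)

    data = np.zeros(grid.shape)
    for value, (i, j, k) in zip(mean_abs, voxel_index):
        data[i, j, k] = value
    vmap = VoxelMap(data, grid, mask)

    present = data > 0
    labels, n = ndimage.label(present, structure=_STRUCTURES[connectivity])
    rows = []
    for lab in range(1, n + 1):
        voxels = labels == lab
        size = int(voxels.sum())
        if size < min_cluster:
            continue
        win = np.where(voxels, data, -np.inf)
        peak = np.unravel_index(np.argmax(win), data.shape)
        rows.append({"size": size, "peak_i": int(peak[0]),
                     "peak_j": int(peak[1]), "peak_k": int(peak[2]),
                     "peak_w": float(data[peak]),
                     "mean_w": float(data[voxels].mean())})
    clusters = pd.DataFrame(
        rows, columns=["size", "peak_i", "peak_j", "peak_k", "peak_w",
                       "mean_w"]).sort_values(
        "peak_w", ascending=False).reset_index(drop=True)
    return WeightMap(map=vmap, consensus=consensus, clusters=clusters)
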