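"""Group-level inference: interaction contrasts, one-sample / paired t
maps, and Monte-Carlo cluster-extent family-wise error correction.

The cluster correction simulates smooth Gaussian null fields on the
analysis mask (white noise, Gaussian smoothing at the estimated or
supplied FWHM, renormalized to unit variance), thresholds them at the
voxelwise p, and records the maximum suprathreshold cluster size per
simulation; the critical size is the smallest extent whose null
probability of occurring anywhere in the mask is at most 0.05.  A primary
tier (voxel p < 0.001) marks significant clusters; a lenient tier (voxel
p < 0.005) marks trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import EMOTIONS, INTENTION_LEVELS, VALUE_LEVELS, condition_name
from .images import VoxelGrid, VoxelMap

Z_CAP = 10.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# --------------------------------------------------------------------------
# contrasts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSpec:
    name: str
    weights: dict

    def vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.weights.get(n, 0.0) for n in names])


#: per-level weights of each printed interaction formula; each level's
#: weight is spread evenly over the collapsed factor's three cells
_INTENTION_W = {"strong": 1.0, "weak": -0.5, "no": -0.5}
_VALUE_W = {"high": -1.0, "low": 0.5, "zero": 0.5}
_THREE_WAY_W = {
    ("strong", "high"): -1.0, ("strong", "low"): 0.5, ("strong", "zero"): 0.5,
    ("weak", "high"): 0.5, ("weak", "low"): -0.25, ("weak", "zero"): -0.25,
    ("no", "high"): 0.5, ("no", "low"): -0.25, ("no", "zero"): -0.25,
}

CONTRAST_KINDS = ("gratitude_vs_joy", "emotion_by_intention",
                  "emotion_by_value", "three_way")


def build_interaction_contrast(kind: str) -> ContrastSpec:
    """Weight vector over the 18 condition regressors for the group
    contrasts; gratitude-block weights are the negation of the joy block."""
    if kind not in CONTRAST_KINDS:
        raise ValueError(f"unknown contrast kind {kind!r}")
    weights = {}
    for intention in INTENTION_LEVELS:
        for value in VALUE_LEVELS:
            if kind == "gratitude_vs_joy":
                w = 1.0 / 9.0
            elif kind == "emotion_by_intention":
                w = _INTENTION_W[intention] / 3.0
            elif kind == "emotion_by_value":
                w = _VALUE_W[value] / 3.0
            else:
                w = _THREE_WAY_W[(intention, value)]
            weights[condition_name("gratitude", intention, value)] = w
            weights[condition_name("joy", intention, value)] = -w
    return ContrastSpec(name=kind, weights=weights)


# --------------------------------------------------------------------------
# group t maps
# --------------------------------------------------------------------------

@dataclass
class TMapResult:
    t: VoxelMap
    z: VoxelMap
    n: int
    df: int
    excluded: np.ndarray     # zero-variance (or degenerate) voxels
    capped: np.ndarray       # voxels whose |Z| hit the cap


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Probability-transform t to a standard-normal score, symmetric in
    sign and capped at |Z| = Z_CAP for numerically degenerate values."""
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    return np.clip(z, -Z_CAP, Z_CAP)


def _stack(maps) -> tuple[np.ndarray, VoxelGrid, np.ndarray | None]:
    grid = maps[0].grid
    mask = maps[0].mask
    for m in maps[1:]:
        if not maps[0].same_grid(m):
            raise ValueError("subject maps are on different grids")
    return np.stack([m.data for m in maps]), grid, mask


def one_sample_t_map(contrast_maps: list[VoxelMap],
                     mask: np.ndarray | None = None) -> TMapResult:
    """Voxelwise one-sample t-test against zero across subjects."""
    data, grid, map_mask = _stack(contrast_maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subject maps")
    m = np.ones(grid.shape, bool) if mask is None else np.asarray(mask, bool)
    if map_mask is not None:
        m = m & map_mask
    m = m & ~np.isnan(data).any(axis=0)

    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    degenerate = m & (sd == 0)
    valid = m & (sd > 0)
    df = n - 1
    t = np.full(grid.shape, np.nan)
    z = np.full(grid.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    z[valid] = _t_to_z(t[valid], df)
    # zero-variance voxels: identical nonzero values cap at +/- Z_CAP
    # (flagged), identical zeros are an exact null (t = 0)
    t[degenerate] = np.sign(mean[degenerate]) * Z_CAP
    z[degenerate] = np.sign(mean[degenerate]) * Z_CAP
    capped = np.zeros(grid.shape, bool)
    capped[valid] = np.abs(z[valid]) >= Z_CAP
    capped[degenerate] = mean[degenerate] != 0
    return TMapResult(t=VoxelMap(t, grid, m), z=VoxelMap(z, grid, m),
                      n=n, df=df, excluded=degenerate, capped=capped)


def paired_t_map(maps_a: list[VoxelMap], maps_b: list[VoxelMap],
                 mask: np.ndarray | None = None) -> TMapResult:
    """Paired t-test: one-sample t on the per-subject difference maps."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired map lists must have equal length")
    diffs = []
    for a, b in zip(maps_a, maps_b):
        if not a.same_grid(b):
            raise ValueError("paired maps are on different grids")
        diffs.append(VoxelMap(a.data - b.data, a.grid, a.mask))
    return one_sample_t_map(diffs, mask=mask)


# --------------------------------------------------------------------------
# smoothness and the Monte-Carlo null
# --------------------------------------------------------------------------

def estimate_fwhm(residuals_4d: np.ndarray, mask: np.ndarray) -> float:
    """Smoothness (FWHM in voxels) of standardized residual fields.

    Assumes a Gaussian spatial autocorrelation rho(d) = exp(-d^2 / 4 s^2)
    (the model the Monte-Carlo null uses) and inverts the lag-1 spatial
    autocorrelation of the per-voxel-standardized residuals:
    s^2 = -1 / (4 ln rho(1)), FWHM = 2 sqrt(2 ln 2) s, averaged over axes.
    Uncorrelated residuals give FWHM 0."""
    mask = np.asarray(mask, bool)
    r = np.asarray(residuals_4d, float)
    sd = r.std(axis=3, keepdims=True)
    sd[sd == 0] = 1.0
    z = r / sd

    rhos = []
    for axis in range(3):
        a = np.moveaxis(z, axis, 0)
        ma = np.moveaxis(mask, axis, 0)
        pair = ma[:-1] & ma[1:]
        if not pair.any():
            continue
        x = a[:-1][pair].ravel()
        y = a[1:][pair].ravel()
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        if denom > 0:
            rhos.append((x * y).sum() / denom)
    if not rhos:
        return 0.0
    rho = float(np.mean(rhos))
    if rho <= 0:
        return 0.0
    if rho >= 1:
        return float("inf")
    s2 = -1.0 / (4.0 * np.log(rho))
    return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * np.sqrt(s2))


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_null_field(shape, fwhm_vox: float, rng,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """One unit-variance smooth Gaussian null field (white noise smoothed
    at ``fwhm_vox`` and restandardized over the mask; unsmoothed white
    noise is already standard and is returned as drawn)."""
    field = rng.standard_normal(tuple(shape))
    if fwhm_vox > 0:
        field = ndimage.gaussian_filter(field, sigma=fwhm_vox * _FWHM_TO_SIGMA)
        m = np.ones(field.shape, bool) if mask is None else mask
        sd = field[m].std()
        field = field / (sd if sd > 0 else 1.0)
    return field


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


@dataclass
class NullClusterDistribution:
    max_sizes: np.ndarray
    n_simulations: int
    voxel_p: float
    fwhm_vox: float
    connectivity: int

    def critical_size(self, alpha: float = 0.05) -> int:
        """Smallest extent k with P(max null cluster >= k) <= alpha."""
        sizes = np.sort(self.max_sizes)[::-1]
        k = 1
        while np.mean(self.max_sizes >= k) > alpha:
            k += 1
        return k

    def cluster_p(self, size: int) -> float:
        """Cluster-level FWE p: null probability of any cluster this large."""
        return float(np.mean(self.max_sizes >= size))


def monte_carlo_cluster_threshold(mask: np.ndarray, fwhm_vox: float,
                                  voxel_p: float = 0.001,
                                  n_sim: int = 10_000,
                                  connectivity: int = 26,
                                  seed=0) -> NullClusterDistribution:
    """Null distribution of the maximum suprathreshold cluster size.

    Each simulation draws a smooth Gaussian field on the mask grid,
    thresholds it one-sided at ``voxel_p``, and records the largest
    connected component.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    if fwhm_vox < 0:
        raise ValueError("fwhm must be nonnegative")
    structure = _STRUCTURES[connectivity]
    zthr = stats.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)
    max_sizes = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        field = smooth_null_field(mask.shape, fwhm_vox, rng, mask)
        max_sizes[s] = _max_cluster_size((field > zthr) & mask, structure)
    return NullClusterDistribution(
        max_sizes=max_sizes, n_simulations=n_sim, voxel_p=voxel_p,
        fwhm_vox=fwhm_vox, connectivity=connectivity)


# --------------------------------------------------------------------------
# cluster extraction
# --------------------------------------------------------------------------

def _clusters_at(z: np.ndarray, mask: np.ndarray, zthr: float,
                 structure: np.ndarray) -> list[dict]:
    supra = (z > zthr) & mask
    labels, n = ndimage.label(supra, structure=structure)
    out = []
    for lab in range(1, n + 1):
        voxels = labels == lab
        size = int(voxels.sum())
        zin = np.where(voxels, z, -np.inf)
        peak = np.unravel_index(np.argmax(zin), z.shape)
        out.append({"size": size, "peak_i": int(peak[0]),
                    "peak_j": int(peak[1]), "peak_k": int(peak[2]),
                    "peak_z": float(z[peak]), "voxels": voxels})
    return out


def extract_clusters(stat_map: VoxelMap, voxel_p: float, critical_size: int,
                     connectivity: int = 26,
                     trend_p: float | None = None,
                     trend_critical_size: int | None = None,
                     null_dist: NullClusterDistribution | None = None
                     ) -> pd.DataFrame:
    """Suprathreshold connected components of a Z map.

    Components at the primary threshold with extent >= ``critical_size``
    are labeled ``significant``; when a trend tier is given, components at
    the lenient threshold passing its critical size (and not already
    significant) are labeled ``trend``.  If a null distribution is
    supplied, each cluster gets its FWE-corrected p.
    """
    z = np.where(np.isnan(stat_map.data), -np.inf, stat_map.data)
    mask = (np.ones(stat_map.grid.shape, bool) if stat_map.mask is None
            else stat_map.mask)
    structure = _STRUCTURES[connectivity]

    rows = []
    primary = _clusters_at(z, mask, stats.norm.isf(voxel_p), structure)
    sig_voxels = np.zeros(z.shape, bool)
    for c in primary:
        if c["size"] >= critical_size:
            sig_voxels |= c["voxels"]
            rows.append({**{k: c[k] for k in
                            ("size", "peak_i", "peak_j", "peak_k", "peak_z")},
                         "label": "significant"})
    if trend_p is not None:
        tcrit = (trend_critical_size if trend_critical_size is not None
                 else critical_size)
        for c in _clusters_at(z, mask, stats.norm.isf(trend_p), structure):
            if c["size"] >= tcrit and not (c["voxels"] & sig_voxels).any():
                rows.append({**{k: c[k] for k in
                                ("size", "peak_i", "peak_j", "peak_k",
                                 "peak_z")},
                             "label": "trend"})
    table = pd.DataFrame(
        rows, columns=["size", "peak_i", "peak_j", "peak_k", "peak_z",
                       "label"])
    if null_dist is not None and len(table):
        table["p_fwe"] = [null_dist.cluster_p(s) for s in table["size"]]
    return table.sort_values("size", ascending=False).reset_index(drop=True)
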