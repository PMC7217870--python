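"""Synthetic 4D BOLD generation.

Voxel time courses follow the first-level design: condition regressors
scaled by per-voxel ground-truth amplitudes plus Model-2 parametric
modulator columns scaled by per-voxel modulation slopes, with AR(1)
Gaussian noise (optionally spatially smoothed to mimic the spatial
correlation of preprocessed data).  The ground truth also carries ROI
label maps marking voxel sets whose modulation slopes differ between
gratitude and joy, so that downstream univariate and multivariate recovery
is testable against a known answer.

By default the modulator signal is injected through the *orthogonalized*
modulator columns — the exact columns Model 2 fits — so that a noiseless
simulation is recovered to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .design import SubjectDesign
from .glm import MODULATOR_ORDER, build_model1, build_model2
from .images import VoxelGrid, VoxelMap
from .ratings import RatingRecord

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_brain_mask(shape) -> np.ndarray:
    """Ellipsoid inscribed in the grid (drops the corners, as a brain
    bounding box does)."""
    shape = tuple(shape)
    grids = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    r = np.asarray(shape) / 2.0
    d2 = sum(((grids[k] - c[k]) / r[k]) ** 2 for k in range(3))
    return d2 <= 1.0


@dataclass
class GroundTruth:
    """Per-voxel generative parameters on a fixed grid.

    ``condition_amplitudes`` maps Model-1 condition names to 3D amplitude
    fields; ``onset_amplitudes`` maps an emotion to the amplitude of its
    unmodulated rating-event response; ``modulator_slopes`` maps
    (emotion, modulator) to 3D slope fields.  ``roi_labels`` names disjoint
    voxel sets carrying emotion-dissociable slopes.
    """
    grid: VoxelGrid
    condition_amplitudes: dict = field(default_factory=dict)
    onset_amplitudes: dict = field(default_factory=dict)
    modulator_slopes: dict = field(default_factory=dict)
    roi_labels: dict = field(default_factory=dict)
    ar1_phi: float = 0.3
    innovation_sd: float = 1.0
    smoothing_fwhm_mm: float = 0.0
    brain_mask: np.ndarray | None = None
    gray_matter_prob: np.ndarray | None = None

    def __post_init__(self):
        if self.brain_mask is None:
            self.brain_mask = default_brain_mask(self.grid.shape)
        if self.gray_matter_prob is None:
            self.gray_matter_prob = np.where(self.brain_mask, 0.6, 0.0)
        rois = list(self.roi_labels.values())
        for a in range(len(rois)):
            for b in range(a + 1, len(rois)):
                if np.any(rois[a] & rois[b]):
                    raise ValueError("ROI label maps must be disjoint")

    @classmethod
    def null(cls, shape=(6, 6, 6), voxel_size: float = 3.0,
             **kwargs) -> "GroundTruth":
        """Truth with no signal anywhere (noise-only simulation)."""
        return cls(grid=VoxelGrid(tuple(shape), voxel_size), **kwargs)

    def gm_mask(self, threshold: float = 0.2) -> np.ndarray:
        return self.gray_matter_prob > threshold

    def plant_modulator_difference(self, roi_name: str, roi_mask: np.ndarray,
                                   modulator: str, delta: float,
                                   base_slope: float = 0.0) -> None:
        """Give gratitude and joy slopes of base +/- delta/2 inside the ROI
        (equal ``base_slope`` outside), for one modulator."""
        if modulator not in MODULATOR_ORDER:
            raise ValueError(f"unknown modulator {modulator!r}")
        roi_mask = np.asarray(roi_mask, bool)
        self.roi_labels[roi_name] = roi_mask
        for emotion, sign in (("gratitude", +0.5), ("joy", -0.5)):
            fld = np.full(self.grid.shape, base_slope)
            fld[roi_mask] = base_slope + sign * delta
            self.modulator_slopes[(emotion, modulator)] = fld


@dataclass
class SimulatedBold:
    runs: list[np.ndarray]
    tr: float
    grid: VoxelGrid
    brain_mask: VoxelMap
    gray_matter_prob: VoxelMap
    motion: list[np.ndarray]

    @property
    def n_volumes(self) -> list[int]:
        return [r.shape[3] for r in self.runs]


def synthesize_motion(n_volumes: int, seed, step_sd: float = 0.02,
                      n_params: int = 6) -> np.ndarray:
    """Slow-drift random-walk series standing in for realignment
    parameters (3 translations mm, 3 rotations deg)."""
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.normal(0.0, step_sd, size=(n_volumes, n_params)),
                     axis=0)


def _ar1_noise(rng, shape, n_t, phi, sd):
    innov = rng.normal(0.0, sd, size=shape + (n_t,))
    if phi == 0.0:
        return innov
    return lfilter([1.0], [1.0, -phi], innov, axis=3)


def simulate_bold(design: SubjectDesign, records: list[RatingRecord],
                  truth: GroundTruth, seed,
                  use_orthogonalized_modulators: bool = True,
                  oversampling: int = 16) -> SimulatedBold:
    """Generate per-run 4D volumes whose in-mask voxels follow the design.

    Signal: condition columns (Model-1 style) times ``condition_amplitudes``
    plus emotion onset and modulator columns (Model-2 style) times
    ``onset_amplitudes`` / ``modulator_slopes``.  Noise: AR(1) Gaussian with
    optional spatial smoothing at ``truth.smoothing_fwhm_mm`` (rescaled to
    preserve the marginal SD).  Voxels outside the brain mask are zero.
    Deterministic under ``seed``.
    """
    grid = truth.grid
    mask = truth.brain_mask
    if mask.shape != tuple(grid.shape):
        raise ValueError("truth grid and brain mask shapes differ")
    rng = np.random.default_rng(seed)
    tr = design.runs[0].tr

    cols = []          # (name, time course, 3D amplitude field)
    if truth.condition_amplitudes:
        X1 = build_model1(design, records, include_rating_order=False,
                          include_run_intercepts=False,
                          oversampling=oversampling)
        for name, amp in truth.condition_amplitudes.items():
            if name in X1.names:
                cols.append((X1.column(name), np.asarray(amp, float)))
            else:
                warnings.warn(f"condition {name} has no events; skipped")
    if truth.onset_amplitudes or truth.modulator_slopes:
        X2 = build_model2(design, records, include_rating_order=False,
                          include_run_intercepts=False,
                          oversampling=oversampling,
                          orthogonalize=use_orthogonalized_modulators)
        for emotion, amp in truth.onset_amplitudes.items():
            cols.append((X2.column(f"{emotion}_onset"), np.asarray(amp, float)))
        for (emotion, mod), slope in truth.modulator_slopes.items():
            name = f"{emotion}_x_{mod}"
            if name in X2.names:
                cols.append((X2.column(name), np.asarray(slope, float)))
            else:
                warnings.warn(f"modulator column {name} absent; skipped")

    n_t_total = sum(r.n_volumes for r in design.runs)
    flat_signal = np.zeros((n_t_total, grid.n_voxels))
    for tc, amp in cols:
        flat_signal += np.outer(tc, amp.ravel())
    signal = flat_signal.T.reshape(grid.shape + (n_t_total,))

    sigma_vox = (truth.smoothing_fwhm_mm * _FWHM_TO_SIGMA / grid.voxel_size
                 if truth.smoothing_fwhm_mm > 0 else 0.0)
    runs, motion = [], []
    start = 0
    for run in design.runs:
        n_t = run.n_volumes
        noise = _ar1_noise(rng, tuple(grid.shape), n_t,
                           truth.ar1_phi, truth.innovation_sd)
        if sigma_vox > 0:
            sd_before = noise.std()
            noise = gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0.0,))
            sd_after = noise.std()
            if sd_after > 0:
                noise *= sd_before / sd_after
        vol = signal[..., start:start + n_t] + noise
        vol[~mask] = 0.0
        runs.append(vol)
        motion.append(synthesize_motion(n_t, rng.integers(2 ** 31)))
        start += n_t

    return SimulatedBold(
        runs=runs, tr=tr, grid=grid,
        brain_mask=VoxelMap(mask.astype(float), grid),
        gray_matter_prob=VoxelMap(truth.gray_matter_prob, grid),
        motion=motion)
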