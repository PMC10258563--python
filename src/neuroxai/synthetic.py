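"""Synthetic volumetric activation datasets with planted class structure.

The generator emulates the statistical structure of trial-level BOLD maps
used in whole-brain mental-state decoding: smooth, spatially correlated
activation patterns inside a brain-like mask, one pattern per mental state,
with per-subject random effects and additive smooth noise.  Each class
pattern is a sum of isotropic Gaussian blobs; a configurable fraction of
blobs carries negative sign (de-activations), and extra "redundant" clusters
duplicate the signal of an existing blob at a disjoint location so that a
decoder can rely on either copy — the redundancy that makes explanation
faithfulness and ground-truth alignment dissociate.

Because the generator owns the ground truth (the planted per-class weight
volumes), every downstream stage — decoding, attribution, GLM aggregation,
and the benchmark metrics — is testable without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "GroundTruthPattern",
    "TrialVolume",
    "SplitDataset",
    "ellipsoid_mask",
    "make_class_patterns",
    "generate_dataset",
    "stack_trials",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
# support = voxels above half of the pattern's peak |weight| (the FWHM
# convention for the extent of a Gaussian blob)
_SUPPORT_THRESHOLD = 0.5


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic decoding dataset.

    Defaults are sized so that a full benchmark (ensemble training included)
    runs on a single CPU in minutes while preserving the qualitative
    structure of the emulated data: 4 balanced states, 12 subjects with a
    held-out 20% subject-wise test split, smooth signal and smooth noise of
    comparable amplitude, and two planted redundant clusters per state.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_subjects: int = 12
    trials_per_class_per_subject: int = 24
    n_classes: int = 4
    n_blobs_per_class: int = 3
    blob_fwhm: float = 4.0
    negative_blob_fraction: float = 0.25
    redundant_cluster_count: int = 2
    subject_sd: float = 0.1
    noise_sd: float = 0.5
    noise_smoothing_fwhm: float = 2.0
    test_fraction: float = 0.2
    n_runs_per_subject: int = 2
    seed: int = 0

    def validate(self) -> None:
        gs = tuple(self.grid_shape)
        if len(gs) != 3 or any((not isinstance(g, (int, np.integer))) or g < 8 for g in gs):
            raise ValueError(f"grid_shape must be 3 integers each >= 8, got {self.grid_shape}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_subjects < 1 or self.trials_per_class_per_subject < 1:
            raise ValueError("n_subjects and trials_per_class_per_subject must be positive")
        if self.n_blobs_per_class < 1:
            raise ValueError("n_blobs_per_class must be positive")
        if not 0.0 <= self.negative_blob_fraction <= 1.0:
            raise ValueError("negative_blob_fraction must lie in [0, 1]")
        if self.redundant_cluster_count < 0:
            raise ValueError("redundant_cluster_count must be non-negative")
        if self.blob_fwhm <= 0:
            raise ValueError("blob_fwhm must be positive")
        if self.subject_sd < 0 or self.noise_sd < 0 or self.noise_smoothing_fwhm < 0:
            raise ValueError("scales must be non-negative")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if int(round(self.test_fraction * self.n_subjects)) < 1:
            raise ValueError("test_fraction * n_subjects must be at least 1 subject")

    @property
    def class_labels(self) -> list[str]:
        return [f"state{c + 1:02d}" for c in range(self.n_classes)]


@dataclass
class GroundTruthPattern:
    """Planted per-class spatial weight volume (the generator's truth)."""

    class_id: str
    weights: np.ndarray
    support_mask: np.ndarray
    blobs: list = field(default_factory=list, repr=False, compare=False)


@dataclass
class TrialVolume:
    """One trial-level 3D activation map with its mask and identifiers."""

    values: np.ndarray
    mask: np.ndarray
    label: str
    subject_id: str
    run_id: str
    trial_id: str

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trial {self.trial_id}: non-finite values")
        if self.values.shape != self.mask.shape:
            raise ValueError(f"trial {self.trial_id}: values/mask shape mismatch")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError(f"trial {self.trial_id}: non-zero values outside mask")


@dataclass
class SplitDataset:
    """Subject-exclusive train/test partition of trial volumes."""

    train: list[TrialVolume]
    test: list[TrialVolume]

    def __post_init__(self):
        overlap = {t.subject_id for t in self.train} & {t.subject_id for t in self.test}
        if overlap:
            raise ValueError(f"subjects appear in both splits: {sorted(overlap)}")


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid — a cheap brain-like mask."""
    coords = np.indices(grid_shape).astype(float)
    out = np.zeros(grid_shape, dtype=bool)
    dist2 = np.zeros(grid_shape)
    for ax, n in enumerate(grid_shape):
        c = (n - 1) / 2.0
        r = n / 2.0 - 0.5
        dist2 += ((coords[ax] - c) / r) ** 2
    out[dist2 <= 1.0] = True
    return out


def _gaussian_blob(grid_shape, center, sigma) -> np.ndarray:
    coords = np.indices(grid_shape).astype(float)
    d2 = sum((coords[ax] - center[ax]) ** 2 for ax in range(3))
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _sample_blobs(config: SyntheticConfig, rng: np.random.Generator, mask: np.ndarray):
    """Blob specifications per class: (center, sign, group) triples.

    Redundant clusters share the ``group`` index of the base blob they
    duplicate, so per-subject amplitude perturbations keep the two copies
    perfectly correlated (true predictive redundancy).
    """
    in_mask = np.argwhere(mask)
    min_sep = 1.5 * config.blob_fwhm
    specs = []
    for _ in range(config.n_classes):
        n_neg = int(round(config.negative_blob_fraction * config.n_blobs_per_class))
        signs = np.ones(config.n_blobs_per_class)
        neg_idx = rng.choice(config.n_blobs_per_class, size=n_neg, replace=False)
        signs[neg_idx] = -1.0
        blobs = []
        for b in range(config.n_blobs_per_class):
            center = in_mask[rng.integers(len(in_mask))].astype(float)
            blobs.append({"center": center, "sign": float(signs[b]), "group": b})
        for r in range(config.redundant_cluster_count):
            base = blobs[int(rng.integers(config.n_blobs_per_class))]
            for attempt in range(1000):
                cand = in_mask[rng.integers(len(in_mask))].astype(float)
                if np.linalg.norm(cand - base["center"]) > min_sep:
                    break
            else:
                raise RuntimeError(
                    "could not place a spatially disjoint redundant cluster; "
                    "mask too small for blob_fwhm")
            blobs.append({"center": cand, "sign": base["sign"], "group": base["group"]})
        specs.append(blobs)
    return specs


def _render_pattern(blobs, grid_shape, sigma, mask,
                    amp_by_group=None, jitter=None) -> np.ndarray:
    vol = np.zeros(grid_shape)
    for blob in blobs:
        amp = 1.0 if amp_by_group is None else amp_by_group[blob["group"]]
        center = blob["center"] if jitter is None else blob["center"] + jitter
        vol += blob["sign"] * amp * _gaussian_blob(grid_shape, center, sigma)
    vol[~mask] = 0.0
    return vol


def make_class_patterns(config: SyntheticConfig) -> list[GroundTruthPattern]:
    """Planted per-class weight volumes; deterministic given ``config.seed``."""
    config.validate()
    mask = ellipsoid_mask(tuple(config.grid_shape))
    ss = np.random.SeedSequence(config.seed)
    rng_blobs = np.random.default_rng(ss.spawn(4)[0])
    sigma = config.blob_fwhm * FWHM_TO_SIGMA
    specs = _sample_blobs(config, rng_blobs, mask)
    patterns = []
    for label, blobs in zip(config.class_labels, specs):
        weights = _render_pattern(blobs, tuple(config.grid_shape), sigma, mask)
        thresh = _SUPPORT_THRESHOLD * np.abs(weights).max()
        support = np.abs(weights) > thresh
        if not support.any():
            raise RuntimeError(f"empty support for class {label}")
        patterns.append(GroundTruthPattern(label, weights, support, blobs))
    return patterns


def _smooth_noise(rng, grid_shape, noise_sd, smoothing_fwhm):
    noise = rng.normal(size=grid_shape)
    if smoothing_fwhm > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smoothing_fwhm * FWHM_TO_SIGMA)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return noise_sd * noise


def generate_dataset(config: SyntheticConfig):
    """Full synthetic dataset plus its ground-truth patterns.

    Per subject s and class c, each trial is
    ``pattern_c(subject-perturbed) + smooth Gaussian noise``, masked; the
    subject perturbation is a per-blob-group multiplicative amplitude factor
    ``1 + N(0, subject_sd)`` plus a small rigid jitter (<= 1 voxel) of all
    blob centers.  Subjects are split subject-wise into train/test.

    Returns ``(SplitDataset, list[GroundTruthPattern])``.
    """
    config.validate()
    grid = tuple(config.grid_shape)
    mask = ellipsoid_mask(grid)
    sigma = config.blob_fwhm * FWHM_TO_SIGMA
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4)
    patterns = make_class_patterns(config)
    rng_subj = np.random.default_rng(children[1])
    rng_noise = np.random.default_rng(children[2])
    rng_split = np.random.default_rng(children[3])

    subject_ids = [f"sub{s + 1:02d}" for s in range(config.n_subjects)]
    n_test = max(1, int(round(config.test_fraction * config.n_subjects)))
    test_subjects = set(np.array(subject_ids)[rng_split.permutation(config.n_subjects)[:n_test]])

    n_groups = config.n_blobs_per_class
    train, test = [], []
    trial_counter = 0
    for subject in subject_ids:
        # rigid <=1-voxel jitter is part of the subject effect
        jitter = rng_subj.uniform(-1.0, 1.0, size=3) if config.subject_sd > 0 else None
        subject_patterns = {}
        for pat in patterns:
            amps = 1.0 + rng_subj.normal(0.0, config.subject_sd, size=n_groups) \
                if config.subject_sd > 0 else np.ones(n_groups)
            subject_patterns[pat.class_id] = _render_pattern(
                pat.blobs, grid, sigma, mask, amp_by_group=amps, jitter=jitter)
        bucket = test if subject in test_subjects else train
        for t in range(config.trials_per_class_per_subject):
            for label in config.class_labels:
                values = subject_patterns[label].copy()
                if config.noise_sd > 0:
                    values = values + _smooth_noise(
                        rng_noise, grid, config.noise_sd, config.noise_smoothing_fwhm)
                values[~mask] = 0.0
                run = f"run{(t % config.n_runs_per_subject) + 1:02d}"
                trial = TrialVolume(values=values, mask=mask, label=label,
                                    subject_id=subject, run_id=run,
                                    trial_id=f"trial{trial_counter:05d}")
                trial_counter += 1
                bucket.append(trial)
    return SplitDataset(train=train, test=test), patterns


def stack_trials(trials: list[TrialVolume]):
    """Stack trials into arrays: values (n, D, H, W) plus aligned metadata."""
    if not trials:
        raise ValueError("empty trial list")
    X = np.stack([t.values for t in trials])
    y = np.array([t.label for t in trials])
    subjects = np.array([t.subject_id for t in trials])
    runs = np.array([t.run_id for t in trials])
    ids = np.array([t.trial_id for t in trials])
    return X, y, subjects, runs, ids
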