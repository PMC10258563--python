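"""Two-stage voxelwise GLM machinery for reference maps and aggregation.

Stage one fits an ordinary-least-squares model independently at every voxel
of a stack of trial volumes (class indicator regressors of interest plus
nuisance regressors such as run indicators), producing per-subject
one-vs-rest contrast maps.  Stage two smooths the subject maps and fits a
second voxelwise GLM across subjects (class indicators of interest, subject
indicators as nuisance) — the paired t-test aggregation used for group
maps, with t statistics converted to Z scores through the Student-t CDF.

The same machinery aggregates trial-level attribution maps, adding binary
nuisance indicators for the model training runs and the per-map attribution
sum as a nuisance covariate.

Nuisance indicator columns are centered (deviation coding, one redundant
level dropped) so that the interest coefficients remain interpretable as
adjusted class means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic import FWHM_TO_SIGMA, GroundTruthPattern, TrialVolume

__all__ = [
    "DesignMatrix",
    "ContrastMap",
    "GLMFit",
    "fit_voxelwise_glm",
    "subject_contrast",
    "group_contrast",
    "aggregate_attributions",
    "ground_truth_reference",
    "smooth_volume",
]


@dataclass
class DesignMatrix:
    """Named regressors with an interest/nuisance kind per column."""

    frame: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self):
        unknown = set(self.kinds) - set(self.frame.columns)
        if unknown:
            raise ValueError(f"kinds refer to unknown columns: {sorted(unknown)}")
        for col in self.frame.columns:
            self.kinds.setdefault(col, "nuisance")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def check_rank(self) -> None:
        X = self.matrix
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns by greedy elimination
            keep, bad = [], []
            for i, name in enumerate(self.names):
                trial = keep + [i]
                if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                    keep.append(i)
                else:
                    bad.append(name)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.loc["__kind__"] = [self.kinds[c] for c in out.columns]
        out.to_csv(path)


@dataclass
class ContrastMap:
    """Voxelwise contrast: effect size, t and Z statistic volumes."""

    effect: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df: int
    contrast: np.ndarray
    degenerate: np.ndarray  # voxels with zero residual variance (t -> inf)

    def validate(self, mask: np.ndarray | None = None) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        region = mask if mask is not None else np.ones_like(self.effect, dtype=bool)
        if not np.all(np.isfinite(self.effect[region])):
            raise ValueError("non-finite effect inside mask")


class GLMFit:
    """OLS fit shared across voxels (one design, many independent targets)."""

    def __init__(self, Y: np.ndarray, design: DesignMatrix):
        # Y: (n_obs, ...) — trailing axes are the volume grid
        design.check_rank()
        X = design.matrix
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError(f"{Y.shape[0]} observations vs {n} design rows")
        self.grid_shape = Y.shape[1:]
        Yf = Y.reshape(n, -1)
        self.xtx_inv = np.linalg.inv(X.T @ X)
        self.beta = self.xtx_inv @ X.T @ Yf          # (p, n_vox)
        resid = Yf - X @ self.beta
        self.df = n - p
        if self.df <= 0:
            raise ValueError("no residual degrees of freedom")
        self.sigma2 = (resid ** 2).sum(axis=0) / self.df
        self.design = design

    def coefficient_volume(self, name: str) -> np.ndarray:
        i = self.design.names.index(name)
        return self.beta[i].reshape(self.grid_shape)

    def residual_variance(self) -> np.ndarray:
        return self.sigma2.reshape(self.grid_shape)

    def contrast(self, c: np.ndarray) -> ContrastMap:
        c = np.asarray(c, dtype=float)
        effect = c @ self.beta
        var_scale = float(c @ self.xtx_inv @ c)
        se = np.sqrt(self.sigma2 * var_scale)
        degenerate = se == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degenerate, np.sign(effect) * np.inf, effect / np.where(se == 0, 1, se))
        t = np.where(degenerate & (effect == 0), 0.0, t)
        z = _t_to_z(t, self.df)
        shape = self.grid_shape
        return ContrastMap(effect.reshape(shape), t.reshape(shape), z.reshape(shape),
                           self.df, c, degenerate.reshape(shape))


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles through the t CDF."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    # work on the tail for numerical stability, symmetric in sign
    z[pos] = -stats.norm.ppf(stats.t.sf(t[pos], df))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], df))
    return np.clip(z, -40, 40)


def fit_voxelwise_glm(observations, design: DesignMatrix) -> GLMFit:
    """Independent OLS at every voxel of a stack of volumes."""
    if isinstance(observations, (list, tuple)):
        observations = np.stack([
            o.values if isinstance(o, TrialVolume) else np.asarray(o)
            for o in observations])
    return GLMFit(np.asarray(observations, dtype=float), design)


def _indicators(values, prefix: str, drop_first: bool, center: bool) -> pd.DataFrame:
    levels = sorted(set(values))
    cols = {}
    use = levels[1:] if drop_first else levels
    for lev in use:
        col = (np.asarray(values) == lev).astype(float)
        if center:
            col = col - col.mean()
        cols[f"{prefix}{lev}"] = col
    return pd.DataFrame(cols)


def one_vs_rest_contrast(design: DesignMatrix, class_prefix: str, target: str) -> np.ndarray:
    """Contrast vector: target class vs the mean of all other classes."""
    names = design.names
    class_cols = [n for n in names if n.startswith(class_prefix)]
    others = [n for n in class_cols if n != f"{class_prefix}{target}"]
    c = np.zeros(len(names))
    c[names.index(f"{class_prefix}{target}")] = 1.0
    for n in others:
        c[names.index(n)] = -1.0 / len(others)
    return c


def subject_contrast(trials: list[TrialVolume]) -> dict[str, ContrastMap]:
    """Per-class one-vs-rest contrast maps for one subject's trials.

    Includes run indicator nuisance regressors when the subject has more
    than one run.
    """
    labels = [t.label for t in trials]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("subject has a single class; contrast undefined")
    frame = _indicators(labels, "class_", drop_first=False, center=False)
    kinds = {c: "interest" for c in frame.columns}
    runs = [t.run_id for t in trials]
    if len(set(runs)) > 1:
        run_cols = _indicators(runs, "run_", drop_first=True, center=True)
        frame = pd.concat([frame, run_cols], axis=1)
        kinds.update({c: "nuisance" for c in run_cols.columns})
    design = DesignMatrix(frame, kinds)
    fit = fit_voxelwise_glm(trials, design)
    return {cls: fit.contrast(one_vs_rest_contrast(design, "class_", cls))
            for cls in classes}


def smooth_volume(vol: np.ndarray, fwhm: float) -> np.ndarray:
    """Gaussian smoothing with FWHM in voxel units; fwhm=0 is the identity."""
    if fwhm <= 0:
        return np.asarray(vol, dtype=float)
    return ndimage.gaussian_filter(np.asarray(vol, dtype=float), sigma=fwhm * FWHM_TO_SIGMA)


def group_contrast(subject_maps: dict[str, list[np.ndarray]],
                   smoothing_fwhm: float = 1.5) -> dict[str, ContrastMap]:
    """Random-effects aggregation of per-subject contrast maps.

    ``subject_maps`` maps each class to the list of its subject-level effect
    volumes (aligned across classes by subject).  Maps are smoothed, then a
    voxelwise GLM with class indicators (interest) and centered subject
    indicators (nuisance) is fitted — the paired t-test across subjects.
    """
    classes = sorted(subject_maps)
    n_subj = len(subject_maps[classes[0]])
    if n_subj < 3:
        raise ValueError("group analysis requires at least 3 subjects")
    if any(len(v) != n_subj for v in subject_maps.values()):
        raise ValueError("unbalanced subject maps across classes")
    vols, cls_col, subj_col = [], [], []
    for cls in classes:
        for s, vol in enumerate(subject_maps[cls]):
            vols.append(smooth_volume(vol, smoothing_fwhm))
            cls_col.append(cls)
            subj_col.append(f"s{s:03d}")
    frame = _indicators(cls_col, "class_", drop_first=False, center=False)
    kinds = {c: "interest" for c in frame.columns}
    if n_subj > 1 and len(classes) > 1:
        subj_cols = _indicators(subj_col, "subject_", drop_first=True, center=True)
        frame = pd.concat([frame, subj_cols], axis=1)
        kinds.update({c: "nuisance" for c in subj_cols.columns})
    design = DesignMatrix(frame, kinds)
    fit = fit_voxelwise_glm(np.stack(vols), design)
    out = {}
    for cls in classes:
        c = np.zeros(len(design.names))
        c[design.names.index(f"class_{cls}")] = 1.0
        out[cls] = fit.contrast(c)
    return out


def aggregate_attributions(attributions, trials: list[TrialVolume],
                           smoothing_fwhm: float = 1.5):
    """Two-stage GLM over trial-level attribution maps from several runs.

    Subject stage: class indicators (interest), model-run indicators, fMRI
    run indicators and the centered per-map attribution sum (nuisance).
    Group stage: identical to :func:`group_contrast`.

    Returns ``(subject_maps, group_maps)`` where ``subject_maps`` maps
    ``(subject_id, class)`` to the subject-level effect volume and
    ``group_maps`` maps class to the group :class:`ContrastMap`.
    """
    meta = {t.trial_id: t for t in trials}
    runs = sorted({a.model_id for a in attributions})
    cells = {(a.trial_id, a.model_id) for a in attributions}
    missing = [(t.trial_id, r) for t in trials for r in runs
               if (t.trial_id, r) not in cells]
    if missing:
        raise ValueError(f"missing (trial, model-run) attribution cells, e.g. {missing[:3]}")

    by_subject: dict[str, list] = {}
    for a in attributions:
        if a.trial_id not in meta:
            continue
        by_subject.setdefault(meta[a.trial_id].subject_id, []).append(a)

    classes = sorted({t.label for t in trials})
    subject_maps: dict[tuple[str, str], np.ndarray] = {}
    for subject in sorted(by_subject):
        maps = by_subject[subject]
        labels = [meta[a.trial_id].label for a in maps]
        frame = _indicators(labels, "class_", drop_first=False, center=False)
        kinds = {c: "interest" for c in frame.columns}
        for values, prefix in (
                ([a.model_id for a in maps], "modelrun_"),
                ([meta[a.trial_id].run_id for a in maps], "run_")):
            if len(set(values)) > 1:
                cols = _indicators(values, prefix, drop_first=True, center=True)
                frame = pd.concat([frame, cols], axis=1)
                kinds.update({c: "nuisance" for c in cols.columns})
        sums = np.array([a.relevance_sum for a in maps], dtype=float)
        if np.ptp(sums) > 0:
            frame["relevance_sum"] = sums - sums.mean()
            kinds["relevance_sum"] = "nuisance"
        design = DesignMatrix(frame, kinds)
        fit = fit_voxelwise_glm(np.stack([a.relevance for a in maps]), design)
        for cls in classes:
            cmap = fit.contrast(one_vs_rest_contrast(design, "class_", cls))
            subject_maps[(subject, cls)] = cmap.effect

    subjects = sorted(by_subject)
    per_class = {cls: [subject_maps[(s, cls)] for s in subjects] for cls in classes}
    group_maps = group_contrast(per_class, smoothing_fwhm=smoothing_fwhm)
    return subject_maps, group_maps


def ground_truth_reference(patterns: list[GroundTruthPattern]) -> dict[str, np.ndarray]:
    """Planted class patterns as reference maps (the meta-analysis stand-in)."""
    return {p.class_id: p.weights for p in patterns}
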