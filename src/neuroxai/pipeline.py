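"""End-to-end benchmark orchestration: generate → train → attribute → evaluate.

Each stage writes its artifacts under the output directory and can be re-run
in isolation (stages load their inputs from disk), so a failed or resumed
benchmark never recomputes finished stages.  A master seed fans out to
per-stage seeds through a deterministic derivation, and every output is
traceable to the hash of the configuration that produced it.

Benchmark axes produced by the evaluate stage:

* ``alignment_runs.csv`` — per model run and method, mean KSG MI (and
  Pearson r) between subject-level aggregated attribution maps and the two
  references (planted ground truth; group-level GLM contrast of the
  training subjects' trial volumes).
* ``critical_rates.csv`` / ``faithfulness_curves.csv`` — occlusion curves
  per method and run with the chance-crossing rate (censored at 0.5).
* ``sanity.csv`` — model- and data-randomization MI per method on the
  primary model.
* ``summary.csv`` — the four-row check matrix (aligned / faithful /
  data-sensitive / model-sensitive): a method is marked "yes" when its
  score falls on the good side of the cross-method median.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import AttributionParams, AttributionVolume, METHODS
from .decoder import (DecoderConfig, TrainedDecoder, evaluate as evaluate_decoder,
                      full_search_grid, hyperparameter_search, small_search_grid,
                      train_ensemble)
from .evaluation import (MISpec, alignment_score, compare_methods,
                         data_randomization_check, default_rate_grid,
                         faithfulness_curve, model_randomization_check)
from .glm import aggregate_attributions, ground_truth_reference, group_contrast, subject_contrast
from .io import read_trials, write_map, write_trials
from .synthetic import SyntheticConfig, generate_dataset, stack_trials

__all__ = ["BenchmarkConfig", "run_benchmark", "stage_generate", "stage_train",
           "stage_attribute", "stage_evaluate", "stage_report"]

STAGES = ["generate", "train", "attribute", "evaluate", "report"]

# summary-axis definitions: score column and whether higher is better
SUMMARY_AXES = {
    "aligned": ("alignment", True),
    "faithful": ("critical_rate", False),
    "data_sensitive": ("mi_data_randomization", False),
    "model_sensitive": ("mi_model_randomization", False),
}


@dataclass
class BenchmarkConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    attribution: AttributionParams = field(default_factory=AttributionParams)
    mi: MISpec = field(default_factory=MISpec)
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    n_model_runs: int = 10
    search: str | None = None          # None, "small" or "full"
    max_epochs: int = 100
    occlusion_rates: list[float] = field(
        default_factory=lambda: [float(r) for r in default_rate_grid()])
    run_sanity_checks: bool = True
    memorize_epochs: int = 300
    sanity_n_trials: int = 24
    sanity_train_subset: int = 128
    attrib_max_trials: int | None = None
    smoothing_fwhm: float = 1.5
    out_dir: str = "benchmark_out"
    seed: int = 0

    def validate(self) -> None:
        self.synthetic.validate()
        self.decoder.validate()
        self.attribution.validate()
        self.mi.validate()
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown attribution method {m!r}")
        if self.search not in (None, "small", "full"):
            raise ValueError("search must be None, 'small' or 'full'")
        if self.n_model_runs < 1:
            raise ValueError("n_model_runs must be >= 1")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attribution"].pop("reference_data", None)
        d["attribution"].pop("deeplift_reference", None)
        d["attribution"]["ig_baselines"] = list(d["attribution"]["ig_baselines"])
        d["synthetic"]["grid_shape"] = [int(g) for g in self.synthetic.grid_shape]
        d["occlusion_rates"] = [float(r) for r in d["occlusion_rates"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if "grid_shape" in syn:
            syn["grid_shape"] = tuple(syn["grid_shape"])
        dec = d.pop("decoder", {})
        att = d.pop("attribution", {})
        if "ig_baselines" in att:
            att["ig_baselines"] = tuple(att["ig_baselines"])
        mi = d.pop("mi", {})
        cfg = cls(synthetic=SyntheticConfig(**syn), decoder=DecoderConfig(**dec),
                  attribution=AttributionParams(**att), mi=MISpec(**mi), **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES) + 1)
        return {name: int(s % (2 ** 31 - 1)) for name, s in zip(STAGES, state)}


def _log(stage: str, message: str, t0: float) -> None:
    print(f"[neuroxai] stage={stage} t={time.time() - t0:7.1f}s {message}",
          file=sys.stderr, flush=True)


def _provenance(config: BenchmarkConfig, outdir: Path, stage: str) -> None:
    path = outdir / "provenance.json"
    record = json.loads(path.read_text()) if path.exists() else {}
    record.setdefault("config_hash", config.config_hash())
    record.setdefault("package_version", __version__)
    record.setdefault("stage_seeds", config.stage_seeds())
    record.setdefault("stages", {})
    record["stages"][stage] = {"completed_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    path.write_text(json.dumps(record, indent=2))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path}, produced by stage '{stage}'; "
            f"run that stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def stage_generate(config: BenchmarkConfig, outdir: Path):
    t0 = time.time()
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "data").mkdir(exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    syn = SyntheticConfig(**{**asdict(config.synthetic),
                             "seed": config.stage_seeds()["generate"]})
    dataset, patterns = generate_dataset(syn)
    write_trials(dataset.train, outdir / "data" / "train.nii")
    write_trials(dataset.test, outdir / "data" / "test.nii")
    import nibabel as nib
    stack = np.stack([p.weights for p in patterns], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, np.eye(4)), str(outdir / "data" / "patterns.nii"))
    pd.DataFrame({"class_id": [p.class_id for p in patterns]}).to_csv(
        outdir / "data" / "patterns.csv", index=False)
    _provenance(config, outdir, "generate")
    _log("generate", f"wrote {len(dataset.train)} train / {len(dataset.test)} test trials", t0)
    return dataset, patterns


def _load_dataset(config: BenchmarkConfig, outdir: Path):
    train = read_trials(_require(outdir / "data" / "train.nii", "generate", "downstream"))
    test = read_trials(_require(outdir / "data" / "test.nii", "generate", "downstream"))
    import nibabel as nib
    pat_vals = np.asarray(nib.load(str(outdir / "data" / "patterns.nii")).dataobj)
    pat_ids = pd.read_csv(outdir / "data" / "patterns.csv")["class_id"].tolist()
    from .synthetic import GroundTruthPattern, _SUPPORT_THRESHOLD
    patterns = []
    for i, cid in enumerate(pat_ids):
        w = np.asarray(pat_vals[..., i], dtype=np.float64)
        thr = _SUPPORT_THRESHOLD * np.abs(w).max()
        patterns.append(GroundTruthPattern(cid, w, np.abs(w) > thr))
    return train, test, patterns


def stage_train(config: BenchmarkConfig, outdir: Path) -> list[TrainedDecoder]:
    t0 = time.time()
    train_trials, test_trials, _ = _load_dataset(config, outdir)
    mdir = outdir / "models"
    mdir.mkdir(exist_ok=True)
    seed = config.stage_seeds()["train"]
    decoder_cfg = DecoderConfig(**{**asdict(config.decoder), "seed": seed})
    if config.search is not None:
        grid = (small_search_grid(seed) if config.search == "small"
                else full_search_grid(seed))
        best, table = hyperparameter_search(grid, train_trials,
                                            max_epochs=config.max_epochs)
        table.to_csv(mdir / "search_table.csv", index=False)
        decoder_cfg = DecoderConfig(**{**asdict(best.config), "seed": seed})
        _log("train", f"search selected {decoder_cfg}", t0)
    models = train_ensemble(decoder_cfg, train_trials, n_runs=config.n_model_runs,
                            max_epochs=config.max_epochs)
    logs = []
    for i, model in enumerate(models):
        model.save(mdir / f"run{i:02d}.npz")
        acc, _ = evaluate_decoder(model, test_trials)
        hist = model.history_frame()
        hist["run"] = f"run{i:02d}"
        logs.append(hist)
        _log("train", f"run{i:02d} test accuracy {acc:.3f}"
                      f"{' (primary)' if model.is_primary else ''}", t0)
    pd.concat(logs).to_csv(mdir / "training_log.csv", index=False)
    _provenance(config, outdir, "train")
    return models


def _load_models(config: BenchmarkConfig, outdir: Path) -> list[TrainedDecoder]:
    mdir = outdir / "models"
    paths = sorted(mdir.glob("run*.npz")) if mdir.exists() else []
    if not paths:
        raise FileNotFoundError(
            f"stage 'attribute' needs trained models under {mdir}; run stage 'train' first")
    return [TrainedDecoder.load(p) for p in paths]


def _attrib_trials(config: BenchmarkConfig, test_trials):
    if config.attrib_max_trials is None or config.attrib_max_trials >= len(test_trials):
        return test_trials
    rng = np.random.default_rng(config.stage_seeds()["attribute"])
    idx = np.sort(rng.choice(len(test_trials), size=config.attrib_max_trials, replace=False))
    return [test_trials[i] for i in idx]


def stage_attribute(config: BenchmarkConfig, outdir: Path):
    t0 = time.time()
    train_trials, test_trials, _ = _load_dataset(config, outdir)
    models = _load_models(config, outdir)
    adir = outdir / "attributions"
    adir.mkdir(exist_ok=True)
    trials = _attrib_trials(config, test_trials)
    X_train, _, _, _, _ = stack_trials(train_trials)
    params = AttributionParams(**{**asdict_params(config.attribution),
                                  "seed": config.stage_seeds()["attribute"]})
    params.reference_data = X_train
    manifest = []
    from .attribution import attribute_batch
    for i, model in enumerate(models):
        run = f"run{i:02d}"
        for method in config.methods:
            attrs = attribute_batch(model, trials, method, params, model_id=run)
            rel = np.stack([a.relevance for a in attrs]).astype(np.float32)
            np.savez_compressed(adir / f"{method}_{run}.npz", relevance=rel,
                                trial_ids=np.array([a.trial_id for a in attrs]),
                                sums=np.array([a.relevance_sum for a in attrs]))
            manifest.extend({"trial_id": a.trial_id, "method": method, "model_run": run,
                             "target": a.target, "relevance_sum": a.relevance_sum}
                            for a in attrs)
        _log("attribute", f"{run}: {len(config.methods)} methods x {len(trials)} trials", t0)
    pd.DataFrame(manifest).to_csv(adir / "manifest.csv", index=False)
    _provenance(config, outdir, "attribute")


def asdict_params(params: AttributionParams) -> dict:
    d = dict(params.__dict__)
    d.pop("reference_data", None)
    d.pop("deeplift_reference", None)
    return d


def _load_attributions(outdir: Path, method: str, run: str,
                       trials) -> list[AttributionVolume]:
    path = _require(outdir / "attributions" / f"{method}_{run}.npz",
                    "attribute", "evaluate")
    data = np.load(path)
    by_id = {t.trial_id: t for t in trials}
    out = []
    for i, tid in enumerate(data["trial_ids"]):
        tid = str(tid)
        out.append(AttributionVolume(
            relevance=np.asarray(data["relevance"][i], dtype=np.float64),
            method=method, target=by_id[tid].label if tid in by_id else "",
            model_id=run, trial_id=tid, relevance_sum=float(data["sums"][i])))
    return out


def stage_evaluate(config: BenchmarkConfig, outdir: Path):
    t0 = time.time()
    train_trials, test_trials, patterns = _load_dataset(config, outdir)
    models = _load_models(config, outdir)
    rdir = outdir / "results"
    rdir.mkdir(exist_ok=True)
    seed = config.stage_seeds()["evaluate"]
    mask = test_trials[0].mask
    trials = _attrib_trials(config, test_trials)
    runs = [f"run{i:02d}" for i in range(len(models))]
    classes = sorted({t.label for t in train_trials})

    # reference maps: planted ground truth + group GLM of training subjects
    gt_ref = ground_truth_reference(patterns)
    by_subject: dict[str, list] = {}
    for t in train_trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    subj_effects = {cls: [] for cls in classes}
    for subj in sorted(by_subject):
        cmaps = subject_contrast(by_subject[subj])
        for cls in classes:
            subj_effects[cls].append(cmaps[cls].effect)
    glm_ref = {cls: cm.z for cls, cm in
               group_contrast(subj_effects, smoothing_fwhm=config.smoothing_fwhm).items()}
    for cls in classes:
        write_map(glm_ref[cls], rdir / f"reference_glm_{cls}.nii")
        write_map(gt_ref[cls], rdir / f"reference_groundtruth_{cls}.nii")

    # alignment: subject-level aggregated attribution maps per model run
    align_rows = []
    for method in config.methods:
        for run in runs:
            attrs = _load_attributions(outdir, method, run, trials)
            subj_maps, _group = _aggregate_single_run(attrs, trials, config.smoothing_fwhm)
            for ref_name, ref in (("ground_truth", gt_ref), ("glm", glm_ref)):
                mis, rs = [], []
                for (subj, cls), vol in subj_maps.items():
                    spec = MISpec(config.mi.n_neighbors, config.mi.tie_noise_scale,
                                  config.mi.voxel_subsample, seed)
                    mi, r = alignment_score(vol, ref[cls], mask, spec)
                    mis.append(mi)
                    rs.append(r)
                align_rows.append({"method": method, "run": run, "reference": ref_name,
                                   "mi": float(np.mean(mis)), "pearson": float(np.mean(rs))})
    alignment = pd.DataFrame(align_rows)
    alignment.to_csv(rdir / "alignment_runs.csv", index=False)
    _log("evaluate", "alignment done", t0)

    # pooled two-stage aggregation across runs (group stage needs >= 3 subjects)
    n_test_subjects = len({t.subject_id for t in trials})
    if n_test_subjects >= 3:
        for method in config.methods:
            attrs = [a for run in runs
                     for a in _load_attributions(outdir, method, run, trials)]
            _, group_maps = aggregate_attributions(attrs, trials,
                                                   smoothing_fwhm=config.smoothing_fwhm)
            for cls, cm in group_maps.items():
                write_map(cm.z, rdir / f"group_attribution_{method}_{cls}.nii")

    # faithfulness
    rate_grid = np.asarray(config.occlusion_rates, dtype=float)
    curve_rows, crit_rows = [], []
    for method in config.methods:
        for run_idx, run in enumerate(runs):
            attrs = _load_attributions(outdir, method, run, trials)
            curve = faithfulness_curve(models[run_idx], trials, attrs, rate_grid)
            for rate, acc in zip(curve.occlusion_rates, curve.accuracy_at_rate):
                curve_rows.append({"method": method, "run": run,
                                   "occlusion_rate": rate, "accuracy": acc})
            crit_rows.append({"method": method, "run": run,
                              "critical_rate": curve.critical_rate
                              if not curve.censored else rate_grid[-1],
                              "censored": curve.censored,
                              "chance_level": curve.chance_level})
        _log("evaluate", f"faithfulness {method} done", t0)
    pd.DataFrame(curve_rows).to_csv(rdir / "faithfulness_curves.csv", index=False)
    critical = pd.DataFrame(crit_rows)
    critical.to_csv(rdir / "critical_rates.csv", index=False)

    # sanity checks on the primary model
    sanity = None
    if config.run_sanity_checks:
        primary = models[int(np.argmax([m.is_primary for m in models]))]
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(trials), size=min(config.sanity_n_trials, len(trials)),
                                 replace=False))
        strials = [trials[i] for i in idx]
        X_train, _, _, _, _ = stack_trials(train_trials)
        params = AttributionParams(**{**asdict_params(config.attribution), "seed": seed})
        params.reference_data = X_train
        spec = MISpec(config.mi.n_neighbors, config.mi.tie_noise_scale,
                      config.mi.voxel_subsample, seed)
        model_table = model_randomization_check(primary, strials, config.methods,
                                                params, spec, seed=seed)
        sub = train_trials[: config.sanity_train_subset]
        data_table, diagnostics = data_randomization_check(
            primary, sub, strials, config.methods, params, spec,
            n_epochs_memorize=config.memorize_epochs, seed=seed)
        sanity = model_table.rename(columns={"mi": "mi_model_randomization"}).merge(
            data_table.rename(columns={"mi": "mi_data_randomization"}),
            on="method", suffixes=("_model", "_data"))
        sanity.to_csv(rdir / "sanity.csv", index=False)
        (rdir / "sanity_diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
        _log("evaluate", "sanity checks done", t0)

    # method comparisons vs the DeepLift baseline
    baseline = "deeplift" if "deeplift" in config.methods else config.methods[0]
    gt_align = alignment.query("reference == 'ground_truth'").rename(columns={"mi": "score"})
    if len(config.methods) >= 2 and len(runs) >= 3:
        compare_methods(gt_align, baseline, seed=seed).table.to_csv(
            rdir / "comparison_alignment.csv", index=False)
        compare_methods(critical.rename(columns={"critical_rate": "score"}),
                        baseline, seed=seed).table.to_csv(
            rdir / "comparison_faithfulness.csv", index=False)

    # summary matrix
    scores = pd.DataFrame({"method": config.methods}).set_index("method")
    scores["alignment"] = gt_align.groupby("method")["score"].mean()
    scores["critical_rate"] = critical.groupby("method")["critical_rate"].mean()
    if sanity is not None:
        scores["mi_model_randomization"] = sanity.set_index("method")["mi_model_randomization"]
        scores["mi_data_randomization"] = sanity.set_index("method")["mi_data_randomization"]
    summary = pd.DataFrame(index=scores.index)
    for axis, (col, higher_better) in SUMMARY_AXES.items():
        if col not in scores.columns:
            continue
        med = scores[col].median()
        good = scores[col] >= med if higher_better else scores[col] <= med
        summary[axis] = np.where(good, "yes", "no")
    summary.to_csv(rdir / "summary.csv")
    scores.to_csv(rdir / "scores.csv")
    _provenance(config, outdir, "evaluate")
    _log("evaluate", "done", t0)
    return summary


def _aggregate_single_run(attrs, trials, smoothing_fwhm):
    """Subject-level aggregation of one run's attributions (no group stage)."""
    from .glm import DesignMatrix, _indicators, fit_voxelwise_glm, one_vs_rest_contrast
    meta = {t.trial_id: t for t in trials}
    by_subject: dict[str, list] = {}
    for a in attrs:
        by_subject.setdefault(meta[a.trial_id].subject_id, []).append(a)
    classes = sorted({t.label for t in trials})
    subj_maps = {}
    for subject in sorted(by_subject):
        maps = by_subject[subject]
        labels = [meta[a.trial_id].label for a in maps]
        frame = _indicators(labels, "class_", drop_first=False, center=False)
        kinds = {c: "interest" for c in frame.columns}
        run_vals = [meta[a.trial_id].run_id for a in maps]
        if len(set(run_vals)) > 1:
            cols = _indicators(run_vals, "run_", drop_first=True, center=True)
            frame = pd.concat([frame, cols], axis=1)
            kinds.update({c: "nuisance" for c in cols.columns})
        sums = np.array([a.relevance_sum for a in maps], dtype=float)
        if np.ptp(sums) > 0:
            frame["relevance_sum"] = sums - sums.mean()
            kinds["relevance_sum"] = "nuisance"
        design = DesignMatrix(frame, kinds)
        fit = fit_voxelwise_glm(np.stack([a.relevance for a in maps]), design)
        for cls in classes:
            cm = fit.contrast(one_vs_rest_contrast(design, "class_", cls))
            from .glm import smooth_volume
            subj_maps[(subject, cls)] = smooth_volume(cm.effect, smoothing_fwhm)
    return subj_maps, None


def stage_report(config: BenchmarkConfig, outdir: Path) -> str:
    rdir = outdir / "results"
    _require(rdir / "summary.csv", "evaluate", "report")
    summary = pd.read_csv(rdir / "summary.csv", index_col=0)
    scores = pd.read_csv(rdir / "scores.csv", index_col=0)
    lines = ["# Benchmark report", "",
             f"config hash: {config.config_hash()}", "",
             "## Check matrix (good side of the cross-method median)", "",
             summary.to_markdown(), "",
             "## Mean scores per method", "",
             scores.round(4).to_markdown(), ""]
    for name in ("comparison_alignment", "comparison_faithfulness"):
        path = rdir / f"{name}.csv"
        if path.exists():
            lines += [f"## {name} (vs DeepLift, 94% interval)", "",
                      pd.read_csv(path).round(4).to_markdown(index=False), ""]
    text = "\n".join(lines)
    (rdir / "summary.md").write_text(text)
    _provenance(config, outdir, "report")
    return text


def run_benchmark(config: BenchmarkConfig, stages: list[str] | None = None):
    """Run the full benchmark (or a subset of stages) under config.out_dir."""
    config.validate()
    outdir = Path(config.out_dir)
    todo = stages or STAGES
    for stage in todo:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    result = None
    for stage in STAGES:
        if stage not in todo:
            continue
        fn = {"generate": stage_generate, "train": stage_train,
              "attribute": stage_attribute, "evaluate": stage_evaluate,
              "report": stage_report}[stage]
        try:
            result = fn(config, outdir)
        except Exception:
            print(f"[neuroxai] stage '{stage}' failed; partial outputs retained in {outdir}",
                  file=sys.stderr)
            raise
    return result
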