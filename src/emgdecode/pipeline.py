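"""End-to-end orchestration: simulate -> preprocess -> features ->
experiment grid -> statistics -> motion synthesis.

A run is a pure function of its :class:`RunConfig`; a single master seed fans
out to per-stage seeds through a stable hash, so each stage is independently
reproducible.  Every stage's row/window/feature counts are logged into a run
manifest, and the end-to-end conservation of windows (kept rows + remainder
rule) is asserted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataio, evaluation, models, motion, preprocess, selection, synthgen
from .synthgen import ProtocolConfig, _rep_seed, _subject_seed

__all__ = ["RunConfig", "RunResult", "featurize_database", "sparse_sweep",
           "worst_repetition_motion", "run_all"]


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    feature_params: preprocess.FeatureParams = field(
        default_factory=preprocess.FeatureParams)
    chi2_p: float = 0.999            # outlier-elimination probability level
    ridge: float = 1e-6
    kinds: tuple[str, ...] = models.KINDS
    treatments: tuple[str, ...] = evaluation.TREATMENTS
    master_seed: int = 0
    artifact_rate: float = 0.0
    artifact_scale: float = 50.0
    sfs_scope: str = "dataset"
    sfs_max_features: int | None = None
    sparse_components: tuple[int, ...] | None = None   # None = auto sweep
    alpha: float = 0.05
    write_database: bool = True      # materialize the CSV tree on disk
    write_features: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = dataclasses.asdict(self.protocol)
        d["protocol"]["band"] = list(self.protocol.band)
        d["feature_params"] = dataclasses.asdict(self.feature_params)
        for k in ("kinds", "treatments", "sparse_components"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d:
            proto = dict(d["protocol"])
            if "band" in proto:
                proto["band"] = tuple(proto["band"])
            d["protocol"] = ProtocolConfig(**proto)
        if "feature_params" in d:
            d["feature_params"] = preprocess.FeatureParams(
                **d["feature_params"])
        for k in ("kinds", "treatments", "sparse_components"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunResult:
    config: RunConfig
    outlier_report: preprocess.OutlierReport
    per_subject_features: list[tuple[np.ndarray, np.ndarray]]
    pooled_features: tuple[np.ndarray, np.ndarray]
    grid: evaluation.GridResult
    metrics_subject_avg: dict
    metrics_pooled: dict
    sparse_curve: list[tuple[int, float]]
    sparse_baseline: float
    manifest: dict


def _simulate_matrices(config: ProtocolConfig, master_seed: int,
                       artifact_rate: float, artifact_scale: float,
                       ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-subject labeled matrices, global matrix, subject-id column."""
    subjects = []
    for s in range(1, config.n_subjects + 1):
        profile = synthgen.default_profile(
            _subject_seed(master_seed, s), config.n_classes,
            config.n_channels)
        parts = []
        for label in range(1, config.n_classes + 1):
            data = synthgen.generate_movement(profile, label, config,
                                              master_seed, s)
            if artifact_rate > 0:
                spec = synthgen.ArtifactSpec(
                    artifact_rate, artifact_scale,
                    seed=_rep_seed(master_seed, s, label, -2))
                data, _ = synthgen.inject_artifacts(data, spec)
            labeled = np.empty((data.shape[0], config.n_channels + 1))
            labeled[:, :-1] = data
            labeled[:, -1] = label
            parts.append(labeled)
        subjects.append(dataio.assemble_subject(parts))
    global_m = dataio.assemble_global(subjects)
    subject_ids = np.concatenate([
        np.full(len(m), i + 1, dtype=int) for i, m in enumerate(subjects)])
    return subjects, global_m, subject_ids


def _expected_windows(labels: np.ndarray, subject_ids: np.ndarray,
                      window_len: int) -> int:
    """Windows implied by kept rows + the remainder rule, computed
    independently of make_windows for the conservation assertion."""
    key = labels.astype(np.int64) * 1_000_003 + subject_ids.astype(np.int64)
    boundaries = np.flatnonzero(np.diff(key) != 0) + 1
    sizes = np.diff(np.concatenate([[0], boundaries, [len(key)]]))
    return int(sum(s // window_len + (1 if s % window_len else 0)
                   for s in sizes))


def featurize_database(config: ProtocolConfig, master_seed: int,
                       feature_params: preprocess.FeatureParams,
                       chi2_p: float = 0.999, artifact_rate: float = 0.0,
                       artifact_scale: float = 50.0):
    """Simulate, clean and featurize: the shared front half of a run.

    Returns (per-subject (X, y) list, pooled (X, y), outlier report,
    stage-count manifest).
    """
    subjects, global_m, subject_ids = _simulate_matrices(
        config, master_seed, artifact_rate, artifact_scale)
    total_rows = int(global_m.shape[0])
    kept, report = preprocess.remove_outliers(
        global_m, p=chi2_p, subject_ids=subject_ids)
    # re-derive kept subject ids through the same mask bookkeeping
    kept_ids = []
    for sid, info in sorted(report.per_subject.items()):
        kept_ids.append(np.full(info["kept"], sid, dtype=int))
    kept_ids = (np.concatenate(kept_ids) if kept_ids
                else np.empty(0, dtype=int))
    assert len(kept_ids) == len(kept)

    per_subject = []
    window_total = 0
    for s in range(1, config.n_subjects + 1):
        m = kept[kept_ids == s]
        windows = preprocess.make_windows(m, config.window_len)
        X, y = preprocess.feature_matrix(windows, feature_params)
        window_total += len(windows)
        per_subject.append((X, y))
    expected = _expected_windows(kept[:, -1].astype(int), kept_ids,
                                 config.window_len)
    assert window_total == expected, (
        f"window conservation violated: {window_total} != {expected}")
    pooled = (np.concatenate([X for X, _ in per_subject]),
              np.concatenate([y for _, y in per_subject]))
    manifest = {
        "total_rows": total_rows,
        "kept_rows": report.kept_rows,
        "removed_rows": report.removed_rows,
        "windows": window_total,
        "features_per_window": int(pooled[0].shape[1]),
        "feature_rows_pooled": int(pooled[0].shape[0]),
    }
    return per_subject, pooled, report, manifest


def _qda_a_pipeline(X, y, subset, ridge):
    """Normalize (fit on given rows) + restrict to subset; helper for the
    metrics / sparse / motion stages that reuse the winning treatment."""
    norm = preprocess.normalize_fit(X)
    Xn = preprocess.normalize_apply(norm, X)
    return norm, (Xn[:, subset] if subset is not None else Xn)


def _cv_predictions(X, y, kind, subset, ridge, seed, k=10):
    """Out-of-fold predictions under normalization + fixed subset."""
    folds = evaluation.cv_partition(len(y), k, seed, labels=y)
    pred = np.empty(len(y), dtype=int)
    for t in range(k):
        tst = folds == t
        norm = preprocess.normalize_fit(X[~tst])
        Xtrn = preprocess.normalize_apply(norm, X[~tst])
        Xtst = preprocess.normalize_apply(norm, X[tst])
        if subset is not None:
            Xtrn, Xtst = Xtrn[:, subset], Xtst[:, subset]
        model = models.fit(kind, Xtrn, y[~tst], ridge=ridge)
        pred[tst] = models.predict(model, Xtst)
    return pred


def sparse_sweep(X, y, subset, components, ridge=1e-6, seed=0, k=5):
    """Recognition vs retained components for the sparse-space conversion.

    Returns (curve [(m, recognition %)], no-transform baseline %).  Each
    point is a k-fold CV: normalization and the projection are fit on the
    training rows only.
    """
    folds = evaluation.cv_partition(len(y), k, seed, labels=y)

    def cv_recognition(m: int | None) -> float:
        accs = []
        for t in range(k):
            tst = folds == t
            norm = preprocess.normalize_fit(X[~tst])
            Xtrn = preprocess.normalize_apply(norm, X[~tst])
            Xtst = preprocess.normalize_apply(norm, X[tst])
            if subset is not None:
                Xtrn, Xtst = Xtrn[:, subset], Xtst[:, subset]
            if m is not None:
                sp = selection.sparse_fit(Xtrn, y[~tst], m, ridge=ridge)
                Xtrn = selection.sparse_transform(sp, Xtrn)
                Xtst = selection.sparse_transform(sp, Xtst)
            model = models.fit("qda", Xtrn, y[~tst], ridge=ridge)
            accs.append(models.recognition(models.predict(model, Xtst),
                                           y[tst]))
        return float(np.mean(accs))

    baseline = cv_recognition(None)
    curve = [(int(m), cv_recognition(int(m))) for m in components]
    return curve, baseline


def worst_repetition_motion(per_subject, config, master_seed, ridge=1e-6,
                            seed=0):
    """Reproduce one badly classified repetition as a motion file pair.

    Finds the (subject, class) cell with the lowest out-of-fold sensitivity
    under the winning treatment (QDA, normalization + SFS), regenerates one
    repetition of that movement, feeds its window decisions through the
    motion builder, and returns (ideal, predicted) motion matrices plus
    provenance.
    """
    worst = (101.0, 1, 1)  # sensitivity, subject, class
    cached = {}
    for s, (X, y) in enumerate(per_subject, start=1):
        Xs = preprocess.normalize_apply(preprocess.normalize_fit(X), X)
        subset = selection.sfs(Xs, y, model_kind="qda", ridge=ridge).subset
        pred = _cv_predictions(X, y, "qda", subset, ridge, seed)
        cached[s] = subset
        cm = evaluation.confusion_matrix(y, pred, np.unique(y))
        sens = evaluation.confusion_metrics(cm)["sensitivity"]
        for ci, c in enumerate(np.unique(y)):
            if sens[ci] < worst[0]:
                worst = (float(sens[ci]), s, int(c))
    _, subj, cls = worst

    X, y = per_subject[subj - 1]
    norm = preprocess.normalize_fit(X)
    subset = cached[subj]
    model = models.fit("qda", preprocess.normalize_apply(norm, X)[:, subset],
                       y, ridge=ridge)
    profile = synthgen.default_profile(_subject_seed(master_seed, subj),
                                       config.n_classes, config.n_channels)
    rep = synthgen.generate_repetition(
        profile, cls, config, _rep_seed(master_seed, subj, cls, 0))
    labeled = np.column_stack([rep, np.full(len(rep), cls, dtype=float)])
    windows = preprocess.make_windows(labeled, config.window_len)
    Xr, _ = preprocess.feature_matrix(windows, preprocess.FeatureParams())
    decisions = models.predict(
        model, preprocess.normalize_apply(norm, Xr)[:, subset])
    predicted = motion.build_motion_matrix(decisions)
    ideal = motion.ideal_motion(cls, n_frames=len(decisions))
    return {
        "subject": subj, "class_label": cls,
        "abbreviation": dataio.abbreviation_for(cls),
        "sensitivity": worst[0],
        "decisions": decisions.tolist(),
        "ideal": ideal, "predicted": predicted,
    }


def run_all(config: RunConfig, out_dir: str | Path,
            overwrite: bool = False) -> RunResult:
    """Execute every stage and write the report bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    proto = config.protocol
    if config.write_database:
        artifacts = (synthgen.ArtifactSpec(config.artifact_rate,
                                           config.artifact_scale)
                     if config.artifact_rate > 0 else None)
        synthgen.generate_dataset(proto, config.master_seed,
                                  out_dir / "database", overwrite=overwrite,
                                  artifacts=artifacts)

    per_subject, pooled, report, manifest = featurize_database(
        proto, config.master_seed, config.feature_params,
        chi2_p=config.chi2_p, artifact_rate=config.artifact_rate,
        artifact_scale=config.artifact_scale)
    with open(out_dir / "outlier_report.yaml", "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=False)

    names = preprocess.feature_names(proto.n_channels)
    if config.write_features:
        feat_dir = out_dir / "features"
        feat_dir.mkdir(exist_ok=True)
        dataio.save_features(feat_dir / "NMU.tsv", pooled[0], pooled[1],
                             names)
        for i, (X, y) in enumerate(per_subject, start=1):
            dataio.save_features(feat_dir / f"NMP_sub{i}.tsv", X, y, names)

    grid = evaluation.run_experiment_grid(
        per_subject, pooled, kinds=config.kinds,
        treatments=config.treatments, seed=config.master_seed,
        ridge=config.ridge, sfs_scope=config.sfs_scope,
        sfs_max_features=config.sfs_max_features, alpha=config.alpha)
    _write_grid_tables(grid, out_dir, config)

    best_kind = "qda" if "qda" in config.kinds else config.kinds[0]
    best_tr = "A" if "A" in config.treatments else config.treatments[0]
    metrics_subject, metrics_pooled = _per_class_metrics(
        per_subject, pooled, grid, best_kind, best_tr, config)

    # sparse-space sweep on subject 1 under the winning treatment
    X1, y1 = per_subject[0]
    rep1 = grid.reports.get((best_kind, best_tr, "sub1"))
    subset = rep1.sfs_subset if rep1 is not None else None
    d = len(subset) if subset else X1.shape[1]
    comps = (config.sparse_components or
             sorted({1, 2, max(1, d // 4), max(1, d // 2), d}))
    curve, baseline = sparse_sweep(X1, y1, subset, comps,
                                   ridge=config.ridge,
                                   seed=config.master_seed)
    with open(out_dir / "sparse_sweep.tsv", "w") as fh:
        fh.write("n_components\trecognition\n")
        for m, r in curve:
            fh.write(f"{m}\t{r:.4f}\n")
        fh.write(f"baseline\t{baseline:.4f}\n")

    motion_dir = out_dir / "motion"
    motion_dir.mkdir(exist_ok=True)
    worst = worst_repetition_motion(per_subject, proto, config.master_seed,
                                    ridge=config.ridge,
                                    seed=config.master_seed)
    abbr = worst["abbreviation"]
    motion.write_mot(worst["ideal"], f"{abbr}_ideal",
                     motion_dir / f"{abbr}_ideal.mot")
    motion.write_mot(worst["predicted"],
                     f"{abbr}_sub{worst['subject']}_predicted",
                     motion_dir / f"{abbr}_sub{worst['subject']}_predicted.mot")
    for label in range(1, proto.n_classes + 1):
        m = motion.ideal_motion(label)
        nm = dataio.abbreviation_for(label)
        motion.write_mot(m, f"{nm}_ideal", motion_dir / f"ideal_{nm}.mot")

    manifest.update({
        "master_seed": config.master_seed,
        "stages": ["simulate", "outliers", "windows", "features", "grid",
                   "stats", "sparse", "motion"],
        "worst_repetition": {k: worst[k] for k in
                             ("subject", "class_label", "abbreviation",
                              "sensitivity")},
    })
    stats_doc = {
        "anova": (dataclasses.asdict(grid.anova) if grid.anova else None),
        "duncan": _duncan_doc(grid.duncan) if grid.duncan else None,
        "per_class_metrics_subject_avg": _metrics_doc(metrics_subject),
        "per_class_metrics_pooled": _metrics_doc(metrics_pooled),
    }
    with open(out_dir / "stats.yaml", "w") as fh:
        yaml.safe_dump(stats_doc, fh, sort_keys=False)
    with open(out_dir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump({"config": config.to_dict(), **manifest}, fh,
                       sort_keys=False)
    return RunResult(
        config=config, outlier_report=report,
        per_subject_features=per_subject, pooled_features=pooled,
        grid=grid, metrics_subject_avg=metrics_subject,
        metrics_pooled=metrics_pooled, sparse_curve=curve,
        sparse_baseline=baseline, manifest=manifest,
    )


def _per_class_metrics(per_subject, pooled, grid, kind, treatment, config):
    """Per-class sensitivity/specificity/precision/F1 under the chosen cell:
    subject-averaged (out-of-fold per subject) and pooled."""
    classes = np.unique(pooled[1])
    acc = {m: [] for m in ("sensitivity", "specificity", "precision", "f1")}
    for s, (X, y) in enumerate(per_subject, start=1):
        rep = grid.reports.get((kind, treatment, f"sub{s}"))
        subset = rep.sfs_subset if rep is not None else None
        pred = _cv_predictions(X, y, kind, subset, config.ridge,
                               config.master_seed)
        mets = evaluation.confusion_metrics(
            evaluation.confusion_matrix(y, pred, classes))
        for m in acc:
            acc[m].append(mets[m])
    subject_avg = {m: np.mean(np.vstack(v), axis=0) for m, v in acc.items()}
    subject_avg["classes"] = classes

    repp = grid.reports.get((kind, treatment, "pooled"))
    subsetp = repp.sfs_subset if repp is not None else None
    predp = _cv_predictions(pooled[0], pooled[1], kind, subsetp,
                            config.ridge, config.master_seed)
    pooled_m = evaluation.confusion_metrics(
        evaluation.confusion_matrix(pooled[1], predp, classes))
    pooled_m["classes"] = classes
    return subject_avg, pooled_m


def _metrics_doc(m: dict) -> dict:
    return {
        "classes": [int(c) for c in m["classes"]],
        **{k: [round(float(v), 4) for v in m[k]]
           for k in ("sensitivity", "specificity", "precision", "f1")},
    }


def _duncan_doc(d: evaluation.DuncanResult) -> dict:
    return {
        "alpha": d.alpha,
        "means": {k: round(v, 4) for k, v in d.means.items()},
        "ranges": {f"R{p}": round(v, 4) for p, v in d.ranges.items()},
        "decisions": {"-".join(sorted(pair)): ("significant" if sig
                                               else "not significant")
                      for pair, sig in d.significant.items()},
    }


def _write_grid_tables(grid: evaluation.GridResult, out_dir: Path,
                       config: RunConfig) -> None:
    with open(out_dir / "grid_summary.tsv", "w") as fh:
        fh.write("kind\ttreatment\tscope\tN.F\tTRN\tVAL\tTST\n")
        for (kind, tr, scope), rep in sorted(grid.reports.items()):
            fh.write(f"{kind}\t{tr}\t{scope}\t{rep.n_features:.1f}\t"
                     f"{rep.trn:.2f}\t{rep.val:.2f}\t{rep.tst:.2f}\n")
        for kind in config.kinds:
            for tr in config.treatments:
                s = grid.summary[(kind, tr)]
                fh.write(f"{kind}\t{tr}\t1..{len(grid.subject_scopes)}-avg\t"
                         f"\t\t\t{s['subject_avg_tst']:.2f}\n")
    if grid.treatment_table:
        with open(out_dir / "treatment_table.tsv", "w") as fh:
            trs = list(grid.treatment_table)
            fh.write("subject\t" + "\t".join(trs) + "\n")
            for i in range(len(grid.subject_scopes)):
                row = "\t".join(f"{grid.treatment_table[t][i]:.2f}"
                                for t in trs)
                fh.write(f"{i + 1}\t{row}\n")
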