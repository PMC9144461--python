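"""Nested 10x10 cross-validation, the four-treatment experiment grid, and
the statistical validation suite (one-way ANOVA, Duncan's multiple range
test, per-class confusion metrics).

The evaluation protocol: an outer stratified 10-fold split separates a test
block (TST) from a train-validation block (TRN-VAL); each TRN-VAL block is
split again into 10 stratified folds of TRN/VAL.  That yields 100 fitted
models; every inner model is also evaluated on its outer fold's TST block,
and the per-outer-fold TST scores are the average over the 10 inner models.

Treatments combine the two preprocessing steps:

    A  z-score normalization + sequential forward selection (SFS)
    B  normalization only
    C  SFS only
    D  no preprocessing

Normalization statistics are fit on TRN rows only, per inner fold.  SFS, by
default, runs once per dataset/classifier on training recognition and the
selected subset is then cross-validated (``sfs_scope="dataset"``, the
replicated procedure); ``sfs_scope="outer_fold"`` instead reruns SFS inside
every outer TRN-VAL block, which keeps the test block untouched by selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import models, selection
from .preprocess import normalize_apply, normalize_fit

__all__ = [
    "CvReport", "AnovaResult", "DuncanResult", "GridResult",
    "cv_partition", "nested_cv_10x10", "anova1", "duncan_ranges", "duncan",
    "confusion_matrix", "confusion_metrics", "run_experiment_grid",
    "TREATMENTS",
]

TREATMENTS = ("A", "B", "C", "D")
_NORMALIZING = {"A": True, "B": True, "C": False, "D": False}
_SELECTING = {"A": True, "B": False, "C": True, "D": False}


@dataclass
class CvReport:
    kind: str
    treatment: str
    scope: str                       # "sub<i>" or "pooled"
    fold_trn: list[float]
    fold_val: list[float]
    fold_tst: list[float]
    trn: float
    val: float
    tst: float
    n_features: float                # mean subset size over outer folds
    n_features_per_fold: list[int] = field(default_factory=list)
    sfs_subset: list[int] | None = None   # dataset-scope SFS subset, if any


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    MS_between: float
    MS_within: float
    SS_between: float
    SS_within: float


@dataclass
class DuncanResult:
    names: list[str]                 # group names, input order
    means: dict                      # name -> mean
    order: list[str]                 # names sorted by ascending mean
    ranges: dict                     # span p -> least significant range R_p
    significant: dict                # frozenset({a, b}) -> bool
    alpha: float


def cv_partition(n: int, k: int, seed: int,
                 labels: np.ndarray | None = None) -> np.ndarray:
    """Assign each of n indices to one of k folds.

    With ``labels`` the split is stratified: within every class the fold
    sizes differ by at most 1.  Deterministic given ``seed``.
    """
    if n < k:
        raise ValueError("n must be at least k")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if labels is None:
        idx = rng.permutation(n)
        assignment[idx] = np.arange(n) % k
        return assignment
    labels = np.asarray(labels).ravel()
    offset = 0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < k:
            raise ValueError(
                f"class {c} has {members.size} members, fewer than k={k}")
        perm = rng.permutation(members)
        assignment[perm] = (np.arange(members.size) + offset) % k
        offset += members.size
    return assignment


def _run_sfs(X, y, kind, ridge, max_features):
    res = selection.sfs(X, y, model_kind=kind, ridge=ridge,
                        max_features=max_features)
    return res.subset


def nested_cv_10x10(X: np.ndarray, y: np.ndarray, kind: str,
                    treatment: str = "D", k_outer: int = 10,
                    k_inner: int = 10, seed: int = 0, ridge: float = 1e-6,
                    scope: str = "", sfs_scope: str = "dataset",
                    sfs_max_features: int | None = None) -> CvReport:
    """Run the nested cross-validation for one dataset/classifier/treatment."""
    if treatment not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    normalizing = _NORMALIZING[treatment]
    selecting = _SELECTING[treatment]

    dataset_subset = None
    if selecting and sfs_scope == "dataset":
        Xs = X
        if normalizing:
            Xs = normalize_apply(normalize_fit(X), X)
        dataset_subset = _run_sfs(Xs, y, kind, ridge, sfs_max_features)

    outer = cv_partition(len(y), k_outer, seed, labels=y)
    fold_trn, fold_val, fold_tst = [], [], []
    nf_per_fold = []
    for t in range(k_outer):
        tst = outer == t
        trnval = ~tst
        Xtv, ytv = X[trnval], y[trnval]
        if selecting and sfs_scope == "outer_fold":
            Xs = Xtv
            if normalizing:
                Xs = normalize_apply(normalize_fit(Xtv), Xtv)
            subset = _run_sfs(Xs, ytv, kind, ridge, sfs_max_features)
        else:
            subset = dataset_subset
        nf_per_fold.append(len(subset) if subset is not None else X.shape[1])
        inner = cv_partition(len(ytv), k_inner, seed * 1009 + t + 1,
                             labels=ytv)
        t_trn, t_val, t_tst = [], [], []
        for v in range(k_inner):
            val = inner == v
            trn = ~val
            Xtrn, ytrn = Xtv[trn], ytv[trn]
            Xval, yval = Xtv[val], ytv[val]
            Xtst, ytst = X[tst], y[tst]
            if normalizing:
                norm = normalize_fit(Xtrn)
                Xtrn = normalize_apply(norm, Xtrn)
                Xval = normalize_apply(norm, Xval)
                Xtst = normalize_apply(norm, Xtst)
            if subset is not None:
                Xtrn, Xval, Xtst = (Z[:, subset] for Z in (Xtrn, Xval, Xtst))
            try:
                model = models.fit(kind, Xtrn, ytrn, ridge=ridge)
            except (ValueError, np.linalg.LinAlgError) as exc:
                raise RuntimeError(
                    f"fit failed in outer fold {t}, inner fold {v}: {exc}"
                ) from exc
            # one batched scoring pass over the three blocks
            pred = models.predict(model, np.concatenate([Xtrn, Xval, Xtst]))
            n1, n2 = len(ytrn), len(ytrn) + len(yval)
            t_trn.append(models.recognition(pred[:n1], ytrn))
            t_val.append(models.recognition(pred[n1:n2], yval))
            t_tst.append(models.recognition(pred[n2:], ytst))
        fold_trn.append(float(np.mean(t_trn)))
        fold_val.append(float(np.mean(t_val)))
        fold_tst.append(float(np.mean(t_tst)))
    return CvReport(
        kind=kind, treatment=treatment, scope=scope,
        fold_trn=fold_trn, fold_val=fold_val, fold_tst=fold_tst,
        trn=float(np.mean(fold_trn)), val=float(np.mean(fold_val)),
        tst=float(np.mean(fold_tst)),
        n_features=float(np.mean(nf_per_fold)),
        n_features_per_fold=nf_per_fold,
        sfs_subset=dataset_subset,
    )


def anova1(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        F = 0.0 if ms_b == 0.0 else np.inf
    else:
        F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(F=float(F), p=p, df_between=df_b, df_within=df_w,
                       MS_between=float(ms_b), MS_within=float(ms_w),
                       SS_between=float(ss_between),
                       SS_within=float(ss_within))


def duncan_ranges(p: int, df: int, alpha: float = 0.05) -> float:
    """Duncan's significant range r_alpha(p, df).

    Equals the studentized-range quantile at Duncan's protection level
    1 - (1-alpha)^(p-1) for p ordered means and df error degrees of freedom.
    """
    if p < 2 or df < 1:
        raise ValueError("need span p >= 2 and df >= 1")
    return float(stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df))


def duncan(groups: list[np.ndarray], alpha: float = 0.05,
           names: list[str] | None = None) -> DuncanResult:
    """Duncan's multiple range test on equal-size groups.

    A pair of means spanning p positions in the ordered sequence differs
    significantly iff its difference exceeds R_p = r_alpha(p, df_w) *
    sqrt(MS_within / n); the standard containment rule applies (no pair
    inside a non-significant span is declared significant).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise ValueError("Duncan's test here requires equal group sizes")
    n = sizes.pop()
    if names is None:
        names = [f"g{i + 1}" for i in range(len(groups))]
    an = anova1(groups)
    se = np.sqrt(an.MS_within / n)
    k = len(groups)
    ranges = {p: duncan_ranges(p, an.df_within, alpha) * se
              for p in range(2, k + 1)}

    means = np.array([g.mean() for g in groups])
    order = np.argsort(means, kind="stable")       # ascending
    ordered_names = [names[i] for i in order]
    ordered_means = means[order]

    significant: dict = {}
    # widest spans first so the containment rule can veto inner pairs
    shielded = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            pair = frozenset({ordered_names[lo], ordered_names[hi]})
            diff = ordered_means[hi] - ordered_means[lo]
            sig = diff > ranges[span] and not shielded[lo, hi]
            significant[pair] = bool(sig)
            if not sig:
                for a in range(lo, hi + 1):
                    for b in range(a + 1, hi + 1):
                        shielded[a, b] = True
    return DuncanResult(
        names=list(names),
        means={nm: float(mn) for nm, mn in zip(names, means)},
        order=ordered_names,
        ranges={p: float(r) for p, r in ranges.items()},
        significant=significant,
        alpha=alpha,
    )


def confusion_matrix(truth: np.ndarray, pred: np.ndarray,
                     classes: np.ndarray | None = None) -> np.ndarray:
    """K x K count matrix; rows = truth, columns = prediction."""
    truth = np.asarray(truth).astype(int).ravel()
    pred = np.asarray(pred).astype(int).ravel()
    if truth.size != pred.size:
        raise ValueError("truth/pred size mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([truth, pred]))
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes.tolist())}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for t, q in zip(truth, pred):
        cm[index[t], index[q]] += 1
    return cm


def confusion_metrics(cm: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class one-vs-rest sensitivity, specificity, precision and F1
    score, as percentages.  0/0 ratios yield 0 with a warning."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("need a square confusion matrix with K >= 2")
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def ratio(num, den, what):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if (~ok).any():
            warnings.warn(f"0/0 in {what}; reporting 0", stacklevel=2)
        return out * 100.0

    return {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "precision": ratio(tp, tp + fp, "precision"),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


@dataclass
class GridResult:
    reports: dict                    # (kind, treatment, scope) -> CvReport
    subject_scopes: list[str]
    summary: dict                    # (kind, treatment) -> averaged-subject + pooled TST
    treatment_table: dict            # treatment -> per-subject QDA TST list
    anova: AnovaResult | None = None
    duncan: DuncanResult | None = None

    def subject_average(self, kind: str, treatment: str,
                        which: str = "tst") -> float:
        vals = [getattr(self.reports[(kind, treatment, s)], which)
                for s in self.subject_scopes]
        return float(np.mean(vals))


def run_experiment_grid(per_subject: list[tuple[np.ndarray, np.ndarray]],
                        pooled: tuple[np.ndarray, np.ndarray],
                        kinds=models.KINDS, treatments=TREATMENTS,
                        seed: int = 0, ridge: float = 1e-6,
                        sfs_scope: str = "dataset",
                        sfs_max_features: int | None = None,
                        alpha: float = 0.05) -> GridResult:
    """The full kind x treatment x scope grid, plus treatment statistics.

    For every classifier kind and treatment the nested CV runs on each
    subject's feature matrix and on the pooled matrix.  The per-subject QDA
    TST percentages per treatment feed a one-way ANOVA and Duncan's test.
    """
    scopes = [f"sub{i + 1}" for i in range(len(per_subject))]
    reports: dict = {}
    for kind in kinds:
        for tr in treatments:
            for sc, (X, y) in zip(scopes, per_subject):
                reports[(kind, tr, sc)] = nested_cv_10x10(
                    X, y, kind, tr, seed=seed, ridge=ridge, scope=sc,
                    sfs_scope=sfs_scope, sfs_max_features=sfs_max_features)
            reports[(kind, tr, "pooled")] = nested_cv_10x10(
                pooled[0], pooled[1], kind, tr, seed=seed, ridge=ridge,
                scope="pooled", sfs_scope=sfs_scope,
                sfs_max_features=sfs_max_features)

    summary = {}
    for kind in kinds:
        for tr in treatments:
            subj_avg = float(np.mean(
                [reports[(kind, tr, s)].tst for s in scopes]))
            summary[(kind, tr)] = {
                "subject_avg_tst": subj_avg,
                "pooled_tst": reports[(kind, tr, "pooled")].tst,
            }

    treatment_table = {}
    anova_res = dunc = None
    if "qda" in kinds:
        for tr in treatments:
            treatment_table[tr] = [reports[("qda", tr, s)].tst
                                   for s in scopes]
        if len(treatments) >= 2 and len(scopes) >= 2:
            arrays = [np.asarray(treatment_table[tr]) for tr in treatments]
            anova_res = anova1(arrays)
            dunc = duncan(arrays, alpha=alpha, names=list(treatments))
    return GridResult(reports=reports, subject_scopes=scopes,
                      summary=summary, treatment_table=treatment_table,
                      anova=anova_res, duncan=dunc)
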