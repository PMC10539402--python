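"""Classification and statistics over per-cell deformability records.

* SVM on deformability features (polynomial kernel, degree 3, coef0 = 1,
  C = 5) with z-score standardization fit on training folds only and
  stratified k-fold cross-validation;
* diameter gating: exhaustive threshold scan maximizing raw accuracy, for
  separating large cells (e.g. tumor cells) from small ones (leukocytes);
* ROC/AUC (trapezoid over the empirical curve; equals the normalized
  Mann-Whitney U statistic);
* groupwise two-tailed t-tests and Mann-Whitney tests with the standard
  star convention and no multiplicity correction by default (Holm optional);
* fouling QC: discard a recording when more than 3 constrictions in one
  group are blocked by a stalled object.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .device import DeviceGeometry
from .errors import InputError

DEFAULT_SVM_PARAMS = {"kernel": "poly", "degree": 3, "coef0": 1.0, "C": 5.0}


@dataclass
class SVMResult:
    accuracy: float
    fold_scores: np.ndarray
    n_samples: int
    classes: tuple
    hyperparams: dict


def svm_classify(
    features,
    labels,
    hyperparams: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SVMResult:
    """Cross-validated accuracy of the polynomial-kernel SVM.

    Features are z-scored inside each training fold (no test leakage);
    folds are stratified and shuffled with ``seed``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("svm_classify needs >= 2 classes")
    if counts.min() < cv_folds:
        raise InputError(
            f"each class needs >= cv_folds={cv_folds} samples (min is {counts.min()})"
        )
    hp = dict(DEFAULT_SVM_PARAMS)
    hp.update(hyperparams or {})
    model = make_pipeline(StandardScaler(), SVC(**hp))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(model, x, y, cv=cv, scoring="accuracy")
    return SVMResult(
        accuracy=float(scores.mean()),
        fold_scores=scores,
        n_samples=len(y),
        classes=tuple(classes.tolist()),
        hyperparams=hp,
    )


def diameter_gate(diameters, labels) -> tuple[float, float]:
    """Best single-threshold diameter classifier.

    Scans the midpoints between consecutive sorted unique diameters (plus
    sentinels below/above the data) and returns the (threshold, accuracy)
    maximizing raw accuracy over both gate orientations; accuracy ties break
    to the smallest threshold.  Never worse than majority-class prevalence.
    """
    d = np.asarray(diameters, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InputError("diameter_gate needs exactly 2 classes")
    order = np.argsort(d, kind="stable")
    d_sorted, y_sorted = d[order], y[order]
    uniq = np.unique(d_sorted)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    # cumulative class-0 counts below each threshold
    is_c0 = (y_sorted == classes[0]).astype(int)
    cum_c0 = np.concatenate(([0], np.cumsum(is_c0)))
    n0, n = int(is_c0.sum()), len(y)
    best_thr, best_acc = candidates[0], -1.0
    for thr in candidates:
        k = int(np.searchsorted(d_sorted, thr, side="left"))  # samples below thr
        c0_below = cum_c0[k]
        # orientation A: predict class0 below thr; B: class0 above thr
        correct_a = c0_below + (n - k) - (n0 - c0_below)
        correct_b = n - correct_a
        acc = max(correct_a, correct_b) / n
        if acc > best_acc:
            best_acc, best_thr = acc, float(thr)
    return best_thr, float(best_acc)


def roc_auc(scores, labels, positive=None) -> tuple[float, np.ndarray]:
    """AUC by the trapezoid rule over the empirical ROC curve.

    Returns (auc, curve) with curve columns (fpr, tpr).  Numerically equal to
    U / (n1 * n2), the normalized Mann-Whitney statistic, and invariant under
    strictly monotone transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InputError("roc_auc needs exactly 2 classes")
    pos = positive if positive is not None else classes[1]
    fpr, tpr, _ = roc_curve(y == pos, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def significance_stars(p: float) -> str:
    """Star convention: >0.05 ns; <0.05 *; <0.01 **; <0.001 ***; <0.0001 ****."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    t_p: float
    mann_whitney_p: float
    t_stars: str = ""
    mw_stars: str = ""

    def __post_init__(self):
        self.t_stars = significance_stars(self.t_p)
        self.mw_stars = significance_stars(self.mann_whitney_p)


def group_tests(values_by_group: dict, holm: bool = False) -> list[GroupComparison]:
    """All pairwise two-tailed Student's t and Mann-Whitney U comparisons.

    No multiplicity correction by default; ``holm`` applies the Holm
    step-down correction to each test family.  Groups with fewer than 2
    values are skipped with a warning.
    """
    usable = {}
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has < 2 values; skipped")
            continue
        usable[name] = vals
    comparisons = []
    for a, b in itertools.combinations(usable, 2):
        va, vb = usable[a], usable[b]
        t_p = float(stats.ttest_ind(va, vb, equal_var=True).pvalue)
        mw_p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        comparisons.append(GroupComparison(a, b, t_p, mw_p))
    if holm and comparisons:
        for attr in ("t_p", "mann_whitney_p"):
            ps = np.array([getattr(c, attr) for c in comparisons])
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * ps[idx])
                adj[idx] = min(running, 1.0)
            for c, p in zip(comparisons, adj):
                setattr(c, attr, float(p))
        for c in comparisons:
            c.t_stars = significance_stars(c.t_p)
            c.mw_stars = significance_stars(c.mann_whitney_p)
    return comparisons


@dataclass
class QCResult:
    fouled_constrictions: list
    fouled_by_group: dict
    verdict: str  # "keep" | "discard"

    @property
    def keep(self) -> bool:
        return self.verdict == "keep"


def fouling_qc(
    tracks,
    geom: DeviceGeometry,
    fps: float,
    stall_frames_threshold: int | None = None,
) -> QCResult:
    """Fouling quality control on a recording.

    A constriction counts as fouled when any tracked object's centroid stays
    within its span [entrance, entrance + length] for at least
    ``stall_frames_threshold`` consecutive frames (default 3 s worth).  The
    recording is discarded iff more than 3 constrictions in any one group are
    fouled ("over 3": exactly 3 still keeps).
    """
    if stall_frames_threshold is None:
        stall_frames_threshold = int(round(3.0 * fps))
    fouled: set[int] = set()
    for t in tracks:
        cents = t.centroids()
        frames = t.frames()
        cid = geom.nearest_constriction(float(np.median(cents[:, 1])))
        x_in = float(geom.entrance_x[cid])
        x_out = x_in + geom.constriction_length_px
        inside = (cents[:, 0] > x_in) & (cents[:, 0] < x_out)
        run = 0
        prev_f = None
        for f, flag in zip(frames, inside):
            if flag and (prev_f is None or f == prev_f + 1):
                run += 1
            elif flag:
                run = 1
            else:
                run = 0
            prev_f = f if flag else None
            if run >= stall_frames_threshold:
                fouled.add(cid)
                break
    by_group: dict[int, int] = {g: 0 for g in range(geom.n_groups)}
    for cid in fouled:
        by_group[geom.group_of(cid)] += 1
    verdict = "discard" if any(v > 3 for v in by_group.values()) else "keep"
    return QCResult(sorted(fouled), by_group, verdict)
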