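"""Static pre-screen: SVM-RFE over every binary stage-pair sub-problem.

Before any network is built, non-informative features are removed.  The
N_s disease stages give N_s*(N_s-1)/2 binary classification sub-problems,
each contrasting the model-group samples at the typical time points of two
stages.  Each sub-problem is attacked with recursive feature elimination
driven by a linear max-margin classifier (linear kernel, penalty C = 1):
features are scored by squared hyperplane weight and the lowest-scoring
fraction is dropped each iteration until none remain.

The elimination is wrapped in repeated stratified cross-validation
(default 5-fold x 50 repeats).  Within a repeat, each elimination step
fits one classifier per training fold, scores features by the
fold-averaged squared weight, and scores the surviving subset by held-out
accuracy; the repeat's best subset is the one with maximal accuracy (ties
to the smaller subset).  A feature is selected for a sub-problem when it
appears in at least half of the repeats' best subsets, and the selections
of all sub-problems are united.  Driving the elimination from the training
folds makes the repeats genuinely independent re-runs, so the selection
frequency separates consistently informative features from fold noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_model import StageDesign, TimeSeriesDataset, MODEL
from .errors import DesignError, InsufficientDataError, AtsdnetError


@dataclass(frozen=True)
class RfeConfig:
    """Knobs of the static filter.

    elim_fraction: fraction of surviving features dropped per iteration
        (at least one is always dropped).
    n_folds / n_repeats: repeated stratified cross-validation protocol
        (default 5-fold x 50 repeats).
    selection_threshold: minimum fraction of repeats in which a feature
        must appear in the best subset to be retained.
    C: penalty parameter of the linear max-margin classifier.
    """

    elim_fraction: float = 0.10
    n_folds: int = 5
    n_repeats: int = 50
    selection_threshold: float = 0.5
    seed: int = 0
    C: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.elim_fraction < 1:
            raise ValueError(f"elim_fraction must be in (0,1), got {self.elim_fraction}")


@dataclass(frozen=True)
class SubproblemSpec:
    """One binary stage-pair classification sub-problem."""

    stage_a: str
    stage_b: str
    time_a: int
    time_b: int


@dataclass
class RfeResult:
    """Outcome of one repeated SVM-RFE run.

    ``ranking`` orders features from most to least important (a feature
    removed later, averaged over repeats, ranks higher).
    ``cv_accuracy_trace`` holds the mean held-out accuracy at each subset
    size along the elimination path (largest size first), and
    ``repeat_best`` the best subset of each repeat.
    """

    ranking: list[int]
    subset_sizes: list[int]
    cv_accuracy_trace: np.ndarray
    repeat_best: list[tuple[int, ...]] = field(default_factory=list)
    selection_frequency: np.ndarray | None = None

    @property
    def elimination_order(self) -> list[int]:
        """Least to most important (reverse of ranking)."""
        return list(reversed(self.ranking))

    @property
    def best_subset(self) -> tuple[int, ...]:
        """Top-ranked features at the size with maximal mean CV accuracy.

        Accuracy ties break toward the smaller subset.
        """
        top = self.cv_accuracy_trace.max()
        # sizes are listed large -> small, so the last hit is the smallest
        k = max(i for i, a in enumerate(self.cv_accuracy_trace) if a == top)
        return tuple(sorted(self.ranking[: self.subset_sizes[k]]))


def enumerate_subproblems(
    ds: TimeSeriesDataset, design: StageDesign
) -> list[SubproblemSpec]:
    """All N_s*(N_s-1)/2 stage-pair sub-problems at typical time points."""
    stages = ds.stages
    if len(stages) < 2:
        raise DesignError(f"need >= 2 stages for static filtering, got {stages}")
    for stage in stages:
        if stage not in design.typical_points:
            raise DesignError(f"stage {stage!r} has no typical point declared")
    specs = []
    for a in range(len(stages)):
        for b in range(a + 1, len(stages)):
            specs.append(
                SubproblemSpec(
                    stage_a=stages[a],
                    stage_b=stages[b],
                    time_a=design.typical_points[stages[a]],
                    time_b=design.typical_points[stages[b]],
                )
            )
    return specs


def _standardize(train: np.ndarray, *apply: np.ndarray):
    """Zero-mean unit-variance scaling fit on ``train``; constant columns pass through."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    out = [(a - mu) / sd for a in (train, *apply)]
    return out[0] if not apply else out


def _drop_lowest(surviving: list[int], w2: np.ndarray, elim_fraction: float) -> list[int]:
    """Indices (positions in ``surviving``) of the features to drop this round.

    Drops ``ceil(elim_fraction * remaining)`` (at least one) features with
    the smallest scores; score ties break by removing the larger canonical
    index first.
    """
    k = max(1, math.ceil(elim_fraction * len(surviving)))
    rank = sorted(range(len(surviving)), key=lambda p: (w2[p], -surviving[p]))
    return sorted(rank[:k], reverse=True)


def elimination_path(
    X: np.ndarray, y: np.ndarray, elim_fraction: float, C: float = 1.0
) -> tuple[list[int], list[tuple[int, ...]]]:
    """Deterministic greedy elimination on the full sample.

    Returns the removal order (least important first) and the surviving
    subsets along the path (largest first).
    """
    surviving = list(range(X.shape[1]))
    order: list[int] = []
    subsets: list[tuple[int, ...]] = []
    while surviving:
        subsets.append(tuple(surviving))
        if len(surviving) == 1:
            order.append(surviving.pop())
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(_standardize(X[:, surviving]), y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        for p in _drop_lowest(surviving, w2, elim_fraction):
            order.append(surviving.pop(p))
    return order, subsets


def _rfe_one_repeat(
    X: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    elim_fraction: float,
    C: float,
) -> tuple[list[int], list[int], list[float]]:
    """One elimination run driven by fold-averaged weights.

    Returns (removal order, subset sizes, held-out accuracy per subset).
    """
    m = X.shape[1]
    surviving = list(range(m))
    order: list[int] = []
    sizes: list[int] = []
    accs: list[float] = []
    while surviving:
        w2 = np.zeros(len(surviving))
        correct = total = 0
        for train, test in splits:
            Ztr, Zte = _standardize(X[np.ix_(train, surviving)], X[np.ix_(test, surviving)])
            clf = SVC(kernel="linear", C=C)
            clf.fit(Ztr, y[train])
            w2 += np.asarray(clf.coef_).ravel() ** 2
            correct += int(np.sum(clf.predict(Zte) == y[test]))
            total += len(test)
        sizes.append(len(surviving))
        accs.append(correct / total)
        if len(surviving) == 1:
            order.append(surviving.pop())
            break
        for p in _drop_lowest(surviving, w2 / len(splits), elim_fraction):
            order.append(surviving.pop(p))
    return order, sizes, accs


def svm_rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    config: RfeConfig = RfeConfig(),
) -> RfeResult:
    """Repeated SVM-RFE ranking of one binary sub-problem.

    Each repeat re-shuffles the stratified folds, re-runs the elimination
    with fold-averaged squared weights, and picks its best subset by
    held-out accuracy (ties to the smaller subset).  The aggregate ranking
    orders features by their mean removal step over repeats (removed later
    = more important; ties to the smaller canonical index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise InsufficientDataError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} sample(s); need >= 2"
        )
    n_folds = min(config.n_folds, int(counts.min()))
    m = X.shape[1]

    removal_step = np.zeros(m)
    freq = np.zeros(m)
    acc_by_size: dict[int, list[float]] = {}
    repeat_best: list[tuple[int, ...]] = []
    sizes_ref: list[int] = []
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=(config.seed * 10_007 + rep) % (2**31 - 1),
        )
        splits = [(tr, te) for tr, te in skf.split(X, y)]
        order, sizes, accs = _rfe_one_repeat(X, y, splits, config.elim_fraction, config.C)
        sizes_ref = sizes
        for step, feat in enumerate(order):
            removal_step[feat] += step
        for s, a in zip(sizes, accs):
            acc_by_size.setdefault(s, []).append(a)
        best_acc = max(accs)
        pick = max(i for i, a in enumerate(accs) if a == best_acc)  # smallest size
        best = tuple(sorted(order[m - sizes[pick]:]))  # survivors at that step
        repeat_best.append(best)
        freq[list(best)] += 1

    ranking = sorted(range(m), key=lambda f: (-removal_step[f], f))
    trace = np.array([float(np.mean(acc_by_size[s])) for s in sizes_ref])
    return RfeResult(
        ranking=ranking,
        subset_sizes=sizes_ref,
        cv_accuracy_trace=trace,
        repeat_best=repeat_best,
        selection_frequency=freq / config.n_repeats,
    )


def subproblem_data(
    ds: TimeSeriesDataset, spec: SubproblemSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Model-group samples at the two typical time points, stage labels as y."""
    Xa = ds.values_at(spec.time_a, MODEL)
    Xb = ds.values_at(spec.time_b, MODEL)
    X = np.vstack([Xa, Xb])
    y = np.array([spec.stage_a] * len(Xa) + [spec.stage_b] * len(Xb))
    return X, y


def retained_features(
    ds: TimeSeriesDataset,
    design: StageDesign,
    config: RfeConfig = RfeConfig(),
) -> list[str]:
    """Union over sub-problems of the frequently-selected features.

    Per sub-problem, a feature is selected when it appears in at least
    ``selection_threshold`` of the repeats' best subsets; the selections of
    all sub-problems are united and returned in canonical feature order.
    """
    union: set[int] = set()
    for s_idx, spec in enumerate(enumerate_subproblems(ds, design)):
        X, y = subproblem_data(ds, spec)
        sub_cfg = RfeConfig(
            elim_fraction=config.elim_fraction,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats,
            selection_threshold=config.selection_threshold,
            seed=config.seed + 131 * s_idx,
            C=config.C,
        )
        result = svm_rfe_rank(X, y, sub_cfg)
        union |= set(
            np.flatnonzero(result.selection_frequency >= config.selection_threshold).tolist()
        )
    if not union:
        raise AtsdnetError(
            "no feature was selected in any sub-problem; "
            "consider lowering selection_threshold"
        )
    names = ds.feature_names
    return [names[i] for i in sorted(union)]
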