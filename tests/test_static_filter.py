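import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from atsdnet.data_model import StageDesign
from atsdnet.errors import DesignError, InsufficientDataError
from atsdnet.static_filter import (
    RfeConfig,
    elimination_path,
    enumerate_subproblems,
    retained_features,
    subproblem_data,
    svm_rfe_rank,
)
from atsdnet.synthetic_data import GeneratorConfig, generate

from conftest import make_dataset


def two_stage_dataset(n_stages):
    """Minimal dataset with n_stages one-point stages, 2 subjects each."""
    times = list(range(1, n_stages + 1))
    stage_map = {t: f"S{t}" for t in times}
    vals = {f: {t: [1.0 + t, 2.0 + t] for t in times} for f in ("a", "b")}
    return make_dataset(vals, stage_map)


class TestEnumerateSubproblems:
    @pytest.mark.parametrize("n_stages,expected", [(2, 1), (3, 3), (4, 6)])
    def test_pair_count_formula(self, n_stages, expected):
        ds = two_stage_dataset(n_stages)
        design = StageDesign(
            typical_points={f"S{t}": t for t in range(1, n_stages + 1)},
            onset_point=n_stages,
            lookback=1,
        )
        specs = enumerate_subproblems(ds, design)
        assert len(specs) == expected

    def test_discovery_stage_pairs(self, discovery_cohort, discovery_design):
        ds, _ = discovery_cohort
        specs = enumerate_subproblems(ds, discovery_design)
        pairs = {(s.stage_a, s.stage_b) for s in specs}
        assert pairs == {("H", "CIR"), ("H", "HCC"), ("CIR", "HCC")}
        assert {(s.time_a, s.time_b) for s in specs} == {(1, 4), (1, 7), (4, 7)}

    def test_missing_typical_point(self, discovery_cohort):
        ds, _ = discovery_cohort
        design = StageDesign(typical_points={"H": 1, "CIR": 4}, onset_point=7, lookback=3)
        with pytest.raises(DesignError, match="HCC"):
            enumerate_subproblems(ds, design)


def single_feature_cv_ranking(X, y, seed=0):
    """Independent oracle: rank features by their solo CV accuracy."""
    accs = []
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    for f in range(X.shape[1]):
        fold_accs = []
        for tr, te in skf.split(X, y):
            col = X[:, [f]]
            mu, sd = col[tr].mean(), col[tr].std() or 1.0
            clf = SVC(kernel="linear", C=1.0)
            clf.fit((col[tr] - mu) / sd, y[tr])
            fold_accs.append(np.mean(clf.predict((col[te] - mu) / sd) == y[te]))
        accs.append(np.mean(fold_accs))
    return np.argsort(accs)[::-1]


class TestSvmRfeRank:
    def test_informative_feature_survives_longest(self):
        """One label-carrying feature among noise ends up top-ranked in
        almost every independent run, agreeing with the solo-CV oracle."""
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 5))
        X[:, 0] = y + rng.normal(scale=0.3, size=20)
        assert single_feature_cv_ranking(X, y)[0] == 0  # oracle agrees f1 is best
        wins = 0
        for seed in range(50):
            res = svm_rfe_rank(X, y, RfeConfig(n_repeats=1, seed=seed))
            wins += res.ranking[0] == 0
        assert wins >= 45

    def test_single_feature_boundary(self):
        y = np.repeat([0, 1], 3)
        X = np.arange(6, dtype=float).reshape(-1, 1)
        res = svm_rfe_rank(X, y, RfeConfig(n_repeats=2, n_folds=2))
        assert res.ranking == [0]
        assert res.best_subset == (0,)

    def test_best_subset_matches_exhaustive_oracle(self):
        """Only f2 separates the classes: every subset's exact CV accuracy
        (enumerated independently) is maximal exactly when f2 is present
        and alone wins the smaller-subset tie-break."""
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 8)
        X = np.column_stack([rng.normal(size=16), y * 4.0 + rng.normal(scale=0.1, size=16)])

        def subset_cv_acc(cols, seed=3):
            skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=seed)
            accs = []
            for tr, te in skf.split(X, y):
                sub = X[:, cols]
                mu, sd = sub[tr].mean(0), sub[tr].std(0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="linear", C=1.0)
                clf.fit((sub[tr] - mu) / sd, y[tr])
                accs.append(np.mean(clf.predict((sub[te] - mu) / sd) == y[te]))
            return np.mean(accs)

        oracle = {cols: subset_cv_acc(list(cols)) for cols in [(0,), (1,), (0, 1)]}
        assert oracle[(1,)] == 1.0 and oracle[(0, 1)] == 1.0 and oracle[(0,)] < 1.0
        res = svm_rfe_rank(X, y, RfeConfig(n_repeats=5, n_folds=4, seed=0))
        assert res.best_subset == (1,)

    def test_requires_two_samples_per_class(self):
        X = np.ones((3, 2))
        y = np.array([0, 0, 1])
        with pytest.raises(InsufficientDataError):
            svm_rfe_rank(X, y)

    def test_elimination_path_terminates_and_covers_all(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 17))
        y = np.repeat([0, 1], 6)
        order, subsets = elimination_path(X, y, elim_fraction=0.25)
        assert sorted(order) == list(range(17))
        assert len(subsets[0]) == 17 and len(subsets[-1]) == 1
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes, reverse=True)


class TestRetainedFeatures:
    def test_reproducible_from_seed(self, single_pair_cohort, discovery_design):
        ds, _ = single_pair_cohort
        cfg = RfeConfig(n_repeats=5, seed=3)
        a = retained_features(ds, discovery_design, cfg)
        b = retained_features(ds, discovery_design, cfg)
        assert a == b

    def test_planted_features_enriched(self, discovery_design):
        """Planted biomarker features are retained far above the nuisance
        rate, and some planted feature survives in every seed."""
        planted_hits = nuisance_hits = planted_n = nuisance_n = 0
        seeds_with_planted = 0
        for seed in range(5):
            ds, man = generate(GeneratorConfig(m=20, n_planted_pairs=2, seed=seed))
            kept = set(retained_features(ds, discovery_design, RfeConfig(n_repeats=10)))
            planted = set(man["planted_features"])
            nuisance = set(ds.feature_names) - planted
            planted_hits += len(kept & planted)
            nuisance_hits += len(kept & nuisance)
            planted_n += len(planted)
            nuisance_n += len(nuisance)
            seeds_with_planted += bool(kept & planted)
        assert seeds_with_planted == 5
        assert planted_hits / planted_n > 2 * (nuisance_hits / nuisance_n)

    def test_ranking_is_permutation(self, single_pair_cohort, discovery_design):
        ds, _ = single_pair_cohort
        spec = enumerate_subproblems(ds, discovery_design)[2]  # CIR vs HCC
        X, y = subproblem_data(ds, spec)
        res = svm_rfe_rank(X, y, RfeConfig(n_repeats=3))
        assert sorted(res.ranking) == list(range(ds.n_features))
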