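import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

from polyrank import (
    DEFAULT_C_GRID,
    RankModel,
    RankSVM,
    build_preferences,
    select_C,
    train,
    unified_ranking,
)
from polyrank.data import DegradationDataset, Polymer
from polyrank.errors import (
    ConfigurationError,
    SchemeMismatchError,
    ValidationError,
)
from polyrank.featurize import FingerprintSet
from polyrank.ranksvm import PreferencePair, PreferenceSet

from conftest import make_linear_instance


def brute_force_pairs(values):
    """Independent enumerator: count value-distinct unordered pairs."""
    pairs = [
        (i, j)
        for i, j in itertools.combinations(range(len(values)), 2)
        if values[i] != values[j]
    ]
    return pairs


def synthetic_preferences(seed, n_items=10, dim=12):
    X, w, s, diffs, labels = make_linear_instance(seed, n_items, dim)
    ij = list(itertools.combinations(range(n_items), 2))
    pairs = [
        PreferencePair(
            x1=diffs[k] + 0.0, x2=np.zeros(dim), t=int(labels[k]),
            dataset_id="syn", id1=f"i{ij[k][0]}", id2=f"i{ij[k][1]}",
        )
        for k in range(len(labels))
    ]
    return X, s, PreferenceSet(pairs=pairs, dataset_ids=("syn",))


class TestBuildPreferences:
    def test_counts_match_brute_force_on_study_data(self, fixtures, fixture_fps):
        expected = {"literature": 275, "exp1": 21, "exp2": 28}
        for name, ds in fixtures.items():
            ps = build_preferences(ds, fixture_fps)
            assert len(ps) == len(brute_force_pairs(ds.values)) == expected[name]
            # rejected + accepted = all unordered pairs
            n = len(ds)
            assert len(ps) + ps.n_tied == n * (n - 1) // 2

    def test_orientation_and_label(self, fixtures, fixture_fps):
        lit = fixtures["literature"]
        ps = build_preferences(lit, fixture_fps)
        by_ids = {(p.id1, p.id2): p.t for p in ps}
        # PET (0.0003) listed before PLA (0.00033): polymer 1 is the less
        # degradable of the two, so t = -1
        assert by_ids[("literature:PET", "literature:PLA")] == -1

    def test_single_polymer_dataset_yields_no_pairs(self):
        p = Polymer(id="d:A", name="A", abbreviation="A", smiles="*CC*", dataset_id="d")
        ds = DegradationDataset(id="d", records=[(p, 1.0)])
        fps = FingerprintSet("s", {"d:A": np.zeros(3)})
        assert len(build_preferences(ds, fps)) == 0


class TestRankSVM:
    def test_separable_pairs_fit_perfectly_at_large_C(self):
        _, _, prefs = synthetic_preferences(seed=0)
        X, y = prefs.to_arrays()
        svm = RankSVM(C=100.0).fit(X, y)
        assert svm.score(X, y) == 1.0

    def test_weight_norm_vanishes_as_C_to_zero(self):
        _, _, prefs = synthetic_preferences(seed=1)
        X, y = prefs.to_arrays()
        norms = [np.linalg.norm(RankSVM(C=c).fit(X, y).coef_) for c in (1e-2, 1e-4, 1e-6)]
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-3

    def test_antisymmetry_and_score_difference_identity(self, rng):
        _, _, prefs = synthetic_preferences(seed=2)
        model = train(prefs, C=1.0, scheme_id="syn")
        for _ in range(20):
            a, b = rng.normal(size=(2, 12))
            y_ab = model.predict_preference(a, b)
            assert y_ab == pytest.approx(-model.predict_preference(b, a))
            assert y_ab == pytest.approx(model.score(a) - model.score(b))

    def test_zero_weights_score_zero(self):
        model = RankModel(w=np.zeros(5), C=1.0, scheme_id="s")
        assert model.score(np.ones(5)) == 0.0

    def test_invalid_labels_and_nonfinite_inputs_rejected(self):
        with pytest.raises(ValidationError):
            RankSVM(C=1.0).fit(np.eye(3), np.array([1, 0, -1]))
        bad = np.eye(3)
        bad[0, 0] = np.nan
        with pytest.raises(Exception):
            RankSVM(C=1.0).fit(bad, np.array([1, -1, 1]))

    def test_duality_gap_certificate_recorded(self):
        _, _, prefs = synthetic_preferences(seed=3)
        X, y = prefs.to_arrays()
        svm = RankSVM(C=1.0).fit(X, y)
        assert 0.0 <= svm.duality_gap_ < 1e-3


class TestInvariances:
    def test_translation_of_all_fingerprints_preserves_ranking(self):
        X, s, prefs = synthetic_preferences(seed=4)
        model = train(prefs, C=1.0, scheme_id="syn")
        shift = np.full(X.shape[1], 7.3)
        d0 = np.array([model.score(x) for x in X])
        d1 = np.array([model.score(x + shift) for x in X])
        assert np.array_equal(np.argsort(-d0), np.argsort(-d1))
        np.testing.assert_allclose(np.diff(d0), np.diff(d1), rtol=1e-8)

    def test_positive_scaling_scales_scores_and_preserves_order(self):
        X, s, prefs = synthetic_preferences(seed=5)
        model = train(prefs, C=1.0, scheme_id="syn")
        d = model.scores(X)
        np.testing.assert_allclose(model.scores(3.0 * X), 3.0 * d, rtol=1e-10)


class TestSelectC:
    def test_singleton_grid_returned(self):
        _, _, prefs = synthetic_preferences(seed=6)
        cv = select_C(prefs, grid=[0.25], n_folds=5, seed=0)
        assert cv.best_C == 0.25

    def test_consistent_noiseless_pairs_reach_high_accuracy(self):
        _, _, prefs = synthetic_preferences(seed=7, n_items=12)
        cv = select_C(prefs, grid=[0.01, 1.0, 100.0], n_folds=5, seed=0)
        assert max(cv.accuracy_by_C.values()) >= 0.95

    def test_deterministic_given_seed(self):
        _, _, prefs = synthetic_preferences(seed=8)
        cv1 = select_C(prefs, grid=[0.1, 1.0], seed=3)
        cv2 = select_C(prefs, grid=[0.1, 1.0], seed=3)
        assert cv1.accuracy_by_C == cv2.accuracy_by_C and cv1.best_C == cv2.best_C

    def test_empty_grid_rejected(self):
        _, _, prefs = synthetic_preferences(seed=9)
        with pytest.raises(ConfigurationError):
            select_C(prefs, grid=[])

    def test_default_grid_contains_the_study_optimum(self):
        assert 0.007 in DEFAULT_C_GRID
        assert len(DEFAULT_C_GRID) == 13

    def test_grouped_splitter_keeps_duplicated_pairs_together(self):
        X, s, prefs = synthetic_preferences(seed=10)
        doubled = prefs + prefs  # same polymer pairs observed in two datasets
        cv = select_C(doubled, grid=[1.0], n_folds=5, seed=0, group_by_polymer_pair=True)
        assert 0.0 <= cv.accuracy_by_C[1.0] <= 1.0


class TestUnifiedRanking:
    def _dataset(self, X, s):
        polymers = [
            Polymer(id=f"d:P{i}", name=f"P{i}", abbreviation=f"P{i}",
                    smiles="*" + "C" * (i + 1) + "*", dataset_id="d")
            for i in range(len(s))
        ]
        records = [(p, float(v - s.min())) for p, v in zip(polymers, s)]
        ds = DegradationDataset(id="d", records=records)
        fps = FingerprintSet("syn", {p.id: X[i] for i, p in enumerate(polymers)})
        return ds, fps

    def test_minmax_normalization_is_order_preserving_affine(self):
        X, w, s, diffs, labels = make_linear_instance(seed=11, n_items=8)
        ds, fps = self._dataset(X, s)
        prefs = build_preferences(ds, fps)
        model = train(prefs, C=1.0, scheme_id="syn")
        raw = unified_ranking(model, ds.polymers, fps, normalization="raw")
        mm = unified_ranking(model, ds.polymers, fps, normalization="minmax")
        assert [e.polymer.id for e in raw] == [e.polymer.id for e in mm]
        norms = [e.d_norm for e in mm]
        assert min(norms) == pytest.approx(0.0) and max(norms) == pytest.approx(1.0)

    def test_kendall_tau_equals_pairwise_accuracy_mapping(self):
        """On one dataset, tau(predicted, measured) = 2*accuracy - 1."""
        X, w, s, diffs, labels = make_linear_instance(seed=12, n_items=6)
        ds, fps = self._dataset(X, s)
        prefs = build_preferences(ds, fps)
        model = train(prefs, C=0.05, scheme_id="syn")
        d = np.array([model.score(fps[p.id]) for p in ds.polymers])
        values = np.array(ds.values)
        # brute-force pairwise accuracy
        correct = total = 0
        for i, j in itertools.combinations(range(len(ds)), 2):
            if values[i] == values[j]:
                continue
            total += 1
            correct += (d[i] - d[j]) * (values[i] - values[j]) > 0
        tau = kendalltau(d, values).statistic
        assert tau == pytest.approx(2 * correct / total - 1)

    def test_scheme_mismatch_rejected(self):
        X, w, s, diffs, labels = make_linear_instance(seed=13, n_items=5)
        ds, fps = self._dataset(X, s)
        model = train(build_preferences(ds, fps), C=1.0, scheme_id="other-scheme")
        with pytest.raises(SchemeMismatchError):
            unified_ranking(model, ds.polymers, fps)

    def test_model_roundtrip_through_json(self, tmp_path):
        model = RankModel(
            w=np.arange(5.0), C=0.007, scheme_id="default-hashed",
            training_meta={"M": 3},
        )
        model.set_normalization([0.0, 2.0])
        path = tmp_path / "model.json"
        model.save(path)
        back = RankModel.load(path)
        np.testing.assert_array_equal(back.w, model.w)
        assert back.C == model.C and back.scheme_id == model.scheme_id
        assert back.norm_min == 0.0 and back.norm_max == 2.0
        assert back.normalize(1.0) == pytest.approx(0.5)
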