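import itertools

import numpy as np
import pytest

from leafhair.manifest import Manifest, ScoreClass, parse_score_label
from leafhair.score import (
    PredictionSet,
    adjacent_error_analysis,
    assign_leaf_score,
    build_report,
    first_image_accuracy,
    image_accuracy,
    leaf_accuracy,
    normalized_confusion,
)

from conftest import make_leaf


def preds_for(manifest: Manifest, predicted: dict[str, str]) -> PredictionSet:
    by_id = manifest.by_image_id()
    entries = tuple(
        (i, by_id[i].score, parse_score_label(predicted[i])) for i in sorted(predicted)
    )
    return PredictionSet(entries)


def full_prediction_set(manifest: Manifest, correct_ids: set[str], wrong_label: str) -> PredictionSet:
    by_id = manifest.by_image_id()
    entries = []
    for i in manifest.image_ids:
        true = by_id[i].score
        pred = true if i in correct_ids else parse_score_label(wrong_label)
        entries.append((i, true, pred))
    return PredictionSet(tuple(entries))


class TestImageAccuracy:
    def test_all_correct(self, toy_manifest):
        preds = full_prediction_set(toy_manifest, set(toy_manifest.image_ids), "1")
        assert image_accuracy(preds) == 1.0

    def test_three_of_four(self):
        sc = ScoreClass.from_rank
        entries = tuple(
            (f"i{k}", sc(2), sc(2) if k < 3 else sc(4)) for k in range(4)
        )
        assert image_accuracy(PredictionSet(entries)) == 0.75

    def test_permutation_invariant(self):
        sc = ScoreClass.from_rank
        entries = [(f"i{k}", sc(k % 3), sc((k + 1) % 3)) for k in range(10)]
        a = image_accuracy(PredictionSet(tuple(entries)))
        b = image_accuracy(PredictionSet(tuple(reversed(entries))))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            image_accuracy(PredictionSet(()))

    def test_duplicate_ids_rejected(self):
        sc = ScoreClass.from_rank
        with pytest.raises(ValueError):
            PredictionSet((("a", sc(0), sc(0)), ("a", sc(1), sc(1))))


class TestFirstImageAccuracy:
    def _manifest(self, n_leaves=10):
        records = []
        for i in range(n_leaves):
            records.extend(make_leaf(f"leaf{i:02d}", 4, score="3"))
        return Manifest(tuple(records))

    def test_nine_of_ten_first_images(self):
        m = self._manifest(10)
        predicted = {}
        firsts = [r.image_id for r in m.records if r.is_first]
        for r in m.records:
            predicted[r.image_id] = "3"
        predicted[firsts[0]] = "4"  # one wrong first image
        assert first_image_accuracy(preds_for(m, predicted), m) == 0.9

    def test_independent_of_non_first_predictions(self):
        m = self._manifest(5)
        base = {r.image_id: "3" for r in m.records}
        scrambled = dict(base)
        for r in m.records:
            if not r.is_first:
                scrambled[r.image_id] = "5+"
        fia_a = first_image_accuracy(preds_for(m, base), m)
        fia_b = first_image_accuracy(preds_for(m, scrambled), m)
        assert fia_a == fia_b == 1.0

    def test_single_image_leaves(self):
        records = make_leaf("a", 1, score="4") + make_leaf("b", 1, score="4")
        m = Manifest(tuple(records))
        predicted = {r.image_id: "4" for r in m.records}
        assert first_image_accuracy(preds_for(m, predicted), m) == 1.0

    def test_denominator_is_leaf_count(self):
        m = self._manifest(4)
        predicted = {r.image_id: "3" for r in m.records}
        preds = preds_for(m, predicted)
        firsts = [e for e in preds.entries if m.by_image_id()[e[0]].is_first]
        assert len(firsts) == 4

    def test_missing_first_image_rejected(self):
        m = self._manifest(3)
        predicted = {r.image_id: "3" for r in m.records if not r.is_first}
        with pytest.raises(ValueError, match="is_first"):
            first_image_accuracy(preds_for(m, predicted), m)


def brute_force_leaf_score(predictions: list[ScoreClass]) -> ScoreClass:
    """Independent oracle: try every class as candidate, keep those with
    maximal count, then the smallest-ranked among them."""
    best = None
    for candidate in sorted(set(predictions), key=lambda s: s.rank):
        count = sum(1 for p in predictions if p == candidate)
        if best is None or count > best[0]:
            best = (count, candidate)
    return best[1]


class TestLeafScoreAssignment:
    def test_unique_mode(self):
        preds = [parse_score_label(s) for s in ("4", "4", "4+")]
        assert assign_leaf_score(preds).label == "4"

    def test_two_way_tie_smallest(self):
        preds = [parse_score_label(s) for s in ("3", "3", "4", "4")]
        assert assign_leaf_score(preds).label == "3"

    def test_three_way_tie_smallest(self):
        preds = [parse_score_label(s) for s in ("3/4", "4", "4+")]
        assert assign_leaf_score(preds).label == "3/4"

    def test_exhaustive_against_brute_force(self):
        # all multisets of size <= 5 over 3 classes
        classes = [ScoreClass.from_rank(r) for r in (1, 4, 7)]
        for size in range(1, 6):
            for combo in itertools.combinations_with_replacement(classes, size):
                preds = list(combo)
                assert assign_leaf_score(preds) == brute_force_leaf_score(preds), preds

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_leaf_score([])


class TestLeafAccuracy:
    def test_majority_fixes_scattered_errors(self):
        records = make_leaf("leafA", 5, score="4")
        m = Manifest(tuple(records))
        predicted = {r.image_id: "4" for r in records}
        predicted[records[2].image_id] = "4+"
        la, assigned = leaf_accuracy(preds_for(m, predicted), m)
        assert la == 1.0
        assert assigned["leafA"].label == "4"

    def test_tie_goes_to_smaller(self):
        records = make_leaf("leafA", 4, score="4")
        m = Manifest(tuple(records))
        predicted = {records[i].image_id: ("3" if i < 2 else "4") for i in range(4)}
        la, assigned = leaf_accuracy(preds_for(m, predicted), m)
        assert assigned["leafA"].label == "3"
        assert la == 0.0


class TestNormalizedConfusion:
    def test_perfect_predictions_identity_pattern(self):
        sc = ScoreClass.from_rank
        pairs = [(sc(r), sc(r)) for r in range(9) for _ in range(3)]
        conf = normalized_confusion(pairs)
        mat = np.array(conf["matrix"])
        assert np.allclose(mat, np.eye(9))

    def test_rows_sum_to_one_for_present_classes(self):
        rng = np.random.default_rng(0)
        sc = ScoreClass.from_rank
        pairs = [(sc(int(rng.integers(0, 5))), sc(int(rng.integers(0, 9)))) for _ in range(200)]
        conf = normalized_confusion(pairs)
        mat = np.array(conf["matrix"])
        for r in range(9):
            expected = 0.0 if conf["labels"][r] in conf["absent_classes"] else 1.0
            assert np.isclose(mat[r].sum(), expected)

    def test_two_class_arithmetic(self):
        sc = ScoreClass.from_rank
        pairs = [(sc(0), sc(0))] * 8 + [(sc(0), sc(1))] * 2 + [(sc(1), sc(0))] * 1 + [
            (sc(1), sc(1))
        ] * 9
        mat = np.array(normalized_confusion(pairs)["matrix"])
        assert np.allclose(mat[0, :2], [0.8, 0.2])
        assert np.allclose(mat[1, :2], [0.1, 0.9])

    def test_matches_sklearn(self):
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(7)
        sc = ScoreClass.from_rank
        true = rng.integers(0, 9, 300)
        pred = rng.integers(0, 9, 300)
        pairs = [(sc(int(t)), sc(int(p))) for t, p in zip(true, pred)]
        mine = np.array(normalized_confusion(pairs)["matrix"])
        ref = confusion_matrix(true, pred, labels=range(9), normalize="true")
        assert np.allclose(mine, np.nan_to_num(ref))


class TestAdjacentErrorAnalysis:
    def test_all_correct(self):
        sc = ScoreClass.from_rank
        preds = PredictionSet(tuple((f"i{k}", sc(2), sc(2)) for k in range(5)))
        assert adjacent_error_analysis(preds) == (0.0, 0.0, 0.0)

    def test_single_off_by_one(self):
        sc = ScoreClass.from_rank
        entries = [(f"i{k}", sc(3), sc(3)) for k in range(9)] + [("iX", sc(3), sc(4))]
        assert adjacent_error_analysis(PredictionSet(tuple(entries))) == (0.1, 0.1, 0.0)

    def test_conservation_randomized(self):
        # oracle: mispredicted = within-1 + beyond, for 1000 random sets
        rng = np.random.default_rng(11)
        sc = ScoreClass.from_rank
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            entries = tuple(
                (f"i{k}", sc(int(rng.integers(0, 9))), sc(int(rng.integers(0, 9))))
                for k in range(n)
            )
            wrong, within, beyond = adjacent_error_analysis(PredictionSet(entries))
            assert np.isclose(wrong, within + beyond)
            assert np.isclose(wrong, 1.0 - image_accuracy(PredictionSet(entries)))


class TestBuildReport:
    def test_report_fields_consistent(self):
        records = []
        for i in range(6):
            records.extend(make_leaf(f"leaf{i}", 4, score="4" if i % 2 else "3"))
        m = Manifest(tuple(records))
        predicted = {r.image_id: r.score.label for r in m.records}
        # corrupt two images of one leaf
        ids = [r.image_id for r in m.records if r.leaf_id == "leaf0"]
        predicted[ids[1]] = "5"
        predicted[ids[2]] = "5"
        report = build_report(preds_for(m, predicted), m)
        assert 0 < report.IA < 1
        assert report.LA == 1.0  # majority still right
        assert np.isclose(
            report.misprediction_fraction,
            report.adjacent_error_fraction + report.off_by_more_fraction,
        )
        assert report.leaf_scores["leaf0"] == "3"
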