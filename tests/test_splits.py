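import numpy as np
import pytest

from leafhair.manifest import Manifest
from leafhair.splits import (
    DatasetSplit,
    group_by_leaf,
    kfold_pairs,
    load_split,
    make_factor_splits,
    make_split,
    make_whole_split,
    save_split,
    split_report,
)

from conftest import make_leaf


def grid_manifest(n_leaves_per_cell=3, n_images=10) -> Manifest:
    """Manifest with leaves in every (year, env, leaf_number) cell."""
    records = []
    scores = ["1", "3", "4", "4+", "5+"]
    for year in ("Y1", "Y2"):
        for env in ("GH", "FD"):
            for leaf_number in (3, 4):
                for i in range(n_leaves_per_cell):
                    score = scores[i % len(scores)]
                    records.extend(
                        make_leaf(
                            f"{year}-{env}-L{leaf_number}-{i}",
                            n_images,
                            score=score,
                            genotype=f"geno-{score}",
                            year=year,
                            environment=env,
                            leaf_number=leaf_number,
                        )
                    )
    return Manifest(tuple(records))


class TestGroupByLeaf:
    def test_partition(self):
        m = grid_manifest()
        groups = group_by_leaf(m, m.image_ids)
        assert sum(len(g) for g in groups) == len(m)
        assert len(groups) == len(m.leaf_groups())

    def test_empty_candidates(self):
        assert group_by_leaf(grid_manifest(), set()) == []

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError):
            group_by_leaf(grid_manifest(), {"nope"})


class TestMakeSplit:
    def test_ten_groups_two_test(self):
        records = []
        for i in range(10):
            records.extend(make_leaf(f"leaf{i}", 5))
        m = Manifest(tuple(records))
        split = make_split(m, m.image_ids, 0.2, seed=0)
        report = split_report(split, m)
        assert report["test"]["n_leaves"] == 2
        assert report["train"]["n_leaves"] == 8

    def test_same_seed_identical(self):
        m = grid_manifest()
        a = make_split(m, m.image_ids, 0.2, seed=5)
        b = make_split(m, m.image_ids, 0.2, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_row_order_invariance(self):
        m = grid_manifest()
        shuffled = Manifest(tuple(np.random.default_rng(1).permutation(np.array(m.records, dtype=object))))
        a = make_split(m, m.image_ids, 0.2, seed=5)
        b = make_split(shuffled, shuffled.image_ids, 0.2, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_leaf_exclusivity(self):
        m = grid_manifest()
        split = make_whole_split(m, 0.2, seed=3)
        by_id = m.by_image_id()
        train_leaves = {by_id[i].leaf_id for i in split.train_ids}
        test_leaves = {by_id[i].leaf_id for i in split.test_ids}
        assert not train_leaves & test_leaves

    def test_extra_train_ids_excluded_from_test(self):
        m = grid_manifest()
        l3 = {r.image_id for r in m.records if r.leaf_number == 3}
        l4 = {r.image_id for r in m.records if r.leaf_number == 4}
        split = make_split(m, l3, 0.2, seed=0, extra_train_ids=l4, name="L3L4/L3")
        by_id = m.by_image_id()
        assert all(by_id[i].leaf_number == 3 for i in split.test_ids)
        assert l4 <= split.train_ids

    def test_too_few_groups_rejected(self):
        m = Manifest(tuple(make_leaf("only", 5)))
        with pytest.raises(ValueError, match="2 leaf groups"):
            make_split(m, m.image_ids, 0.2, seed=0)

    def test_bad_fraction_rejected(self):
        m = grid_manifest()
        with pytest.raises(ValueError):
            make_split(m, m.image_ids, 0.0, seed=0)

    def test_overlapping_train_test_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DatasetSplit("bad", frozenset({"a"}), frozenset({"a"}), 0)


class TestFactorSplits:
    def test_leaf_factor_names(self):
        splits = make_factor_splits(grid_manifest(), "leaf_number", seed=0)
        assert [s.name for s in splits] == [
            "L3L4/L3", "L3L4/L4", "L3/L3", "L4/L4", "L3/L4", "L4/L3",
        ]

    @pytest.mark.parametrize("factor", ["leaf_number", "year", "environment"])
    def test_six_splits_all_leaf_exclusive(self, factor):
        m = grid_manifest()
        by_id = m.by_image_id()
        splits = make_factor_splits(m, factor, seed=1)
        assert len(splits) == 6
        for s in splits:
            train_leaves = {by_id[i].leaf_id for i in s.train_ids}
            test_leaves = {by_id[i].leaf_id for i in s.test_ids}
            assert not train_leaves & test_leaves, s.name

    def test_inter_environment_all_fd_in_test(self):
        m = grid_manifest()
        splits = {s.name: s for s in make_factor_splits(m, "environment", seed=0)}
        fd_ids = {r.image_id for r in m.records if r.environment == "FD"}
        gh_ids = {r.image_id for r in m.records if r.environment == "GH"}
        assert splits["GH/FD"].test_ids == fd_ids
        assert splits["GH/FD"].train_ids == gh_ids
        assert splits["FD/GH"].test_ids == gh_ids

    def test_mixed_split_train_larger_than_whole(self):
        m = grid_manifest()
        whole = make_whole_split(m, 0.2, seed=2)
        for s in make_factor_splits(m, "leaf_number", seed=2)[:2]:
            assert len(s.train_ids) >= len(whole.train_ids)

    def test_inter_year_reduction_excludes_single_year_class(self):
        # class "2" exists only in Y2: its images must vanish from both sides
        records = list(grid_manifest().records)
        records.extend(
            make_leaf("extra-y2-2", 6, score="2", genotype="geno-2", year="Y2",
                      environment="GH")
        )
        m = Manifest(tuple(records))
        splits = {s.name: s for s in make_factor_splits(m, "year", seed=0)}
        by_id = m.by_image_id()
        for name in ("Y1/Y2", "Y2/Y1"):
            s = splits[name]
            labels = {by_id[i].score.label for i in s.train_ids | s.test_ids}
            assert "2" not in labels

    def test_inter_year_reduction_excludes_single_year_genotype(self):
        records = list(grid_manifest().records)
        records.extend(
            make_leaf("y1-only-geno", 6, score="3", genotype="rare", year="Y1",
                      environment="GH")
        )
        m = Manifest(tuple(records))
        splits = {s.name: s for s in make_factor_splits(m, "year", seed=0)}
        by_id = m.by_image_id()
        s = splits["Y1/Y2"]
        genos = {by_id[i].genotype for i in s.train_ids | s.test_ids}
        assert "rare" not in genos

    def test_inter_year_class_sets_equal(self):
        m = grid_manifest()
        splits = {s.name: s for s in make_factor_splits(m, "year", seed=0)}
        report = split_report(splits["Y1/Y2"], m)
        assert report["class_sets_equal"]

    def test_absent_category_rejected(self):
        records = tuple(make_leaf("a", 3, year="Y1") + make_leaf("b", 3, year="Y1"))
        with pytest.raises(ValueError, match="absent"):
            make_factor_splits(Manifest(records), "year", seed=0)

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            make_factor_splits(grid_manifest(), "site", seed=0)


class TestKFold:
    def test_coverage_fractions(self):
        # 10-per-leaf images, 20 leaves: 80% parent train = 16 leaves;
        # 20% validation = 3.2 -> round-half-up 3 leaves = 30 images
        records = []
        for i in range(20):
            records.extend(make_leaf(f"leaf{i:02d}", 10))
        m = Manifest(tuple(records))
        parent = make_whole_split(m, 0.2, seed=0)
        pairs = kfold_pairs(m, parent, k=10, val_fraction=0.2, seed=0)
        assert len(pairs) == 10
        for p in pairs:
            assert p.validation_ids | p.fold_train_ids == parent.train_ids
            assert len(p.validation_ids) == 30

    def test_k1_single_pair(self):
        m = grid_manifest()
        parent = make_whole_split(m, 0.2, seed=0)
        assert len(kfold_pairs(m, parent, k=1, val_fraction=0.2, seed=0)) == 1

    def test_leaf_exclusive_within_pairs(self):
        m = grid_manifest()
        by_id = m.by_image_id()
        parent = make_whole_split(m, 0.2, seed=0)
        for p in kfold_pairs(m, parent, k=5, val_fraction=0.2, seed=0):
            val_leaves = {by_id[i].leaf_id for i in p.validation_ids}
            train_leaves = {by_id[i].leaf_id for i in p.fold_train_ids}
            assert not val_leaves & train_leaves

    def test_resamples_differ(self):
        m = grid_manifest()
        parent = make_whole_split(m, 0.2, seed=0)
        pairs = kfold_pairs(m, parent, k=10, val_fraction=0.2, seed=0)
        assert len({p.validation_ids for p in pairs}) > 1

    def test_bad_val_fraction_rejected(self):
        m = grid_manifest()
        parent = make_whole_split(m, 0.2, seed=0)
        with pytest.raises(ValueError):
            kfold_pairs(m, parent, k=2, val_fraction=1.0, seed=0)


class TestSplitReport:
    def test_train_fraction_near_80(self):
        records = []
        for i in range(50):
            records.extend(make_leaf(f"leaf{i:02d}", 10))
        m = Manifest(tuple(records))
        report = split_report(make_whole_split(m, 0.2, seed=1), m)
        assert abs(report["train_fraction"] - 0.8) < 0.05

    def test_empty_test_flagged(self):
        m = grid_manifest()
        s = DatasetSplit("odd", frozenset(m.image_ids), frozenset(), 0)
        assert "empty test set" in split_report(s, m)["errors"]

    def test_json_roundtrip(self, tmp_path):
        m = grid_manifest()
        s = make_whole_split(m, 0.2, seed=4)
        path = str(tmp_path / "s.json")
        save_split(s, path)
        again = load_split(path)
        assert again == s
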