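import itertools

import numpy as np
import pytest

from cdrscreen.dataset import (
    DatasetSplit,
    PairLabel,
    SplitSpec,
    complement_pool,
    compound_held_out_split,
    disease_held_out_split,
    make_ratio_datasets,
    read_pairs,
    read_split_manifest,
    sample_negatives,
    write_pairs,
    write_split_manifest,
)


def _grid_positives(n_c, n_d, n_pos, seed=0):
    compounds = [f"c{i}" for i in range(n_c)]
    diseases = [f"d{j}" for j in range(n_d)]
    rng = np.random.default_rng(seed)
    grid = list(itertools.product(compounds, diseases))
    idx = rng.choice(len(grid), size=n_pos, replace=False)
    positives = [PairLabel(*grid[i], "positive") for i in idx]
    return compounds, diseases, positives


class TestComplementPool:
    def test_full_grid_when_no_positives(self):
        pool = complement_pool(["c1", "c2"], ["d1", "d2"], [])
        assert len(pool) == 4

    def test_matches_brute_force_enumeration(self):
        compounds, diseases, positives = _grid_positives(8, 5, 11, seed=3)
        pool = complement_pool(compounds, diseases, positives)
        brute = set(itertools.product(compounds, diseases)) - {
            p.key for p in positives
        }
        assert set(pool) == brute
        assert len(pool) == 8 * 5 - 11

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            complement_pool(["c1"], ["d1"], [PairLabel("cX", "d1", "positive")])


class TestSampleNegatives:
    def test_whole_pool(self):
        pool = [("c1", "d1"), ("c2", "d2")]
        out = sample_negatives(pool, 2, seed=0)
        assert {p.key for p in out} == set(pool)
        assert all(p.label == "negative" for p in out)

    def test_deterministic_per_seed(self):
        pool = [(f"c{i}", "d0") for i in range(50)]
        assert sample_negatives(pool, 10, 9) == sample_negatives(pool, 10, 9)
        assert sample_negatives(pool, 10, 9) != sample_negatives(pool, 10, 10)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives([("c", "d")], 2, 0)

    def test_inclusion_frequencies_uniform(self):
        # 10-pair pool, n=5: inclusion probability 0.5 per pair
        pool = [(f"c{i}", "d0") for i in range(10)]
        reps = 10000
        counts = np.zeros(10)
        for rep in range(reps):
            for p in sample_negatives(pool, 5, seed=rep):
                counts[int(p.compound_id[1:])] += 1
        freq = counts / reps
        sigma = np.sqrt(0.5 * 0.5 / reps)
        assert (np.abs(freq - 0.5) < 3 * sigma + 0.01).all()


class TestRatioDatasets:
    def test_ratio_arithmetic_small(self):
        compounds, diseases, positives = _grid_positives(10, 10, 30, seed=1)
        pool = complement_pool(compounds, diseases, positives)
        spec = SplitSpec(ratio_neg_per_pos=3, sample_size=8, repeats=1, seed=0)
        split = make_ratio_datasets(positives, pool, spec)[0]
        prov = split.provenance
        n_pos = prov["n_train_pos"] + prov["n_test_pos"]
        n_neg = prov["n_train_neg"] + prov["n_test_neg"]
        assert (n_pos, n_neg) == (2, 6)

    def test_reference_counts_at_full_scale(self):
        compounds, diseases, positives = _grid_positives(300, 100, 11000, seed=2)
        pool = complement_pool(compounds, diseases, positives)
        spec = SplitSpec(ratio_neg_per_pos=1, sample_size=20000, repeats=1, seed=5)
        split = make_ratio_datasets(positives, pool, spec)[0]
        assert len(split.train) == 15000
        assert len(split.test) == 5000
        train_pos = sum(p.label == "positive" for p in split.train)
        assert train_pos == 7500

    @pytest.mark.parametrize("ratio", [1, 2, 3, 4, 5])
    def test_realized_ratio_within_rounding(self, ratio):
        compounds, diseases, positives = _grid_positives(40, 30, 400, seed=4)
        pool = complement_pool(compounds, diseases, positives)
        spec = SplitSpec(
            ratio_neg_per_pos=ratio, sample_size=600, repeats=2, seed=1
        )
        for split in make_ratio_datasets(positives, pool, spec):
            for part in (split.train, split.test):
                n_pos = sum(p.label == "positive" for p in part)
                n_neg = len(part) - n_pos
                assert abs(n_neg / n_pos - ratio) < 0.05 * ratio + 2 / n_pos * ratio

    def test_infeasible_request_names_shortfall(self):
        compounds, diseases, positives = _grid_positives(5, 5, 10, seed=0)
        pool = complement_pool(compounds, diseases, positives)
        spec = SplitSpec(ratio_neg_per_pos=1, sample_size=1000, repeats=1, seed=0)
        with pytest.raises(ValueError, match="positives"):
            make_ratio_datasets(positives, pool, spec)

    def test_reproducible_from_seed(self):
        compounds, diseases, positives = _grid_positives(20, 10, 60, seed=6)
        pool = complement_pool(compounds, diseases, positives)
        spec = SplitSpec(ratio_neg_per_pos=2, sample_size=90, repeats=2, seed=3)
        a = make_ratio_datasets(positives, pool, spec)
        b = make_ratio_datasets(positives, pool, spec)
        assert [s.train for s in a] == [s.train for s in b]
        assert [s.test for s in a] == [s.test for s in b]


def _labeled_sets(n_c, n_d, n_pos, n_neg, seed):
    compounds, diseases, positives = _grid_positives(n_c, n_d, n_pos, seed)
    pool = complement_pool(compounds, diseases, positives)
    negatives = sample_negatives(pool, n_neg, seed)
    return positives, negatives


class TestHeldOutSplits:
    def test_two_disease_grouping_forced(self):
        positives = [PairLabel(f"c{i}", "dA", "positive") for i in range(10)] + [
            PairLabel(f"c{i}", "dB", "positive") for i in range(10)
        ]
        negatives = [PairLabel(f"c{i}", "dA", "negative") for i in range(10, 20)] + [
            PairLabel(f"c{i}", "dB", "negative") for i in range(10, 20)
        ]
        split = disease_held_out_split(positives, negatives, 10, 5, seed=0)
        train_dis = {p.disease_id for p in split.train if p.label == "positive"}
        assert len(train_dis) == 1  # exactly one whole disease fills the target

    def test_disease_disjointness_many_seeds(self):
        positives, negatives = _labeled_sets(30, 12, 150, 150, seed=1)
        for seed in range(30):
            split = disease_held_out_split(positives, negatives, 90, 30, seed=seed)
            for label in ("positive", "negative"):
                train_ids = {
                    p.disease_id for p in split.train if p.label == label
                }
                test_ids = {p.disease_id for p in split.test if p.label == label}
                assert not train_ids & test_ids

    def test_compound_disjointness_many_seeds(self):
        positives, negatives = _labeled_sets(25, 10, 120, 120, seed=2)
        for seed in range(30):
            split = compound_held_out_split(positives, negatives, 70, 25, seed=seed)
            for label in ("positive", "negative"):
                train_ids = {
                    p.compound_id for p in split.train if p.label == label
                }
                test_ids = {p.compound_id for p in split.test if p.label == label}
                assert not train_ids & test_ids

    def test_single_compound_cannot_separate(self):
        positives = [PairLabel("c1", f"d{j}", "positive") for j in range(5)]
        negatives = [PairLabel("c1", f"d{j}", "negative") for j in range(5, 10)]
        with pytest.raises(ValueError):
            compound_held_out_split(positives, negatives, 3, 2, seed=0)

    def test_overshoot_kept_and_counts_recorded(self):
        positives, negatives = _labeled_sets(60, 8, 200, 200, seed=3)
        split = disease_held_out_split(positives, negatives, 100, 40, seed=1)
        prov = split.provenance
        assert prov["n_train_pos"] >= 100  # stop at first crossing, keep whole group
        assert prov["n_test_pos"] == 40
        assert prov["n_test_neg"] == 40

    def test_unreachable_target_errors(self):
        positives, negatives = _labeled_sets(10, 4, 20, 20, seed=4)
        with pytest.raises(ValueError):
            disease_held_out_split(positives, negatives, 1000, 10, seed=0)


class TestSplitInvariants:
    def test_train_test_share_no_pair(self):
        with pytest.raises(ValueError, match="share"):
            DatasetSplit(
                train=[PairLabel("c", "d", "positive")],
                test=[PairLabel("c", "d", "negative")],
                provenance={},
            )

    def test_pairs_file_round_trip(self, tmp_path):
        pairs = [
            PairLabel("c1", "d1", "positive", "treatment"),
            PairLabel("c2", "d1", "negative"),
        ]
        path = tmp_path / "pairs.csv"
        write_pairs(pairs, path)
        assert read_pairs(path) == pairs

    def test_manifest_round_trip(self, tmp_path):
        positives, negatives = _labeled_sets(10, 5, 20, 20, seed=5)
        split = disease_held_out_split(positives, negatives, 10, 5, seed=2)
        path = tmp_path / "split.json"
        write_split_manifest(split, path)
        back = read_split_manifest(path)
        assert back.train == split.train
        assert back.test == split.test
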