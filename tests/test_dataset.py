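import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosite.dataset import (
    BalancePlan,
    Instance,
    balance,
    build_instances,
    extract_window,
    label_sites,
    read_libsvm,
    split_folds,
    write_libsvm,
)
from phosite.errors import ConfigError, DataError
from phosite.profile_io import PssmProfile
from tests.conftest import make_profile, random_profile


def brute_force_labels(sequence, positives, distance=50):
    """Independent double-loop oracle for the site-labeling rule."""
    labels = {}
    for pos in range(1, len(sequence) + 1):
        if sequence[pos - 1] not in "STY":
            continue
        if pos in positives:
            labels[pos] = "positive"
        elif any(abs(pos - a) <= distance for a in positives):
            labels[pos] = "excluded"
        else:
            labels[pos] = "negative"
    return labels


class TestLabelSites:
    def test_distance_rule(self):
        sequence = ["A"] * 200
        for pos in (60, 100, 160):
            sequence[pos - 1] = "S"
        profile = make_profile(sequence="".join(sequence))
        labels = {s.position: s.label for s in label_sites(profile, [100])}
        assert labels[100] == "positive"
        assert labels[60] == "excluded"   # distance 40 <= 50
        assert labels[160] == "negative"  # distance 60 > 50

    def test_annotated_position_always_positive(self):
        profile = make_profile(sequence="S" * 30)
        labels = {s.position: s.label for s in label_sites(profile, [10])}
        assert labels[10] == "positive"

    def test_short_protein_has_no_negatives(self):
        profile = make_profile(sequence="S" * 30)
        labels = label_sites(profile, [10])
        assert sum(1 for s in labels if s.label == "negative") == 0
        oracle = brute_force_labels(profile.sequence, {10})
        assert {s.position: s.label for s in labels} == oracle

    def test_cross_residue_exclusion(self):
        # an annotated T excludes a nearby non-annotated S
        sequence = ["A"] * 120
        sequence[49] = "T"
        sequence[69] = "S"
        profile = make_profile(sequence="".join(sequence))
        labels = {s.position: s.label for s in label_sites(profile, [50])}
        assert labels[70] == "excluded"

    def test_positive_on_non_sty_rejected(self):
        profile = make_profile(sequence="MKSAT")
        with pytest.raises(DataError, match="not S/T/Y"):
            label_sites(profile, [1])

    def test_non_sty_positions_never_labeled(self):
        profile = make_profile(sequence="MKSAT")
        positions = {s.position for s in label_sites(profile, [3])}
        assert positions == {3, 5}

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_trichotomy_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        profile = random_profile(rng, length=int(rng.integers(10, 150)))
        sty = profile.sty_positions()
        if not sty:
            return
        n_annotated = int(rng.integers(1, min(4, len(sty)) + 1))
        positives = set(
            int(p) for p in rng.choice(sty, size=n_annotated, replace=False)
        )
        labels = {s.position: s.label for s in label_sites(profile, positives)}
        assert labels == brute_force_labels(profile.sequence, positives)


class TestExtractWindow:
    def test_interior_w11(self):
        rng = np.random.default_rng(7)
        profile = random_profile(rng, length=40)
        vector = extract_window(profile, 20, 11)
        assert vector.shape == (220,)
        np.testing.assert_array_equal(
            vector, profile.scores[14:25].reshape(-1)
        )

    def test_terminal_padding(self):
        profile = random_profile(np.random.default_rng(8), length=30)
        vector = extract_window(profile, 1, 7)
        assert vector.shape == (140,)
        assert np.all(vector[:60] == 0)
        np.testing.assert_array_equal(vector[60:], profile.scores[:4].reshape(-1))

    def test_distinct_rows_w3(self):
        scores = np.arange(100).reshape(5, 20)
        profile = PssmProfile("P", "MKSTY", scores)
        vector = extract_window(profile, 2, 3)
        np.testing.assert_array_equal(vector, scores[0:3].reshape(-1))

    @pytest.mark.parametrize("w", [0, -3, 2, 8])
    def test_bad_window_sizes(self, w):
        profile = make_profile()
        with pytest.raises(ConfigError):
            extract_window(profile, 1, w)

    def test_position_out_of_range(self):
        profile = make_profile(sequence="MKSAT")
        with pytest.raises(DataError):
            extract_window(profile, 6, 3)

    def test_locality(self):
        rng = np.random.default_rng(9)
        profile = random_profile(rng, length=50)
        before = extract_window(profile, 25, 9)
        edited = profile.scores.copy()
        edited[0] += 100  # outside the window of position 25
        edited[49] -= 100
        profile2 = PssmProfile("P1", profile.sequence, edited)
        np.testing.assert_array_equal(before, extract_window(profile2, 25, 9))


def toy_fixture():
    """Two proteins with 3 S positives and 4 S negatives in total."""
    rng = np.random.default_rng(0)
    seq1 = ["A"] * 300
    seq1[59] = "S"            # positive
    seq1[179] = "S"           # positive
    seq1[249] = "S"           # negative (70 from 180)
    seq1[269] = "S"           # negative
    seq2 = ["A"] * 260
    seq2[49] = "S"            # positive
    seq2[89] = "S"            # excluded (40 from 50)
    seq2[149] = "S"           # negative
    seq2[199] = "S"           # negative
    profiles = {
        "P1": random_profile(rng, length=300, protein_id="P1"),
        "P2": random_profile(rng, length=260, protein_id="P2"),
    }
    # replace sequences but keep the random scores
    profiles["P1"] = PssmProfile("P1", "".join(seq1), profiles["P1"].scores)
    profiles["P2"] = PssmProfile("P2", "".join(seq2), profiles["P2"].scores)
    from phosite.profile_io import SiteAnnotation

    annotations = [
        SiteAnnotation("P1", 60, "S"),
        SiteAnnotation("P1", 180, "S"),
        SiteAnnotation("P2", 50, "S"),
    ]
    return profiles, annotations


class TestBuildInstances:
    def test_toy_counts(self):
        profiles, annotations = toy_fixture()
        positives, negatives = build_instances(profiles, annotations, "S", 9)
        assert len(positives) == 3
        assert len(negatives) == 4

    def test_residue_filter(self, small_sim):
        positives, negatives = build_instances(
            small_sim.profiles, small_sim.positives, "S", 7
        )
        assert all(inst.residue == "S" for inst in positives + negatives)

    def test_features_match_extract_window(self):
        profiles, annotations = toy_fixture()
        positives, negatives = build_instances(profiles, annotations, "S", 9)
        for inst in positives + negatives:
            expected = extract_window(profiles[inst.protein_id], inst.position, 9)
            np.testing.assert_array_equal(inst.features, expected)

    def test_targets(self):
        profiles, annotations = toy_fixture()
        positives, negatives = build_instances(profiles, annotations, "S", 9)
        assert {inst.target for inst in positives} == {+1}
        assert {inst.target for inst in negatives} == {-1}

    def test_missing_profile_listed(self):
        profiles, annotations = toy_fixture()
        del profiles["P2"]
        with pytest.raises(DataError, match="P2"):
            build_instances(profiles, annotations, "S", 9)

    def test_deterministic_order(self):
        profiles, annotations = toy_fixture()
        _, neg1 = build_instances(profiles, annotations, "S", 9)
        _, neg2 = build_instances(profiles, annotations, "S", 9)
        assert [(i.protein_id, i.position) for i in neg1] == [
            (i.protein_id, i.position) for i in neg2
        ]
        assert [(i.protein_id, i.position) for i in neg1] == sorted(
            (i.protein_id, i.position) for i in neg1
        )


class TestBalance:
    def test_r_formula(self):
        assert BalancePlan(p=100, n=1000, factor=2).r == 5
        assert BalancePlan(p=100, n=200, factor=2).r == 1
        assert BalancePlan(p=10, n=35, factor=1).r == 3

    def test_example_200_kept(self):
        negatives = [_instance(i) for i in range(1000)]
        plan = BalancePlan(p=100, n=1000, factor=2)
        assert len(balance(negatives, plan)) == 200

    def test_exact_ratio_keeps_all(self):
        negatives = [_instance(i) for i in range(200)]
        plan = BalancePlan(p=100, n=200, factor=2)
        assert balance(negatives, plan) == negatives

    def test_stride_indices(self):
        negatives = [_instance(i) for i in range(35)]
        plan = BalancePlan(p=10, n=35, factor=1)
        kept = balance(negatives, plan)
        assert [inst.position for inst in kept] == list(range(1, 36, 3))
        assert len(kept) == 12

    def test_bad_factor(self):
        with pytest.raises(ConfigError):
            BalancePlan(p=10, n=35, factor=0)

    @settings(max_examples=100, deadline=None)
    @given(
        p=st.integers(min_value=1, max_value=500),
        n=st.integers(min_value=0, max_value=3000),
        factor=st.sampled_from([2.0, 1.5, 1.0, 0.5]),
    )
    def test_count_and_order_property(self, p, n, factor):
        negatives = [_instance(i) for i in range(n)]
        plan = BalancePlan(p=p, n=n, factor=factor)
        kept = balance(negatives, plan)
        r = max(1, math.floor(n / (factor * p)))
        assert plan.r == r
        assert len(kept) == (math.ceil(n / r) if n else 0)
        positions = [inst.position for inst in kept]
        assert positions == sorted(positions)
        assert positions == [i + 1 for i in range(0, n, r)]


def _instance(i, target=-1, k=20):
    return Instance(np.zeros(k), target, "P", i + 1, "S")


class TestSplitFolds:
    def _balanced(self, n_per_class):
        return [_instance(i, +1) for i in range(n_per_class)] + [
            _instance(i + n_per_class, -1) for i in range(n_per_class)
        ]

    def test_9_plus_9(self):
        splits = split_folds(self._balanced(9), folds=3, seed=0)
        for _, test in splits:
            assert sum(1 for i in test if i.target == 1) == 3
            assert sum(1 for i in test if i.target == -1) == 3

    def test_partition_property(self):
        instances = self._balanced(10)
        splits = split_folds(instances, folds=3, seed=1)
        seen = []
        for train, test in splits:
            assert len(train) + len(test) == len(instances)
            test_keys = {(i.protein_id, i.position) for i in test}
            train_keys = {(i.protein_id, i.position) for i in train}
            assert not test_keys & train_keys  # no leakage
            seen.extend(sorted(test_keys))
        assert sorted(seen) == sorted((i.protein_id, i.position) for i in instances)

    def test_seed_reproducibility(self):
        instances = self._balanced(12)

        def signature(seed):
            return [
                tuple((i.protein_id, i.position) for i in test)
                for _, test in split_folds(instances, folds=3, seed=seed)
            ]

        assert signature(5) == signature(5)
        assert signature(5) != signature(6)

    def test_too_few_instances(self):
        instances = [_instance(0, +1), _instance(1, +1), _instance(2, +1),
                     _instance(3, -1), _instance(4, -1)]
        with pytest.raises(DataError):
            split_folds(instances, folds=3, seed=0)


class TestLibsvmFormat:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        instances = [
            Instance(rng.integers(-5, 6, size=40), 1 if i % 2 else -1, f"P{i}", i + 1, "S")
            for i in range(10)
        ]
        path = tmp_path / "set.svm"
        write_libsvm(instances, path)
        loaded = read_libsvm(path, k=40)
        assert len(loaded) == 10
        for a, b in zip(instances, loaded):
            np.testing.assert_array_equal(a.features, b.features)
            assert (a.target, a.protein_id, a.position) == (b.target, b.protein_id, b.position)

    def test_sparse_zeros_omitted(self, tmp_path):
        inst = Instance(np.array([0.0, 3.0, 0.0, -2.0]), +1, "P", 1, "S")
        path = tmp_path / "one.svm"
        write_libsvm([inst], path)
        assert path.read_text().splitlines()[0] == "+1 2:3 4:-2"
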