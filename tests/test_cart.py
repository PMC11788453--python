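"""Classification tree: impurity, split search, growth, rule extraction."""

import numpy as np
import pytest

from irae_som.cart import CartConfig, best_split, extract_rules, gini, grow


def brute_force_best(X, labels, names, min_bucket=1, tie_break="last-feature"):
    """Independent exhaustive enumeration of every (feature, midpoint) split."""
    n = len(labels)

    def g(ys):
        counts = {}
        for y in ys:
            counts[y] = counts.get(y, 0) + 1
        return 1.0 - sum((c / len(ys)) ** 2 for c in counts.values())

    parent = g(labels)
    candidates = []
    for j, name in enumerate(names):
        vals = sorted(set(X[:, j]))
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            left = [labels[i] for i in range(n) if X[i, j] < thr]
            right = [labels[i] for i in range(n) if X[i, j] >= thr]
            if len(left) < min_bucket or len(right) < min_bucket:
                continue
            dec = parent - len(left) / n * g(left) - len(right) / n * g(right)
            if dec > 1e-12:
                candidates.append((dec, j, thr))
    if not candidates:
        return None
    best_dec = max(c[0] for c in candidates)
    tied = [c for c in candidates if abs(c[0] - best_dec) <= 1e-12]
    if tie_break == "last-feature":
        jpick = max(c[1] for c in tied)
    else:
        jpick = min(c[1] for c in tied)
    thr = min(c[2] for c in tied if c[1] == jpick)
    return jpick, thr, best_dec


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ((4, 0, 0, 0), 0.0),
        ((1, 1), 0.5),
        ((1, 2, 1, 4), 0.65625),  # the root label distribution of the 8 drugs
    ])
    def test_known_values(self, counts, expected):
        assert gini(counts) == pytest.approx(expected, abs=1e-12)

    def test_dict_input_and_errors(self):
        assert gini({"a": 2, "b": 2}) == 0.5
        with pytest.raises(ValueError):
            gini((0, 0))
        with pytest.raises(ValueError):
            gini((-1, 2))


class TestBestSplit:
    def test_perfect_separator_on_the_published_diabetes_column(
            self, published_matrix, published_units):
        j = published_matrix.features.index("Type 1 diabetes mellitus")
        X = published_matrix.values[:, [j]]
        labels = [published_units[d] for d in published_matrix.drugs]
        sp = best_split(X, labels, ["Type 1 diabetes mellitus"])
        assert sp.threshold == pytest.approx(2.55)
        left = [labels[i] for i in range(8) if X[i, 0] < sp.threshold]
        assert set(left) == {5} and len(left) == 4

    def test_single_distinct_value_gives_no_split(self):
        sp = best_split(np.ones((4, 1)), [0, 0, 1, 1], ["f"])
        assert sp is None

    def test_min_bucket_constraint_respected(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        sp = best_split(X, [0, 0, 0, 1], ["f"], CartConfig(min_bucket=2))
        assert sp is not None
        nl = int((X[:, 0] < sp.threshold).sum())
        assert 2 <= nl <= 2

    @pytest.mark.parametrize("tie_break", ["first-feature", "last-feature"])
    def test_matches_brute_force_on_random_instances(self, tie_break):
        rng = np.random.default_rng(99)
        cfg = CartConfig(tie_break=tie_break)
        checked = 0
        for _ in range(120):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(1, 5))
            # small integer grid provokes frequent exact ties
            X = rng.integers(0, 4, size=(n, m)).astype(float)
            labels = list(rng.integers(0, 3, size=n))
            names = [f"f{j}" for j in range(m)]
            mine = best_split(X, labels, names, cfg)
            ref = brute_force_best(X, labels, names, tie_break=tie_break)
            if ref is None:
                assert mine is None
            else:
                jref, thr, dec = ref
                assert mine.feature_index == jref
                assert mine.threshold == pytest.approx(thr)
                assert mine.decrease == pytest.approx(dec)
                checked += 1
        assert checked >= 60  # most random instances admit a split


class TestGrow:
    def test_uniform_labels_give_a_single_leaf(self, published_matrix):
        tree = grow(published_matrix, [1] * 8)
        assert tree.is_leaf and tree.leaf_label == 1

    def test_published_fixture_reproduces_the_printed_tree(
            self, published_matrix, published_units):
        labels = [published_units[d] for d in published_matrix.drugs]
        tree = grow(published_matrix, labels)
        inner = tree.internal_nodes()
        assert [nd.split_feature for nd in inner] == [
            "Type 1 diabetes mellitus", "Hematological disorder",
            "Type 1 diabetes mellitus"]
        assert [nd.threshold for nd in inner] == pytest.approx([2.55, 1.2, 17.1])
        leaf_sets = {frozenset(lf.members) for lf in tree.leaves()}
        assert leaf_sets == {
            frozenset({"Avelumab", "Cemiplimab", "Durvalumab", "Tremelimumab"}),
            frozenset({"Ipilimumab", "Pembrolizumab"}),
            frozenset({"Atezolizumab"}), frozenset({"Nivolumab"}),
        }
        # every drug classifies back to its published unit
        for i, d in enumerate(published_matrix.drugs):
            x = dict(zip(published_matrix.features, published_matrix.values[i]))
            assert tree.predict_one(x) == published_units[d]

    def test_first_feature_tie_break_changes_the_root_variable(
            self, published_matrix, published_units):
        labels = [published_units[d] for d in published_matrix.drugs]
        tree = grow(published_matrix, labels, CartConfig(tie_break="first-feature"))
        # many categories separate the four low-volume drugs perfectly; the
        # first in row order is Adrenal insufficiency
        assert tree.split_feature == "Adrenal insufficiency"
        leaf_sets = {frozenset(lf.members) for lf in tree.leaves()}
        assert frozenset({"Avelumab", "Cemiplimab", "Durvalumab", "Tremelimumab"}) in leaf_sets

    def test_conservation_and_positive_decrease_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 16))
            m = int(rng.integers(1, 6))
            X = rng.normal(size=(n, m))
            labels = list(rng.integers(0, 4, size=n))
            tree = grow(X, labels)
            for nd in tree.internal_nodes():
                merged = {}
                for child in (nd.left, nd.right):
                    for k, v in child.class_counts.items():
                        merged[k] = merged.get(k, 0) + v
                assert merged == nd.class_counts
                dec = (gini(nd.class_counts)
                       - nd.left.n / nd.n * gini(nd.left.class_counts)
                       - nd.right.n / nd.n * gini(nd.right.class_counts))
                assert dec > 0

    def test_separable_labels_reach_zero_training_error(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0, 0.3, size=(6, 2)),
                       rng.normal(5, 0.3, size=(6, 2))])
        labels = [0] * 6 + [1] * 6
        tree = grow(X, labels)
        names = [f"f{j}" for j in range(2)]
        preds = [tree.predict_one(dict(zip(names, row))) for row in X]
        assert preds == labels

    def test_max_depth_limits_growth(self):
        X = np.arange(8.0).reshape(-1, 1)
        labels = [0, 1, 0, 1, 0, 1, 0, 1]
        tree = grow(X, labels, CartConfig(max_depth=1))
        assert all(lf.depth <= 1 for lf in tree.leaves())

    def test_sklearn_agrees_on_achievable_impurity_decrease(self):
        """Dual-route check of the split search against a library CART."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(555)
        for _ in range(30):
            n = int(rng.integers(4, 20))
            m = int(rng.integers(1, 4))
            X = rng.normal(size=(n, m))
            labels = list(rng.integers(0, 2, size=n))
            mine = best_split(X, labels, [f"f{j}" for j in range(m)])
            clf = sklearn_tree.DecisionTreeClassifier(max_depth=1, random_state=0)
            clf.fit(X, labels)
            if clf.tree_.node_count == 1:
                continue
            nl, nr = clf.tree_.n_node_samples[1], clf.tree_.n_node_samples[2]
            ref_dec = (clf.tree_.impurity[0]
                       - nl / n * clf.tree_.impurity[1]
                       - nr / n * clf.tree_.impurity[2])
            assert mine is not None
            assert mine.decrease == pytest.approx(ref_dec, abs=1e-9)


class TestRules:
    def test_single_leaf_tree_gives_one_unconditional_rule(self, published_matrix):
        tree = grow(published_matrix, [2] * 8)
        rules = extract_rules(tree)
        assert rules == [f"IF always THEN unit 2 ({', '.join(sorted(published_matrix.drugs))})"]

    def test_published_tree_rules(self, published_matrix, published_units):
        labels = [published_units[d] for d in published_matrix.drugs]
        tree = grow(published_matrix, labels)
        rules = extract_rules(tree)
        assert len(rules) == len(tree.leaves()) == 4
        assert rules[0].startswith("IF Type 1 diabetes mellitus < ")
        assert "display 2.6" in rules[0] and "unit 5" in rules[0]
        assert "display 1.2" in rules[1] and "unit 3" in rules[1]
        assert "display 17.1" in rules[2] and "unit 4" in rules[2]
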