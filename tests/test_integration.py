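"""Network normalization and the regression-based weighting algorithms.

The independent oracle used here assembles the least-squares design matrix
row by row (one row per upper-triangle pair with at least one nonzero
network entry, plus an intercept) densely and solves it with
``numpy.linalg.lstsq``, replaying the non-positive-weight elimination rule.
"""

import numpy as np
import pytest

from netassess.datamodel import AnnotationSet, GeneIndex
from netassess.integration import (
    LabelVector,
    build_target,
    combine_automatic,
    combine_equal,
    combine_simultaneous,
    combine_unregularized,
    normalize_network,
)

from conftest import network_from_edges, random_network


def labels_from_positives(index, positives):
    y = -np.ones(len(index))
    for g in positives:
        y[index.lookup[g]] = 1.0
    return LabelVector(y=y)


def dense_weight_oracle(nets, ybars):
    """Brute-force stacked OLS with elimination; None signals the equal fallback."""
    norm = sorted((normalize_network(n) for n in nets), key=lambda n: n.name)
    dense = {n.name: n.matrix.toarray() for n in norm}
    active = [n.name for n in norm]
    n = len(norm[0].index)
    iu, ju = np.triu_indices(n, k=1)
    while active:
        support = np.zeros(iu.size, dtype=bool)
        for name in active:
            support |= dense[name][iu, ju] != 0
        if not support.any():
            return None
        X = np.column_stack(
            [np.ones(support.sum())] + [dense[m][iu, ju][support] for m in active]
        )
        rows = [ybar[iu][support] * ybar[ju][support] for ybar in ybars]
        Xs = np.vstack([X] * len(ybars))
        t = np.concatenate(rows)
        beta, *_ = np.linalg.lstsq(Xs, t, rcond=None)
        w = beta[1:]
        if np.all(w > 0):
            return dict(zip(active, w))
        active = [m for m, wi in zip(active, w) if wi > 0]
    return None


class TestNormalize:
    def test_single_edge_normalizes_to_one(self):
        net = network_from_edges([("a", "b", 4.0)])
        assert normalize_network(net).edge_dict() == {("a", "b"): 1.0}

    def test_unit_triangle_normalizes_to_half(self):
        net = network_from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        norm = normalize_network(net).edge_dict()
        assert norm == pytest.approx({("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5})

    def test_unit_star_leaf_edges(self):
        net = network_from_edges([("hub", "x", 1), ("hub", "y", 1), ("hub", "z", 1)])
        norm = normalize_network(net).edge_dict()
        expected = 1 / np.sqrt(3)
        assert all(w == pytest.approx(expected) for w in norm.values())

    def test_scaling_raw_weights_leaves_normalization_unchanged(self):
        e = [("a", "b", 0.3), ("b", "c", 1.2), ("c", "d", 0.7)]
        n1 = normalize_network(network_from_edges(e))
        n2 = normalize_network(
            network_from_edges([(a, b, 17.0 * w) for a, b, w in e])
        )
        assert n1.edge_dict() == pytest.approx(n2.edge_dict())


class TestCombineEqual:
    def test_single_network_is_its_normalized_form(self):
        net = network_from_edges([("a", "b", 2.0), ("b", "c", 1.0)])
        comb = combine_equal([net])
        assert comb.weights == {"net": 1.0}
        assert (comb.composite != normalize_network(net).matrix).nnz == 0

    def test_two_identical_networks_average_to_one(self):
        syms = ["a", "b", "c"]
        n1 = network_from_edges([("a", "b", 1.0)], symbols=syms, name="n1")
        n2 = network_from_edges([("a", "b", 1.0)], symbols=syms, name="n2")
        comb = combine_equal([n1, n2])
        assert np.allclose(
            comb.composite.toarray(), normalize_network(n1).matrix.toarray()
        )

    def test_disjoint_single_edges_at_half_weight(self):
        syms = ["a", "b", "c", "d"]
        n1 = network_from_edges([("a", "b", 3.0)], symbols=syms, name="n1")
        n2 = network_from_edges([("c", "d", 0.5)], symbols=syms, name="n2")
        comb = combine_equal([n1, n2])
        d = comb.composite.toarray()
        assert d[0, 1] == pytest.approx(0.5) and d[2, 3] == pytest.approx(0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_equal([])


class TestBuildTarget:
    def test_two_of_four_positive_targets(self):
        index = GeneIndex(["a", "b", "c", "d"])
        ybar = build_target(labels_from_positives(index, {"a", "b"}))
        outer = np.outer(ybar, ybar)
        assert outer[0, 1] == pytest.approx(0.25)  # pos-pos
        assert outer[0, 2] == pytest.approx(-0.25)  # mixed
        assert outer[2, 3] == pytest.approx(0.25)  # neg-neg

    def test_flipping_positive_identity_preserves_target_multiset(self):
        index = GeneIndex(["a", "b", "c", "d"])
        y1 = build_target(labels_from_positives(index, {"a", "b"}))
        y2 = build_target(labels_from_positives(index, {"c", "d"}))
        o1 = np.sort(np.outer(y1, y1)[np.triu_indices(4, 1)])
        o2 = np.sort(np.outer(y2, y2)[np.triu_indices(4, 1)])
        assert o1 == pytest.approx(o2)

    def test_balanced_labels_give_uniform_magnitude(self):
        index = GeneIndex(list("abcdef"))
        ybar = build_target(labels_from_positives(index, {"a", "b", "c"}))
        assert np.all(np.abs(ybar) == pytest.approx(0.5))

    def test_single_class_rejected(self):
        index = GeneIndex(["a", "b"])
        with pytest.raises(ValueError):
            build_target(labels_from_positives(index, {"a", "b"}))


def aligned_instance():
    """A network whose normalized entries are exactly proportional (c = 4/9)
    to the pair targets: positives {p0,p1} joined by an isolated edge
    (normalized entry 1, target (18/27)^2), negatives on a 16-leaf star
    (leaf entries 1/4, target (9/27)^2); 7 extra positives and 1 extra
    negative are isolated so the class sizes come out as 9 and 18."""
    symbols = (
        ["p0", "p1"]
        + [f"px{i}" for i in range(7)]
        + ["s0"]
        + [f"leaf{i:02d}" for i in range(16)]
        + ["nx0"]
    )
    index = GeneIndex(symbols)
    edges = [("p0", "p1", 2.0)] + [("s0", f"leaf{i:02d}", 0.5) for i in range(16)]
    net = network_from_edges(edges, symbols=symbols, name="aligned")
    positives = {"p0", "p1"} | {f"px{i}" for i in range(7)}
    return index, net, positives


class TestCombineUnregularized:
    def test_recovers_exact_proportionality_factor(self):
        index, net, positives = aligned_instance()
        labels = labels_from_positives(index, positives)
        comb = combine_unregularized([net], labels)
        assert comb.weights["aligned"] == pytest.approx(4 / 9, abs=1e-10)
        expected = (4 / 9) * normalize_network(net).matrix.toarray()
        assert np.allclose(comb.composite.toarray(), expected, atol=1e-10)

    def test_noise_network_eliminated_next_to_aligned_one(self):
        index, net, positives = aligned_instance()
        rng = np.random.default_rng(7)
        noise = random_network(rng, len(index), 0.3, name="znoise", symbols=index.symbols)
        labels = labels_from_positives(index, positives)
        comb = combine_unregularized([net, noise], labels)
        oracle = dense_weight_oracle([net, noise], [build_target(labels)])
        assert comb.weights["znoise"] == 0.0
        assert comb.weights["aligned"] > 0
        assert comb.weights["aligned"] == pytest.approx(oracle["aligned"], abs=1e-8)

    def test_matches_dense_oracle_on_ten_gene_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            n = 10
            nets = [
                random_network(rng, n, 0.5, name=f"n{k}")
                for k in range(rng.integers(1, 4))
            ]
            positives = set(
                np.array(nets[0].index.symbols)[
                    rng.choice(n, size=rng.integers(2, 6), replace=False)
                ]
            )
            labels = labels_from_positives(nets[0].index, positives)
            comb = combine_unregularized(nets, labels)
            oracle = dense_weight_oracle(nets, [build_target(labels)])
            if oracle is None:
                expected = {net.name: 1.0 / len(nets) for net in nets}
            else:
                expected = {net.name: oracle.get(net.name, 0.0) for net in nets}
            for name, w in expected.items():
                assert comb.weights[name] == pytest.approx(w, abs=1e-8), trial

    def test_degenerate_design_falls_back_to_equal(self):
        # a single mixed-pair edge: one regression row, singular system
        net = network_from_edges([("a", "b", 1.0)], symbols=["a", "b", "c"])
        labels = labels_from_positives(net.index, {"a"})
        comb = combine_unregularized([net], labels)
        assert comb.weights == {"net": 1.0}

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        nets = [random_network(rng, 12, 0.4, name=f"n{k}") for k in range(3)]
        syms = nets[0].index.symbols
        labels = labels_from_positives(nets[0].index, set(syms[:5]))
        nets_shared = [
            network_from_edges(list(n.edges()), symbols=syms, name=n.name)
            for n in nets
        ]
        w1 = combine_unregularized(nets_shared, labels).weights
        w2 = combine_unregularized(nets_shared[::-1], labels).weights
        assert w1 == pytest.approx(w2)


class TestCombineSimultaneous:
    def test_single_term_degenerates_to_unregularized(self):
        index, net, positives = aligned_instance()
        labels = labels_from_positives(index, positives)
        sw = AnnotationSet(terms={"t": set(positives)})
        w_sim = combine_simultaneous([net], sw).weights
        w_unr = combine_unregularized([net], labels).weights
        assert w_sim == pytest.approx(w_unr)

    def test_aligned_network_dominates_noise_across_terms(self):
        rng = np.random.default_rng(5)
        n = 12
        syms = [f"g{i:03d}" for i in range(n)]
        # unequal term sizes: with equal sizes the two stacked targets sum to
        # a constant per pair and the aligned network has zero stacked covariance
        terms = {"t1": set(syms[:4]), "t2": set(syms[4:7])}
        # weighted clique per term: informative for both (weights varied so
        # the normalized entries are not collinear with the intercept)
        edges = []
        w = 1.0
        for genes in terms.values():
            gl = sorted(genes)
            for i, a in enumerate(gl):
                for b in gl[i + 1:]:
                    edges.append((a, b, w))
                    w += 0.2
        aligned = network_from_edges(edges, symbols=syms, name="aligned")
        noise = random_network(rng, n, 0.4, name="noise", symbols=syms)
        comb = combine_simultaneous([aligned, noise], AnnotationSet(terms=terms))
        w = comb.weights
        assert w["aligned"] > 0
        assert w["noise"] == 0.0 or w["aligned"] / w["noise"] > 10

    def test_duplicated_term_leaves_solution_invariant(self):
        index, net, positives = aligned_instance()
        rng = np.random.default_rng(11)
        other = random_network(rng, len(index), 0.2, name="other", symbols=index.symbols)
        sw1 = AnnotationSet(terms={"t": set(positives)})
        sw2 = AnnotationSet(terms={"t": set(positives), "t_copy": set(positives)})
        w1 = combine_simultaneous([net, other], sw1).weights
        w2 = combine_simultaneous([net, other], sw2).weights
        assert w1 == pytest.approx(w2)

    def test_empty_collection_rejected(self):
        net = network_from_edges([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            combine_simultaneous([net], AnnotationSet(terms={}))


class TestCombineAutomatic:
    @pytest.mark.parametrize("n_pos,branch", [(4, "simultaneous"), (5, "unregularized")])
    def test_dispatch_on_training_positive_count(self, n_pos, branch):
        rng = np.random.default_rng(2)
        n = 20
        net = random_network(rng, n, 0.3, name="n0")
        syms = net.index.symbols
        positives = set(syms[:n_pos])
        labels = labels_from_positives(net.index, positives)
        sw = AnnotationSet(terms={"t": set(syms[5:11])})
        comb = combine_automatic([net], labels, sw)
        if branch == "simultaneous":
            expected = combine_simultaneous([net], sw)
        else:
            expected = combine_unregularized([net], labels)
        assert comb.weights == pytest.approx(expected.weights)

    def test_zero_positives_rejected(self):
        net = network_from_edges([("a", "b", 1.0)])
        labels = LabelVector(y=-np.ones(2))
        with pytest.raises(ValueError):
            combine_automatic([net], labels, AnnotationSet(terms={"t": {"a"}}))

    def test_weights_are_never_negative(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            nets = [random_network(rng, 15, 0.3, name=f"n{k}") for k in range(3)]
            syms = nets[0].index.symbols
            shared = [
                network_from_edges(list(n.edges()), symbols=syms, name=n.name)
                for n in nets
            ]
            positives = set(
                np.array(syms)[rng.choice(15, size=rng.integers(2, 9), replace=False)]
            )
            labels = labels_from_positives(shared[0].index, positives)
            sw = AnnotationSet(terms={"t": positives})
            comb = combine_automatic(shared, labels, sw)
            assert all(w >= 0 for w in comb.weights.values())
            assert any(w > 0 for w in comb.weights.values())
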