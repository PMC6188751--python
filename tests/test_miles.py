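"""MILES-Q: quantile embedding, sparse prototype selection, instance scoring."""

import numpy as np
import pytest
from sklearn.svm import LinearSVC

from emphymil import miles
from emphymil.mil import Bag, Instance, KernelSpec, MILParams, kernel_matrix

from conftest import toy_bag


RBF2 = KernelSpec("rbf", bandwidth=2.0)


class TestEmbed:
    def test_bag_containing_prototype(self):
        proto = np.array([[1.0, 2.0]])
        bag_X = np.vstack([proto, np.array([[5.0, 5.0]])])
        s = miles.embed(bag_X, proto, MILParams(kernel=RBF2, C=1.0, q=1.0))
        assert s[0] == pytest.approx(1.0)

    def test_identical_instances_independent_of_q(self):
        bag_X = np.tile(np.array([[1.0, 1.0]]), (5, 1))
        protos = np.array([[0.0, 0.0], [2.0, 2.0]])
        embeds = [
            miles.embed(bag_X, protos, MILParams(kernel=RBF2, C=1.0, q=q))
            for q in (0.25, 0.5, 1.0)
        ]
        assert np.allclose(embeds[0], embeds[1]) and np.allclose(embeds[1], embeds[2])

    def test_nearest_rank_on_known_similarities(self):
        rng = np.random.default_rng(0)
        bag_X = rng.normal(size=(4, 3))
        protos = rng.normal(size=(2, 3))
        K = kernel_matrix(bag_X, protos, RBF2)
        s_half = miles.embed(bag_X, protos, MILParams(kernel=RBF2, C=1.0, q=0.5))
        # k = ceil(0.5 * 4) = 2nd largest similarity per prototype
        expected = np.sort(K, axis=0)[::-1][1, :]
        assert np.allclose(s_half, expected)

    def test_q1_equals_max_similarity(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            bag_X = rng.normal(size=(rng.integers(1, 8), 4))
            protos = rng.normal(size=(6, 4))
            s = miles.embed(bag_X, protos, MILParams(kernel=RBF2, C=1.0, q=1.0))
            K = kernel_matrix(bag_X, protos, RBF2)
            assert np.array_equal(s, K.max(axis=0))

    def test_empty_bag_errors(self):
        with pytest.raises(ValueError):
            miles.embed(np.empty((0, 2)), np.zeros((1, 2)), MILParams(kernel=RBF2, C=1.0, q=1.0))


class TestFit:
    def test_toy_recovery_and_prototype_origin(self, toy_mil_bags, toy_rbf_params):
        model = miles.fit(toy_mil_bags, toy_rbf_params)
        for b in toy_mil_bags:
            assert (miles.predict_bag(model, b) > 0.5) == (b.label == 1)
        assert model.n_prototypes >= 1
        # positively weighted prototypes live near the lesion concept (4,4):
        # undo standardization to check in raw coordinates
        raw = model.prototypes * model.standardizer.scale + model.standardizer.mean
        pos_protos = raw[model.weights > 0]
        assert len(pos_protos) >= 1
        assert np.all(np.linalg.norm(pos_protos - np.array([4.0, 4.0]), axis=1) < 3.0)

    def test_tiny_c_gives_near_empty_prototype_set(self, toy_mil_bags):
        model = miles.fit(
            toy_mil_bags, MILParams(kernel=RBF2, C=1e-4, q=1.0)
        )
        assert model.n_prototypes <= 1

    def test_sparsity_monotone_in_c(self, toy_mil_bags):
        counts = [
            miles.fit(toy_mil_bags, MILParams(kernel=RBF2, C=c, q=1.0)).n_prototypes
            for c in (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_duplicated_bag_leaves_predictions_stable(self, toy_mil_bags, toy_rbf_params):
        model_a = miles.fit(toy_mil_bags, toy_rbf_params)
        model_b = miles.fit(toy_mil_bags + [toy_mil_bags[0]], toy_rbf_params)
        pa = [miles.predict_bag(model_a, b) > 0.5 for b in toy_mil_bags]
        pb = [miles.predict_bag(model_b, b) > 0.5 for b in toy_mil_bags]
        assert pa == pb

    def test_single_class_errors(self, toy_rbf_params):
        rng = np.random.default_rng(5)
        bags = [toy_bag(rng, f"p{i}", 2, 2, 1) for i in range(4)]
        with pytest.raises(ValueError):
            miles.fit(bags, toy_rbf_params)

    def test_q1_matches_reference_miles(self, toy_mil_bags, toy_rbf_params):
        """Side-by-side with an independently coded max-embedding MILES
        (same L1 linear SVM backend): identical bag decision signs."""
        params = MILParams(kernel=toy_rbf_params.kernel, C=1.0, q=1.0)
        X_all = np.vstack([b.X for b in toy_mil_bags])
        mean, sd = X_all.mean(0), X_all.std(0)
        sd[sd == 0] = 1
        S = np.vstack(
            [
                kernel_matrix((b.X - mean) / sd, (X_all - mean) / sd, params.kernel).max(axis=0)
                for b in toy_mil_bags
            ]
        )
        y = np.array([b.label for b in toy_mil_bags])
        ref = LinearSVC(C=1.0, penalty="l1", loss="squared_hinge", dual=False, max_iter=20000)
        ref.fit(S, y)
        ref_sign = np.sign(S @ ref.coef_.ravel() + ref.intercept_[0])

        model = miles.fit(toy_mil_bags, params)
        mine_sign = np.sign(
            [model.bag_decision(b) for b in toy_mil_bags]
        )
        assert np.array_equal(ref_sign, mine_sign)


@pytest.fixture(scope="module")
def trained(toy_mil_bags, toy_rbf_params):
    return miles.fit(toy_mil_bags, toy_rbf_params)


class TestPredictInstances:

    def test_identical_instances_equal_bag_posterior(self, trained):
        bag = Bag([Instance(np.array([2.0, 2.0]), "t") for _ in range(3)], label=None)
        inst = miles.predict_instances(trained, bag)
        assert np.allclose(inst, inst[0])
        assert miles.predict_bag(trained, bag) == pytest.approx(inst[0])

    def test_lesion_instance_dominates_its_bag(self, trained):
        bag = Bag(
            [
                Instance(np.array([4.0, 4.0]), "t"),
                Instance(np.array([0.0, 0.0]), "t"),
            ],
            label=None,
        )
        inst = miles.predict_instances(trained, bag)
        assert inst[0] > inst[1]

    def test_hand_computed_contributions(self, trained):
        """Two-instance bag: each instance's pseudo-decision sums the
        weighted similarities of the prototypes whose bag-level aggregate it
        attains (q=0.5, n=2 -> the larger similarity per prototype)."""
        bag_X = np.array([[4.0, 4.0], [0.0, 0.0]])
        Xs = trained.standardizer(bag_X)
        K = kernel_matrix(Xs, trained.prototypes, trained.params.kernel)
        attained = K >= K.max(axis=0)[None, :] - 1e-12
        expected_dec = (K * attained) @ trained.weights + trained.intercept
        expected = trained.posterior_map(expected_dec)
        bag = Bag([Instance(x, "t") for x in bag_X], label=None)
        assert np.allclose(miles.predict_instances(trained, bag), expected)

    def test_posteriors_in_unit_interval(self, trained, toy_mil_bags):
        for b in toy_mil_bags:
            post = miles.predict_instances(trained, b)
            assert np.all((post >= 0) & (post <= 1))

    def test_bag_posterior_invariant_to_instance_order(self, trained, toy_mil_bags):
        b = toy_mil_bags[0]
        shuffled = Bag(list(reversed(b.instances)), label=b.label)
        assert miles.predict_bag(trained, shuffled) == pytest.approx(
            miles.predict_bag(trained, b)
        )
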