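"""miSVM-Q: imputation training, posteriors, quantile robustness."""

import itertools

import numpy as np
import pytest
from sklearn.svm import SVC

from emphymil import misvm
from emphymil.mil import (
    Bag,
    Instance,
    KernelSpec,
    MILParams,
    kernel_matrix,
    min_positive_instances,
    quantile_agg,
)

from conftest import toy_bag


def _singleton_bags(rng, n=8, sep=5.0):
    """Well separated point clouds as 1-instance bags: MIL collapses to a
    plain supervised SVM."""
    bags = []
    for i in range(n):
        x = rng.normal((sep, sep), 0.5, 2)
        bags.append(Bag([Instance(x, f"p{i}")], label=1))
        x = rng.normal((0, 0), 0.5, 2)
        bags.append(Bag([Instance(x, f"n{i}")], label=-1))
    return bags


def brute_force_misvm_bag_labels(bags, params):
    """Independent oracle: enumerate every feasible instance-label
    assignment, solve each with a supervised SVM, keep the assignment with
    the smallest primal objective, and read off bag labels via the quantile
    of decision-value signs."""
    X = np.vstack([b.X for b in bags])
    mean, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1
    Xs = (X - mean) / sd
    K = kernel_matrix(Xs, Xs, params.kernel)
    bag_idx = np.concatenate([np.full(len(b), i) for i, b in enumerate(bags)])
    choices = []
    for b in bags:
        n = len(b)
        if b.label == -1:
            choices.append([tuple([-1] * n)])
        else:
            m = min_positive_instances(n, params.q)
            choices.append(
                [
                    c
                    for c in itertools.product([-1, 1], repeat=n)
                    if sum(v > 0 for v in c) >= m
                ]
            )
    best = None
    for combo in itertools.product(*choices):
        y = np.concatenate([np.asarray(c) for c in combo])
        svc = SVC(C=params.C, kernel="precomputed")
        svc.fit(K, y)
        dec = svc.decision_function(K)
        Ksv = K[np.ix_(svc.support_, svc.support_)]
        w2 = float((svc.dual_coef_ @ Ksv @ svc.dual_coef_.T)[0, 0])
        obj = 0.5 * w2 + params.C * np.maximum(0, 1 - y * dec).sum()
        if best is None or obj < best[0] - 1e-12:
            best = (obj, dec)
    _, dec = best
    return [
        1 if quantile_agg(np.sign(dec[bag_idx == i]), params.q) > 0 else -1
        for i in range(len(bags))
    ]


class TestFit:
    def test_singleton_bags_reduce_to_supervised_svm(self):
        rng = np.random.default_rng(0)
        bags = _singleton_bags(rng)
        model = misvm.fit(bags, MILParams(kernel=KernelSpec("rbf", bandwidth=2.0), C=1.0, q=1.0))
        assert model.converged
        for b in bags:
            assert (misvm.predict_bag(model, b) > 0.5) == (b.label == 1)

    def test_witness_bags_recovered(self, toy_rbf_params):
        """Positive bags with one lesion-like instance among background:
        a lenient quantile (one witness suffices) labels all bags correctly
        and puts the highest posteriors on the lesion-like instances."""
        rng = np.random.default_rng(8)
        bags = [toy_bag(rng, f"p{i}", 1, 9, 1) for i in range(5)]
        bags += [toy_bag(rng, f"n{i}", 0, 10, -1) for i in range(5)]
        params = MILParams(kernel=toy_rbf_params.kernel, C=1.0, q=0.9)
        model = misvm.fit(bags, params)
        for b in bags:
            assert (misvm.predict_bag(model, b) > 0.5) == (b.label == 1)
        for b in bags[:5]:
            post = misvm.predict_instances(model, b)
            assert np.argmax(post) == 0  # the lesion instance comes first

    def test_matches_brute_force_oracle_q1(self):
        """On tiny separable bag sets, iterative imputation agrees with
        exhaustive search over all feasible instance-label assignments."""
        rng = np.random.default_rng(7)
        params = MILParams(kernel=KernelSpec("polynomial", degree=1), C=1.0, q=1.0)
        for _ in range(6):
            bags = []
            for i in range(2):
                X = rng.normal((4, 4), 0.7, (3, 2))
                bags.append(Bag([Instance(x, f"p{i}") for x in X], label=1))
            for i in range(2):
                X = rng.normal((0, 0), 0.7, (3, 2))
                bags.append(Bag([Instance(x, f"n{i}") for x in X], label=-1))
            oracle = brute_force_misvm_bag_labels(bags, params)
            model = misvm.fit(bags, params)
            mine = [1 if misvm.predict_bag(model, b) > 0.5 else -1 for b in bags]
            assert mine == oracle

    def test_single_class_errors(self, toy_rbf_params):
        rng = np.random.default_rng(1)
        bags = [toy_bag(rng, f"n{i}", 0, 5, -1) for i in range(4)]
        with pytest.raises(ValueError):
            misvm.fit(bags, toy_rbf_params)

    def test_unlabeled_bag_errors(self, toy_rbf_params):
        rng = np.random.default_rng(1)
        bags = [toy_bag(rng, "p0", 2, 2, 1), toy_bag(rng, "n0", 0, 4, -1)]
        bags.append(Bag(bags[0].instances, label=None))
        with pytest.raises(ValueError):
            misvm.fit(bags, toy_rbf_params)


@pytest.fixture(scope="module")
def trained(toy_mil_bags, toy_rbf_params):
    return misvm.fit(toy_mil_bags, toy_rbf_params)


class TestPredict:

    def test_posteriors_in_unit_interval(self, trained, toy_mil_bags):
        for b in toy_mil_bags:
            post = misvm.predict_instances(trained, b)
            assert np.all((post >= 0) & (post <= 1))

    def test_duplicate_instance_same_posterior(self, trained):
        x = np.array([4.0, 4.0])
        bag = Bag([Instance(x, "t"), Instance(x.copy(), "t")], label=None)
        post = misvm.predict_instances(trained, bag)
        assert post[0] == post[1]

    def test_identical_instance_bag_posterior_any_q(self, trained):
        x = np.array([1.0, 1.0])
        bag = Bag([Instance(x, "t") for _ in range(4)], label=None)
        post = misvm.predict_instances(trained, bag)
        assert misvm.predict_bag(trained, bag) == pytest.approx(post[0])

    def test_q1_bag_posterior_is_max(self, toy_mil_bags):
        params = MILParams(kernel=KernelSpec("rbf", bandwidth=2.0), C=1.0, q=1.0)
        model = misvm.fit(toy_mil_bags, params)
        for b in toy_mil_bags[:3]:
            post = misvm.predict_instances(model, b)
            assert misvm.predict_bag(model, b) == pytest.approx(post.max())

    def test_dimension_mismatch_errors(self, trained):
        bag = Bag([Instance(np.zeros(5), "t")], label=None)
        with pytest.raises(ValueError):
            misvm.predict_instances(trained, bag)


class TestQuantileRobustness:
    def test_single_outlier_flips_max_but_not_median(self, toy_mil_bags):
        """One lesion-like patch in a healthy bag flips the bag under the
        witness rule (q=1) but not under the median rule (q=0.5)."""
        kern = KernelSpec("rbf", bandwidth=2.0)
        m1 = misvm.fit(toy_mil_bags, MILParams(kernel=kern, C=1.0, q=1.0))
        m5 = misvm.fit(toy_mil_bags, MILParams(kernel=kern, C=1.0, q=0.5))
        rng = np.random.default_rng(99)
        flips_q1 = flips_q5 = 0
        n_bags = 5
        for i in range(n_bags):
            clean = toy_bag(rng, f"f{i}", 0, 9, -1)
            perturbed = Bag(
                clean.instances + [Instance(np.array([4.0, 4.0]), f"f{i}")],
                label=-1,
            )
            if misvm.predict_bag(m1, clean) <= 0.5 < misvm.predict_bag(m1, perturbed):
                flips_q1 += 1
            if misvm.predict_bag(m5, clean) <= 0.5 < misvm.predict_bag(m5, perturbed):
                flips_q5 += 1
        assert flips_q1 >= 1
        assert flips_q5 == 0
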