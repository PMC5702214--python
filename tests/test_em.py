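"""Bernoulli-mixture EM, K estimation, mutation clusters, doublet flags."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

import clonotrace as ct
from clonotrace.em import (
    derive_mutation_clusters,
    estimate_k,
    fit_bernoulli_mixture,
    flag_doublet_clusters,
)

A = B = 0.5  # Jeffreys smoothing pseudocounts used throughout


def mixture_loglik(X, pi, theta):
    """Independent log-likelihood evaluation (no shared code with the fit)."""
    logp = np.stack(
        [
            np.log(pi[k])
            + (X * np.log(theta[k]) + (1 - X) * np.log(1 - theta[k])).sum(axis=1)
            for k in range(len(pi))
        ],
        axis=1,
    )
    return float(logsumexp(logp, axis=1).sum())


def penalized_objective(X, pi, theta):
    """The EM objective: data log-likelihood plus the Beta prior on theta."""
    return mixture_loglik(X, pi, theta) + float(
        A * np.log(theta).sum() + B * np.log1p(-theta).sum()
    )


def best_hard_partition_loglik(X):
    """Brute force over all 2-colorings; params by smoothed hard-count MLE,
    scored on the same penalized objective the EM maximizes."""
    n = X.shape[0]
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=n):
        z = np.array(bits)
        pi = np.array([(z == 0).mean(), (z == 1).mean()])
        if pi.min() == 0:
            continue
        theta = np.stack(
            [
                (X[z == k].sum(axis=0) + A) / ((z == k).sum() + A + B)
                for k in (0, 1)
            ]
        )
        best = max(best, penalized_objective(X, pi, theta))
    return best


def two_block_matrix(n_per=10, j=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((2 * n_per, j), dtype=int)
    X[:n_per, : j // 2] = 1
    X[n_per:, j // 2 :] = 1
    flip = rng.random(X.shape) < noise
    return np.where(flip, 1 - X, X)


def test_estimate_k_one_for_identical_rows():
    X = np.ones((10, 5), dtype=int)
    assert estimate_k(X) == 1


def test_estimate_k_single_row():
    assert estimate_k(np.array([[1, 0, 1]])) == 1


def test_estimate_k_two_clean_blocks():
    assert estimate_k(two_block_matrix()) == 2


def test_estimate_k_three_planted_clones_with_noise():
    hits = 0
    for s in range(20):
        cfg = ct.SimulationConfig(seed=s, n_cells=200, k_clones=3, doublet_rate=0.0)
        obs = ct.simulate_dataset(cfg)
        res = ct.analyze_tables(
            obs.snv_counts, obs.sv_match_counts, obs.cells,
            obs.truth.snv_sites, obs.truth.junctions, ct.RunConfig(k=1, seed=s),
        )
        hits += estimate_k(res.matrix) == 3
    assert hits >= 19


def test_k1_closed_form_is_smoothed_column_means():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 2, size=(17, 6)).astype(float)
    model = fit_bernoulli_mixture(X, K=1)
    expected = (X.sum(axis=0) + A) / (len(X) + A + B)
    np.testing.assert_allclose(model.theta[0], expected, rtol=0, atol=1e-12)
    assert model.pi.tolist() == [1.0]
    assert (model.gamma == 1.0).all()
    np.testing.assert_allclose(model.data_loglik, mixture_loglik(X, model.pi, model.theta))


def test_loglik_trace_nondecreasing_across_seeds():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(25, 7))
        model = fit_bernoulli_mixture(X, K=3, n_restarts=3, seed=seed)
        diffs = np.diff(model.loglik_trace)
        assert (diffs >= -1e-9).all()


def test_em_at_least_as_good_as_best_hard_partition():
    for seed in range(8):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(int(rng.integers(4, 9)), int(rng.integers(2, 5))))
        model = fit_bernoulli_mixture(X.astype(float), K=2, n_restarts=20, seed=seed)
        assert model.loglik >= best_hard_partition_loglik(X.astype(float)) - 1e-6


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        fit_bernoulli_mixture(np.zeros((3, 2)), K=4)


def test_parameter_recovery_on_separated_clones():
    cfg = ct.SimulationConfig(seed=5, n_cells=200, doublet_rate=0.0,
                              poor_assay_fraction=0.0)
    obs = ct.simulate_dataset(cfg)
    res = ct.analyze_tables(obs.snv_counts, obs.sv_match_counts, obs.cells,
                            obs.truth.snv_sites, obs.truth.junctions,
                            ct.RunConfig(k=2, seed=5))
    truth_labels = [str(c) for c in obs.truth.cell_clones]
    assert adjusted_rand_score(truth_labels, res.model.labels) > 0.9
    # theta for clone k should be near (1 - ado) for carried assays, fp else
    order = {}
    for k in range(2):
        cells_k = res.model.labels == k
        clone = max(set(np.array(truth_labels)[cells_k]), key=list(np.array(truth_labels)[cells_k]).count)
        order[k] = clone
    for k, clone in order.items():
        g = obs.truth.clone_genotypes[clone].astype(float)
        expected = g * (1 - cfg.ado_rate) + (1 - g) * cfg.fp_rate
        assert np.abs(res.model.theta[k] - expected).mean() < 0.05


def test_theta_error_shrinks_with_sample_size():
    errs = []
    for n in (50, 200, 800):
        cfg = ct.SimulationConfig(seed=2, n_cells=n, doublet_rate=0.0,
                                  poor_assay_fraction=0.0)
        obs = ct.simulate_dataset(cfg)
        res = ct.analyze_tables(obs.snv_counts, obs.sv_match_counts, obs.cells,
                                obs.truth.snv_sites, obs.truth.junctions,
                                ct.RunConfig(k=2, seed=2))
        labels = [str(c) for c in obs.truth.cell_clones]
        err = 0.0
        for k in range(2):
            cells_k = res.model.labels == k
            clone = max(set(np.array(labels)[cells_k]),
                        key=list(np.array(labels)[cells_k]).count)
            g = obs.truth.clone_genotypes[clone].astype(float)
            expected = g * (1 - cfg.ado_rate) + (1 - g) * cfg.fp_rate
            err += np.abs(res.model.theta[k] - expected).mean() / 2
        errs.append(err)
    assert errs[2] < errs[0]


def test_fit_is_label_permutation_invariant_metrically():
    X = two_block_matrix(noise=0.05, seed=9)
    m1 = fit_bernoulli_mixture(X, K=2, seed=1)
    m2 = fit_bernoulli_mixture(X, K=2, seed=2)
    assert adjusted_rand_score(m1.labels, m2.labels) == 1.0
    assert m1.loglik == pytest.approx(m2.loglik, rel=1e-6)


def test_masked_entries_are_ignored_when_requested():
    X = two_block_matrix(n_per=15, j=10)
    mask = np.zeros_like(X)
    corrupt = np.random.default_rng(0).random(X.shape) < 0.25
    Xc = np.where(corrupt, 1 - X, X)  # corrupted entries carry wrong values
    mask[corrupt] = 1
    from clonotrace.qc import BinaryMatrix

    m = BinaryMatrix([f"c{i}" for i in range(30)], [f"a{j}" for j in range(10)],
                     Xc, mask)
    fit = fit_bernoulli_mixture(m, K=2, seed=0, use_mask=True)
    # masked fit should recover the clean block structure
    clean_labels = [0] * 15 + [1] * 15
    assert adjusted_rand_score(clean_labels, fit.labels) == 1.0


def make_model(theta):
    theta = np.asarray(theta, dtype=float)
    K = theta.shape[0]
    return ct.MixtureModel(K, np.full(K, 1 / K), theta,
                           np.full((4, K), 1 / K), [0.0])


def test_mutation_cluster_labels():
    theta = np.array([[0.92, 0.9, 0.02, 0.5], [0.88, 0.04, 0.03, 0.5]])
    out = derive_mutation_clusters(make_model(theta), ["a", "b", "c", "d"])
    labels = dict(zip(out.assay_id, out.label))
    assert labels["a"] == "ancestral"
    assert labels["b"] == "clone-0-specific"
    assert labels["c"] == "poor"
    assert labels["d"] == "ancestral"  # threshold is inclusive at 0.5


def test_doublet_cluster_is_union_of_two_clones():
    a = np.array([0.9, 0.9, 0.1, 0.1, 0.9])
    b = np.array([0.1, 0.1, 0.9, 0.9, 0.9])
    model = make_model([a, b, np.maximum(a, b)])
    assert flag_doublet_clusters(model) == [2]


def test_duplicate_clone_is_not_a_doublet():
    a = np.array([0.9, 0.9, 0.1, 0.1])
    b = np.array([0.1, 0.1, 0.9, 0.9])
    model = make_model([a, b, a.copy()])
    assert flag_doublet_clusters(model) == []


def test_doublet_flagging_needs_three_clusters():
    model = make_model([[0.9, 0.1], [0.1, 0.9]])
    assert flag_doublet_clusters(model) == []
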