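import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import non_negative_factorization

from mimelat.baselines import (NmfRelation, dominance_analysis,
                               dominance_stats, fit_log_network,
                               fit_nmf_relation, shuffled_null_contributions)
from mimelat.model import low_rank_approx
from mimelat.preprocess import normalize_relative
from mimelat.evaluation import score_metabolites
from mimelat.simulate import GeneratorConfig, generate_paired


# -- non-negative relation fit ---------------------------------------------

def test_identity_design_recovers_metabolite_matrix(rng):
    Me = rng.uniform(0.0, 1.0, size=(8, 5))
    relation = fit_nmf_relation(np.eye(8), Me, l1_strength=0.0, max_iter=5000)
    assert np.allclose(relation.values, Me, atol=1e-3)


def test_objective_trace_is_monotone_non_increasing(rng):
    Mi = rng.uniform(0, 1, size=(30, 10))
    Me = rng.uniform(0, 1, size=(30, 6))
    relation = fit_nmf_relation(Mi, Me, l1_strength=1.0)
    assert (np.diff(relation.objective_trace) <= 1e-9).all()


def test_negative_input_rejected(rng):
    with pytest.raises(ValueError, match="non-negative"):
        fit_nmf_relation(rng.normal(size=(5, 3)), rng.uniform(size=(5, 2)))


def test_multiplicative_updates_match_sklearn_oracle(rng):
    """Independent oracle: sklearn's non_negative_factorization solving the
    transposed problem with the microbiome factor held fixed."""
    Mi = rng.uniform(0.1, 1.0, size=(40, 8))
    Me = rng.uniform(0.1, 1.0, size=(40, 5))
    ours = fit_nmf_relation(Mi, Me, l1_strength=0.0, max_iter=20000, tol=1e-12)

    W0 = np.random.default_rng(1).uniform(0, 1, size=(5, 8))
    A_T, _, _ = non_negative_factorization(
        Me.T, W=W0, H=np.ascontiguousarray(Mi.T), n_components=8,
        init="custom", update_H=False, solver="mu", max_iter=20000,
        tol=1e-12)
    # both solve min ||Me - Mi A||: compare fits, not coefficients
    ours_fit = np.linalg.norm(Mi @ ours.values - Me)
    oracle_fit = np.linalg.norm(Mi @ A_T.T - Me)
    assert abs(ours_fit - oracle_fit) < 0.01 * oracle_fit


def test_two_seeds_reach_similar_objective(rng):
    Mi = rng.uniform(0.1, 1.0, size=(50, 10))
    Me = rng.uniform(0.1, 1.0, size=(50, 6))
    a = fit_nmf_relation(Mi, Me, l1_strength=1.0, seed=0)
    b = fit_nmf_relation(Mi, Me, l1_strength=1.0, seed=99)
    assert abs(a.objective_trace[-1] - b.objective_trace[-1]) \
        < 0.01 * abs(a.objective_trace[-1])


def test_relative_contributions_scale_invariant_without_l1(rng):
    Mi = rng.uniform(0.1, 1.0, size=(40, 6))
    Me = rng.uniform(0.1, 1.0, size=(40, 4))
    base = fit_nmf_relation(Mi, Me, l1_strength=0.0, tol=1e-10)
    scaled_me = Me.copy()
    scaled_me[:, 2] *= 7.5
    scaled = fit_nmf_relation(Mi, scaled_me, l1_strength=0.0, tol=1e-10)
    rb = dominance_stats(base, Mi).relative_contributions
    rs = dominance_stats(scaled, Mi).relative_contributions
    assert np.allclose(rb[:, 2], rs[:, 2], atol=1e-2)


# -- dominance statistics ---------------------------------------------------

def test_dominance_by_definition_examples():
    A = np.array([[0.9, 0.1], [0.1, 0.1]])  # met 0: 0.9 share; met 1: 0.5
    relation = NmfRelation(coefficients=A, l1_strength=0.0, seed=0)
    rep = dominance_stats(relation, np.eye(2), threshold=0.8)
    assert rep.max_contribution[0] == pytest.approx(0.9)
    assert rep.dominated_fraction == pytest.approx(0.5)


def test_uniform_coefficients_are_not_dominated(rng):
    relation = NmfRelation(coefficients=np.ones((10, 3)), l1_strength=0.0, seed=0)
    rep = dominance_stats(relation, rng.uniform(size=(6, 10)), threshold=0.8)
    assert np.allclose(rep.max_contribution, 0.1)
    assert rep.dominated_fraction == 0.0


def test_all_zero_coefficient_column_excluded_and_counted():
    A = pd.DataFrame([[0.9, 0.0], [0.1, 0.0]], index=["t1", "t2"],
                     columns=["m1", "m2"])
    relation = NmfRelation(coefficients=A, l1_strength=0.0, seed=0)
    rep = dominance_stats(relation, np.eye(2))
    assert rep.zero_metabolites == ["m2"]
    assert rep.dominated_fraction == 1.0  # only m1 enters the fraction


def test_true_producer_carries_max_contribution(dominant_dataset):
    ds, truth = dominant_dataset
    relation, report = dominance_analysis(ds, seed=0)
    top = relation.values.argmax(axis=0)
    assert (top == truth.producers).mean() >= 0.9
    assert report.dominated_fraction >= 0.9


def test_rare_producers_give_null_coefficient_frequency_correlation():
    sccs = []
    for seed in range(3):
        cfg = GeneratorConfig(regime="dominant", n_samples=150, n_taxa=50,
                              n_metabolites=30, noise_sd_met=0.05, seed=seed)
        ds, _ = generate_paired(cfg)
        _, report = dominance_analysis(ds, seed=seed)
        sccs.append(report.scc_coef_frequency)
    assert abs(np.mean(sccs)) <= 0.15


# -- shuffled null ----------------------------------------------------------

def test_shuffle_preserves_multiset_of_microbiome_rows(dominant_dataset, rng):
    ds, _ = dominant_dataset
    mi = normalize_relative(ds.microbiome.with_values(ds.microbiome.df, state="raw"),
                            axis="taxon-wise").df
    me = normalize_relative(ds.metabolites).df * 100
    Mi_before = np.sort(mi.to_numpy(), axis=0).copy()
    _, shuffled, _ = shuffled_null_contributions(mi, me, n_shuffles=1, seed=0)
    # a sample-order permutation leaves every column's multiset intact
    assert np.allclose(Mi_before, np.sort(mi.to_numpy(), axis=0))


def test_real_expectations_exceed_shuffled_under_alternative(dominant_dataset):
    ds, _ = dominant_dataset
    mi = normalize_relative(ds.microbiome.with_values(ds.microbiome.df, state="raw"),
                            axis="taxon-wise").df
    me = normalize_relative(ds.metabolites).df * 100
    real, _, test = shuffled_null_contributions(mi, me, n_shuffles=49, seed=0)
    assert test["real_mean"] > test["shuffled_mean"]
    assert test["p"] < 0.05


def test_zero_shuffles_rejected(dominant_dataset):
    ds, _ = dominant_dataset
    with pytest.raises(ValueError, match="n_shuffles"):
        shuffled_null_contributions(ds.microbiome.df,
                                    normalize_relative(ds.metabolites).df,
                                    n_shuffles=0)


# -- log network ------------------------------------------------------------

def test_log_network_exact_recovery_on_noise_free_linear_data(rng):
    n, p, m, r = 120, 20, 8, 5
    X = rng.standard_normal((n, p))
    A_true = rng.standard_normal((p, r)) @ rng.standard_normal((r, m)) / p
    Y = X @ A_true
    model = fit_log_network(X[:100], Y[:100], rank=r)
    rep = score_metabolites(Y[100:], model.predict(X[100:]))
    assert (rep.scc >= 0.99).all()


def test_log_network_rank_zero_rejected(rng):
    with pytest.raises(ValueError, match="rank"):
        fit_log_network(rng.normal(size=(10, 3)), rng.normal(size=(10, 2)), rank=0)


def test_log_network_min_norm_warning_when_underdetermined(rng):
    with pytest.warns(UserWarning, match="minimum-norm"):
        fit_log_network(rng.normal(size=(5, 8)), rng.normal(size=(5, 2)), rank=2)


def test_full_rank_log_network_equals_unconstrained_least_squares(rng):
    X = rng.standard_normal((60, 12))
    Y = rng.standard_normal((60, 5))
    model = fit_log_network(X, Y, rank=min(12, 5))
    A_ls, *_ = np.linalg.lstsq(X, Y, rcond=None)
    assert np.linalg.norm(model.A_star - A_ls) < 1e-6 * np.linalg.norm(A_ls)
    assert np.allclose(model.A_star, low_rank_approx(model.A, 5), atol=1e-10)
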