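import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mimelat._nn import (Encoder, lstsq_backward, lstsq_forward,
                         svd_truncate_backward, svd_truncate_forward)
from mimelat.model import (LatentConfig, LatentMetaboliteModel,
                           compute_relation_matrix, low_rank_approx,
                           train_locate)
from mimelat.preprocess import normalize_log, normalize_relative, zscore_fit_apply


# -- relation matrix --------------------------------------------------------

def test_relation_matrix_square_invertible_case(rng):
    Z = rng.normal(size=(6, 6))
    Me = rng.normal(size=(6, 4))
    A = compute_relation_matrix(Z, Me)
    assert np.allclose(A, np.linalg.inv(Z) @ Me, atol=1e-8)


def test_relation_matrix_orthonormal_columns_case(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(20, 5)))
    Me = rng.normal(size=(20, 3))
    A = compute_relation_matrix(Q, Me)
    assert np.allclose(A, Q.T @ Me, atol=1e-10)


def test_relation_matrix_matches_normal_equations_oracle(rng):
    Z = rng.normal(size=(50, 10))
    Me = rng.normal(size=(50, 7))
    A = compute_relation_matrix(Z, Me)
    oracle = np.linalg.solve(Z.T @ Z, Z.T @ Me)
    assert np.linalg.norm(A - oracle) < 1e-8 * np.linalg.norm(oracle)


def test_rank_deficient_z_warns_and_returns_min_norm(rng):
    Z = np.hstack([rng.normal(size=(12, 2))] * 2)  # rank 2 of 4 columns
    Me = rng.normal(size=(12, 3))
    with pytest.warns(UserWarning, match="rank-deficient"):
        A = compute_relation_matrix(Z, Me)
    oracle, *_ = np.linalg.lstsq(Z, Me, rcond=None)
    assert np.allclose(A, oracle, atol=1e-8)


def test_relation_matrix_needs_enough_samples(rng):
    with pytest.raises(ValueError, match="latent_dim samples"):
        compute_relation_matrix(rng.normal(size=(4, 6)), rng.normal(size=(4, 2)))


# -- low-rank approximation -------------------------------------------------

def test_full_rank_truncation_is_identity(rng):
    A = rng.normal(size=(8, 12))
    A_star = low_rank_approx(A, rank=8)
    assert np.linalg.norm(A_star - A) < 1e-6 * np.linalg.norm(A)


def test_exact_rank_one_matrix_is_reproduced(rng):
    A = np.outer(rng.normal(size=7), rng.normal(size=9))
    assert np.allclose(low_rank_approx(A, rank=1), A, atol=1e-10)


def test_truncation_matches_full_svd_oracle(rng):
    A = rng.normal(size=(10, 30))
    A_star = low_rank_approx(A, rank=6)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    oracle = (U[:, :6] * s[:6]) @ Vt[:6]
    assert np.linalg.norm(A_star - oracle) < 1e-6 * np.linalg.norm(oracle)
    assert np.linalg.matrix_rank(A_star, tol=1e-8) <= 6


def test_rank_zero_rejected(rng):
    with pytest.raises(ValueError, match="rank"):
        low_rank_approx(rng.normal(size=(4, 4)), 0)


# -- gradients --------------------------------------------------------------

def test_end_to_end_gradient_matches_finite_differences(rng):
    """The full backward pass (MSE -> truncated SVD -> least-squares solve
    -> encoder) agrees with central finite differences."""
    n, p, d, m, r = 12, 7, 4, 6, 2
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, m))
    enc = Encoder(p, (8, 5), d, activation="tanh", dropout=0.0, rng=rng)

    def loss_at(params):
        e = Encoder(p, (8, 5), d, activation="tanh", dropout=0.0)
        e.set_params([np.array(q) for q in params])
        Z, _ = e.forward(X, train=False)
        A, _ = lstsq_forward(Z, Y, 1e-8)
        A_star, _ = svd_truncate_forward(A, r)
        R = Z @ A_star - Y
        return float(np.mean(R * R))

    Z, cache = enc.forward(X, train=False)
    A, c_ls = lstsq_forward(Z, Y, 1e-8)
    A_star, c_svd = svd_truncate_forward(A, r)
    R = Z @ A_star - Y
    G_hat = 2.0 / R.size * R
    G_A = svd_truncate_backward(Z.T @ G_hat, c_svd, A.shape)
    G_Z_ls, _ = lstsq_backward(G_A, c_ls)
    grads = enc.backward(G_hat @ A_star.T + G_Z_ls, cache)

    params = [q.copy() for q in enc.params]
    eps = 1e-6
    for pi, (p0, g) in enumerate(zip(params, grads)):
        flat = [np.unravel_index(k, p0.shape)
                for k in rng.choice(p0.size, size=min(6, p0.size), replace=False)]
        for idx in flat:
            plus = [q.copy() for q in params]
            plus[pi][idx] += eps
            minus = [q.copy() for q in params]
            minus[pi][idx] -= eps
            fd = (loss_at(plus) - loss_at(minus)) / (2 * eps)
            assert abs(fd - g[idx]) <= 1e-5 * max(1.0, abs(fd))


@pytest.mark.parametrize("activation", ["relu", "elu", "tanh"])
def test_encoder_activations_forward_finite(rng, activation):
    enc = Encoder(5, (6, 4), 3, activation=activation, rng=rng)
    Z, _ = enc.forward(rng.normal(size=(7, 5)), train=False)
    assert Z.shape == (7, 3)
    assert np.isfinite(Z).all()


# -- training ---------------------------------------------------------------

def _processed_views(dataset, n_train=200):
    mi_log = normalize_log(dataset.microbiome)
    me_log = normalize_log(normalize_relative(dataset.metabolites))
    def cut(t, a, b):
        return t.with_values(t.df.iloc[a:b], state="log")
    n = dataset.n_samples
    mi_tr, mi_te, _ = zscore_fit_apply(cut(mi_log, 0, n_train), cut(mi_log, n_train, n))
    me_tr, me_te, _ = zscore_fit_apply(cut(me_log, 0, n_train), cut(me_log, n_train, n))
    return mi_tr.df, me_tr.df, mi_te.df, me_te.df


@pytest.fixture(scope="module")
def fitted(latent_dataset):
    ds, truth = latent_dataset
    mi_tr, me_tr, mi_te, me_te = _processed_views(ds)
    cfg = LatentConfig(latent_dim=10, lowrank_rank=10, epochs=120, seed=0)
    model = train_locate(mi_tr, me_tr, cfg)
    return model, mi_tr, me_tr, mi_te, me_te


def test_predict_on_training_data_reproduces_final_loss(fitted):
    model, mi_tr, me_tr, *_ = fitted
    pred = model.predict(mi_tr)
    loss = float(np.mean((pred.to_numpy() - me_tr.to_numpy()) ** 2))
    assert abs(loss - model.final_train_loss_) < 1e-6


def test_embed_times_relation_equals_predict(fitted):
    model, mi_tr, *_ = fitted
    rep = model.embed(mi_tr)
    assert np.array_equal(rep.Z @ model.A_star_, model.predict(mi_tr).to_numpy())


def test_latent_dimension_is_ten_by_default(fitted):
    model, mi_tr, *_ = fitted
    assert model.embed(mi_tr).Z.shape[1] == 10
    assert LatentConfig().latent_dim == 10


def test_identical_microbiome_rows_map_to_identical_latent_rows(fitted):
    model, mi_tr, *_ = fitted
    dup = pd.concat([mi_tr.iloc[:1], mi_tr.iloc[:1]], axis=0)
    dup.index = ["a", "b"]
    Z = model.embed(dup).Z
    assert np.array_equal(Z[0], Z[1])


def test_prediction_is_batch_independent(fitted):
    model, mi_tr, _, mi_te, _ = fitted
    joint = model.predict(mi_te).to_numpy()
    single = np.vstack([model.predict(mi_te.iloc[[i]]).to_numpy()
                        for i in range(5)])
    assert np.allclose(joint[:5], single, atol=1e-12)


def test_relation_matrix_rank_constraint_holds(fitted):
    model, *_ = fitted
    s = np.linalg.svd(model.A_star_, compute_uv=False)
    assert (s[model.config.lowrank_rank:] < 1e-8 * s[0]).all()


def test_seed_determinism_of_training(latent_dataset):
    ds, _ = latent_dataset
    mi_tr, me_tr, *_ = _processed_views(ds)
    cfg = LatentConfig(latent_dim=10, lowrank_rank=6, epochs=15, seed=7)
    m1 = train_locate(mi_tr, me_tr, cfg)
    m2 = train_locate(mi_tr, me_tr, LatentConfig(latent_dim=10, lowrank_rank=6,
                                                 epochs=15, seed=7))
    assert np.array_equal(m1.A_star_, m2.A_star_)
    assert np.array_equal(m1.loss_trace_, m2.loss_trace_)


def test_doubling_epochs_never_raises_best_loss(latent_dataset):
    ds, _ = latent_dataset
    mi_tr, me_tr, *_ = _processed_views(ds)
    short = train_locate(mi_tr, me_tr, LatentConfig(latent_dim=10, epochs=20, seed=3))
    long = train_locate(mi_tr, me_tr, LatentConfig(latent_dim=10, epochs=40, seed=3))
    assert long.loss_trace_.min() <= short.loss_trace_.min() + 1e-12


def test_heldout_recovery_on_noise_free_latent_signal(fitted):
    model, _, _, mi_te, me_te = fitted
    pred = model.predict(mi_te)
    sccs = np.array([spearmanr(me_te.iloc[:, j], pred.iloc[:, j]).statistic
                     for j in range(me_te.shape[1])])
    assert (sccs >= 0.9).mean() >= 0.9


def test_destroyed_pairing_gives_null_scores(latent_dataset, rng):
    ds, _ = latent_dataset
    mi_tr, me_tr, mi_te, me_te = _processed_views(ds)
    shuffled = me_tr.to_numpy().copy()
    for j in range(shuffled.shape[1]):  # permute each metabolite independently
        shuffled[:, j] = shuffled[rng.permutation(shuffled.shape[0]), j]
    model = train_locate(mi_tr, pd.DataFrame(shuffled, index=me_tr.index,
                                             columns=me_tr.columns),
                         LatentConfig(latent_dim=10, lowrank_rank=10,
                                      epochs=120, seed=0))
    pred = model.predict(mi_te)
    sccs = np.array([spearmanr(me_te.iloc[:, j], pred.iloc[:, j]).statistic
                     for j in range(me_te.shape[1])])
    assert abs(np.nanmean(sccs)) <= 0.1


def test_feature_mismatch_is_reported(fitted):
    model, mi_tr, *_ = fitted
    wrong = mi_tr.rename(columns={mi_tr.columns[0]: "unknown_taxon"})
    with pytest.raises(ValueError, match="feature mismatch"):
        model.predict(wrong)


def test_too_few_samples_rejected(rng):
    X = pd.DataFrame(rng.normal(size=(5, 20)))
    Y = pd.DataFrame(rng.normal(size=(5, 4)))
    with pytest.raises(ValueError, match="latent_dim"):
        train_locate(X, Y, LatentConfig(latent_dim=10, epochs=2))


def test_serialization_round_trip(fitted, tmp_path):
    model, mi_tr, *_ = fitted
    path = tmp_path / "model.json"
    model.save(path)
    back = LatentMetaboliteModel.load(path)
    assert np.allclose(back.predict(mi_tr).to_numpy(),
                       model.predict(mi_tr).to_numpy(), atol=1e-12)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        LatentConfig(latent_dim=0)
    with pytest.raises(ValueError):
        LatentConfig(dropout_rate=1.0)
    with pytest.raises(ValueError):
        LatentConfig(activation="gelu")
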