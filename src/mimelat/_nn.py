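"""Minimal feed-forward network with hand-derived backpropagation.

The latent model needs gradients that flow from a mean-squared
reconstruction loss through (i) a truncated SVD, (ii) a least-squares
solve (the Moore-Penrose pseudo-inverse in normal-equations form with a
tiny ridge jitter), and (iii) a small fully connected encoder.  No
autodiff framework ships with the package, so the three vector-Jacobian
products are written out explicitly:

* the solve ``A = (Z'Z + lam I)^{-1} Z' Me`` uses the standard VJPs of a
  linear solve;
* the truncated SVD uses the exact SVD backward formula (the F-matrix
  form with ``F_ij = 1/(s_j^2 - s_i^2)``), with clamped denominators for
  near-degenerate spectra.

All of it is checked against central finite differences in the test
suite, which is the authoritative statement of correctness.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# activations


def _act(name: str):
    if name == "relu":
        return (lambda x: np.maximum(x, 0.0),
                lambda x, y: (x > 0).astype(float))
    if name == "elu":
        def f(x):
            return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))

        def df(x, y):
            return np.where(x > 0, 1.0, y + 1.0)
        return f, df
    if name == "tanh":
        return (np.tanh, lambda x, y: 1.0 - y ** 2)
    raise ValueError(f"unknown activation {name!r} (relu, elu, tanh)")


# ---------------------------------------------------------------------------
# encoder


class Encoder:
    """3-layer fully connected encoder: in -> h1 -> h2 -> latent.

    The two hidden layers use the configured activation followed by
    (inverted) dropout during training; the output layer is linear.
    """

    def __init__(self, n_in: int, hidden: tuple[int, int], n_out: int,
                 activation: str = "elu", dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.dropout = dropout
        self._f, self._df = _act(activation)
        sizes = [n_in, hidden[0], hidden[1], n_out]
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))  # Glorot
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.asarray(p, dtype=float) for p in params[:n]]
        self.biases = [np.asarray(p, dtype=float) for p in params[n:]]

    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False):
        """Return (Z, cache).  Dropout masks are drawn from ``rng`` when
        training; inference is deterministic."""
        cache = {"X": X, "pre": [], "post": [], "masks": []}
        h = X
        for layer in range(3):
            pre = h @ self.weights[layer] + self.biases[layer]
            if layer < 2:
                post = self._f(pre)
                if train and self.dropout > 0.0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random(post.shape) < keep) / keep
                    post = post * mask
                else:
                    mask = None
                cache["masks"].append(mask)
            else:
                post = pre
            cache["pre"].append(pre)
            cache["post"].append(post)
            h = post
        return h, cache

    def backward(self, G_out: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. all parameters given dL/dZ."""
        gW = [None] * 3
        gb = [None] * 3
        g = G_out
        for layer in (2, 1, 0):
            inp = cache["X"] if layer == 0 else cache["post"][layer - 1]
            if layer < 2:
                mask = cache["masks"][layer]
                if mask is not None:
                    g = g * mask
                g = g * self._df(cache["pre"][layer],
                                 self._f(cache["pre"][layer]))
            gW[layer] = inp.T @ g
            gb[layer] = g.sum(axis=0)
            if layer > 0:
                g = g @ self.weights[layer].T
        return gW + gb


# ---------------------------------------------------------------------------
# Adam


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


# ---------------------------------------------------------------------------
# differentiable least-squares solve (pseudo-inverse, normal equations)


def lstsq_forward(Z: np.ndarray, Me: np.ndarray, jitter: float = 1e-8):
    """A = (Z'Z + jitter I)^{-1} Z' Me, plus a cache for the backward pass."""
    d = Z.shape[1]
    M = Z.T @ Z + jitter * np.eye(d)
    P = Z.T @ Me
    A = np.linalg.solve(M, P)
    return A, (Z, Me, M, A)


def lstsq_backward(G_A: np.ndarray, cache):
    """VJP of the solve: returns (dL/dZ, dL/dMe)."""
    Z, Me, M, A = cache
    S = np.linalg.solve(M, G_A)          # M symmetric
    G_M = -S @ A.T
    G_Z = Z @ (G_M + G_M.T) + Me @ S.T
    G_Me = Z @ S
    return G_Z, G_Me


# ---------------------------------------------------------------------------
# truncated SVD with exact backward


def svd_truncate_forward(A: np.ndarray, rank: int):
    """Best rank-``rank`` approximation via exact thin SVD, with cache."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    r = min(rank, s.shape[0])
    A_star = (U[:, :r] * s[:r]) @ Vt[:r]
    return A_star, (U, s, Vt, r)


def _svd_backward_tall(U, s, Vt, gU, gs, gV, shape):
    """SVD backward for an (n x m) matrix with n >= m, thin SVD.

    F-matrix formulation; denominators ``s_j^2 - s_i^2`` and the ``1/s``
    factors are clamped to keep near-degenerate spectra finite (the
    clamped directions carry negligible loss signal for the truncation
    use-case, where only well-separated leading triplets are retained).
    """
    n, m = shape
    V = Vt.T
    s2 = s ** 2
    diff = s2[None, :] - s2[:, None]
    eps = 1e-12 * max(s2.max(), 1.0)
    F = np.where(np.abs(diff) > eps, 1.0 / np.where(diff == 0, 1.0, diff), 0.0)
    np.fill_diagonal(F, 0.0)
    s_inv = np.where(s > 1e-12 * max(s.max(), 1.0), 1.0 / np.where(s == 0, 1.0, s), 0.0)

    UtgU = U.T @ gU
    VtgV = V.T @ gV
    J = F * (UtgU - UtgU.T)
    K = F * (VtgV - VtgV.T)
    inner = J * s[None, :] + s[:, None] * K + np.diag(gs)
    dA = U @ inner @ Vt
    # off-subspace terms
    dA += (gU - U @ UtgU) * s_inv[None, :] @ Vt
    dA += U @ (s_inv[:, None] * (gV - V @ VtgV).T)
    return dA


def svd_truncate_backward(G: np.ndarray, cache, shape):
    """VJP of the rank-r truncation ``A -> U_r S_r V_r'``."""
    U, s, Vt, r = cache
    V = Vt.T
    k = s.shape[0]
    gU = np.zeros_like(U)
    gV = np.zeros_like(V)
    gs = np.zeros_like(s)
    gU[:, :r] = G @ V[:, :r] * s[:r][None, :]
    gV[:, :r] = G.T @ U[:, :r] * s[:r][None, :]
    gs[:r] = np.einsum("ij,ij->j", U[:, :r], G @ V[:, :r])
    n, m = shape
    if n >= m:
        return _svd_backward_tall(U, s, Vt, gU, gs, gV, (n, m))
    # wide matrix: differentiate the transpose and transpose back
    return _svd_backward_tall(V, s, U.T, gV, gs, gU, (m, n)).T
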