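"""Cosine-similarity deep canonical correlation analysis.

Classical DCCA trains two projection networks to maximise the canonical
correlation between their outputs. The variant implemented here replaces
the correlation objective with the cosine of the two *centered* projected
views, flattened to vectors:

    J = tr(H1c' H2c) / (||H1c||_F ||H2c||_F)  in [-1, 1]

J is invariant to positive rescaling of either view and needs no
distributional assumptions, which also makes it less sensitive to outliers
than a covariance-based objective. The training loss is ``-J`` so that
minimising the total loss maximises alignment.

Two gradient forms are exposed. The ``exact`` form,

    dJ/dH1c = H2c/(||H1c|| ||H2c||) - J * H1c/||H1c||^2,

is the true derivative (verified by finite differences in the tests). The
``as_printed`` form keeps only the first term; it coincides with the exact
gradient precisely when J = 0 and is retained for comparison. Training uses
``exact``.

A closed-form linear CCA (whitened cross-covariance SVD) is provided as the
independent oracle the deep objective is validated against.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .autodiff import Tensor
from .layers import Linear, Module

__all__ = [
    "center_views", "pairwise_cosine", "matrix_cosine_objective",
    "objective_gradient", "cos_dcca_loss", "cos_dcca_loss_t",
    "mean_pairwise_cosine", "linear_cca_oracle",
    "ProjectionNet", "train_linear_projections",
]

_EPS_TRAIN = 1e-12


def center_views(h1: np.ndarray, h2: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the per-dimension sample mean from each view (samples as rows)."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("the two views must have identical shape")
    if h1.shape[0] < 2:
        raise ValueError("centering requires at least two samples")
    return h1 - h1.mean(axis=0), h2 - h2.mean(axis=0)


def pairwise_cosine(h1: np.ndarray, h2: np.ndarray,
                    eps: float | None = None) -> float:
    """Cosine similarity of two vectors; errors on zero vectors in strict mode."""
    h1 = np.ravel(np.asarray(h1, dtype=float))
    h2 = np.ravel(np.asarray(h2, dtype=float))
    n1, n2 = np.linalg.norm(h1), np.linalg.norm(h2)
    if eps is None and (n1 == 0 or n2 == 0):
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(h1 @ h2 / (n1 * n2 + (eps or 0.0)))


def matrix_cosine_objective(h1c: np.ndarray, h2c: np.ndarray,
                            eps: float | None = None) -> float:
    """J = tr(H1c' H2c) / (||H1c||_F ||H2c||_F), the flattened-matrix cosine."""
    h1c = np.asarray(h1c, dtype=float)
    h2c = np.asarray(h2c, dtype=float)
    n1 = np.linalg.norm(h1c)
    n2 = np.linalg.norm(h2c)
    if eps is None and (n1 == 0 or n2 == 0):
        raise ValueError("objective undefined for an all-zero view")
    e = eps or 0.0
    return float((h1c * h2c).sum() / (n1 * n2 + e))


def mean_pairwise_cosine(h1c: np.ndarray, h2c: np.ndarray) -> float:
    """Per-sample mean cosine (the alternative reading of the objective)."""
    return float(np.mean([
        pairwise_cosine(a, b) for a, b in zip(h1c, h2c)]))


def objective_gradient(h1c: np.ndarray, h2c: np.ndarray,
                       form: str = "exact"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of J with respect to each centered view.

    `form="exact"` is the full derivative; `form="as_printed"` drops the
    -J * H / ||H||^2 term (the two agree exactly when J = 0).
    """
    h1c = np.asarray(h1c, dtype=float)
    h2c = np.asarray(h2c, dtype=float)
    n1 = np.linalg.norm(h1c)
    n2 = np.linalg.norm(h2c)
    if n1 == 0 or n2 == 0:
        raise ValueError("gradient undefined for an all-zero view")
    g1 = h2c / (n1 * n2)
    g2 = h1c / (n1 * n2)
    if form == "as_printed":
        return g1, g2
    if form != "exact":
        raise ValueError(f"unknown gradient form: {form!r}")
    j = matrix_cosine_objective(h1c, h2c)
    return g1 - j * h1c / n1**2, g2 - j * h2c / n2**2


def cos_dcca_loss(h1p: np.ndarray, h2p: np.ndarray,
                  eps: float | None = None) -> float:
    """Alignment loss -J on centered views; minimising it maximises J."""
    h1c, h2c = center_views(h1p, h2p)
    return -matrix_cosine_objective(h1c, h2c, eps=eps)


def cos_dcca_loss_t(h1p: Tensor, h2p: Tensor,
                    eps: float = _EPS_TRAIN) -> Tensor:
    """Autodiff version of the alignment loss, used inside training."""
    n = h1p.shape[0]
    if n < 2:
        raise ValueError("alignment loss requires at least two samples")
    h1c = h1p - h1p.mean(axis=0, keepdims=True)
    h2c = h2p - h2p.mean(axis=0, keepdims=True)
    n1 = ((h1c * h1c).sum() + eps).sqrt()
    n2 = ((h2c * h2c).sum() + eps).sqrt()
    j = (h1c * h2c).sum() / (n1 * n2 + eps)
    return -j


# ----------------------------------------------------------------------
def linear_cca_oracle(x1: np.ndarray, x2: np.ndarray, k: int = 1,
                      ridge: float = 1e-8
                      ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Closed-form linear CCA via the whitened cross-covariance SVD.

    Returns the top-k canonical correlations (descending, clipped to [0, 1])
    and the projection bases (columns). Covariance diagonals are regularised
    by `ridge`; rank-deficient views with ridge=0 raise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n, d1 = x1.shape
    d2 = x2.shape[1]
    if n <= max(d1, d2):
        raise ValueError("need more samples than the larger view dimension")
    x1c = x1 - x1.mean(axis=0)
    x2c = x2 - x2.mean(axis=0)
    s11 = x1c.T @ x1c / (n - 1) + ridge * np.eye(d1)
    s22 = x2c.T @ x2c / (n - 1) + ridge * np.eye(d2)
    s12 = x1c.T @ x2c / (n - 1)
    for s in (s11, s22):
        ev = linalg.eigvalsh(s)
        if ev[0] <= 1e-10 * max(ev[-1], 1e-30):
            raise ValueError("rank-deficient views; use a positive ridge")
    r11 = linalg.cholesky(s11, lower=True)
    r22 = linalg.cholesky(s22, lower=True)
    m = linalg.solve_triangular(r11, s12, lower=True)
    m = linalg.solve_triangular(r22, m.T, lower=True).T
    u, s, vt = linalg.svd(m)
    corr = np.clip(s[:k], 0.0, 1.0)
    a = linalg.solve_triangular(r11.T, u[:, :k], lower=False)
    b = linalg.solve_triangular(r22.T, vt[:k].T, lower=False)
    return corr, (a, b)


# ----------------------------------------------------------------------
class ProjectionNet(Module):
    """Per-view projection f(X; alpha): d_in -> hidden1 -> hidden2 -> o.

    With ``nonlinearity="identity"`` the composition is linear, which is the
    regime directly comparable against the closed-form CCA oracle.
    """

    def __init__(self, d_in: int, out_dim: int, rng: np.random.Generator,
                 hidden1: int = 64, hidden2: int = 128,
                 nonlinearity: str = "relu"):
        if out_dim < 1:
            raise ValueError("output dimension must be >= 1")
        if nonlinearity not in ("relu", "identity"):
            raise ValueError(f"unknown nonlinearity: {nonlinearity!r}")
        self.nonlinearity = nonlinearity
        self.l1 = Linear(d_in, hidden1, rng)
        self.l2 = Linear(hidden1, hidden2, rng)
        self.l3 = Linear(hidden2, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.l1(x)
        if self.nonlinearity == "relu":
            h = h.relu()
        h = self.l2(h)
        if self.nonlinearity == "relu":
            h = h.relu()
        return self.l3(h)


def train_linear_projections(x1: np.ndarray, x2: np.ndarray, out_dim: int = 1,
                             steps: int = 500, lr: float = 1e-2,
                             seed: int = 0) -> tuple[float, float]:
    """Train identity-nonlinearity projection nets by gradient ascent on J.

    Returns (per-sample Pearson correlation of the 1-D projections, final J).
    Used to show the deep objective approaches the linear CCA oracle.
    """
    from .layers import Adam

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    f1 = ProjectionNet(x1.shape[1], out_dim, rng, nonlinearity="identity")
    f2 = ProjectionNet(x2.shape[1], out_dim, rng, nonlinearity="identity")
    t1, t2 = Tensor(x1), Tensor(x2)
    opt = Adam(list(f1.parameters()) + list(f2.parameters()), lr=lr)
    for _ in range(steps):
        loss = cos_dcca_loss_t(f1(t1), f2(t2))
        opt.zero_grad()
        loss.backward()
        opt.step()
    h1 = f1(t1).data.ravel()
    h2 = f2(t2).data.ravel()
    corr = float(np.corrcoef(h1, h2)[0, 1])
    return corr, -float(loss.data)
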