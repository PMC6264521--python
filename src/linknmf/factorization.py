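"""Jointly regularized NMF for link prediction, and the plain-NMF baseline.

The joint model couples the network adjacency A with an auxiliary similarity
matrix S through a shared non-negative basis W:

    Q = ||A - W H1||_F^2 + alpha ||S - W H2||_F^2
        + beta (||H1||_F^2 + ||H2||_F^2),   W, H1, H2 >= 0

where alpha balances structure against auxiliary information and beta is a
ridge penalty on the coefficient factors. Q is minimized by multiplicative
updates (Gauss-Seidel sweep over W, H1, H2):

    W  <- W  .* (A H1' + alpha S H2') ./ (W H1 H1' + alpha W H2 H2')
    H1 <- H1 .* (W' A)                ./ (W' W H1 + beta H1)
    H2 <- H2 .* (alpha W' S)          ./ (alpha W' W H2 + beta H2)

Link scores are the symmetrized reconstruction (W H1 + (W H1)') / 2 over
unobserved non-self pairs. Estimators follow the scikit-learn protocol
(``get_params``/``set_params``, trailing-underscore fitted attributes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .attributes import attribute_similarity
from .graph import AttributeTable, Graph
from .similarity import structural_similarity

__all__ = [
    "FactorizationState",
    "ScoreMatrix",
    "JointNMF",
    "PlainNMF",
    "initialize_factors",
    "objective",
    "update_step",
    "build_inputs",
    "default_rank",
    "COMBINATION_MODES",
]

COMBINATION_MODES = ("A+S", "A+Sim", "Sim+S")


@dataclass
class FactorizationState:
    """Non-negative factors plus the iteration/objective trace."""

    W: np.ndarray
    H1: np.ndarray
    H2: np.ndarray
    iteration: int = 0
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class ScoreMatrix:
    """Pairwise link scores with a mask of rankable candidate pairs.

    ``candidate_mask`` is True exactly on unobserved non-self pairs of the
    training network — the pairs a predictor is allowed to rank.
    """

    values: np.ndarray
    candidate_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def default_rank(n: int) -> int:
    """Conservative latent dimension: ``min(20, n // 5)``, at least 1."""
    return max(1, min(20, n // 5))


def initialize_factors(n: int, k: int, seed: int) -> FactorizationState:
    """Draw W (n x k), H1 and H2 (k x n) i.i.d. uniform on (0, 1]."""
    if n < 2 or k < 1:
        raise ValueError("need n >= 2 and k >= 1")
    rng = np.random.default_rng(seed)
    # 1 - U with U in [0,1) keeps every entry strictly positive
    W = 1.0 - rng.random((n, k))
    H1 = 1.0 - rng.random((k, n))
    H2 = 1.0 - rng.random((k, n))
    return FactorizationState(W=W, H1=H1, H2=H2)


def _validate_inputs(A: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    S = np.asarray(S, dtype=float)
    for name, M in (("A", A), ("S", S)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"{name} must be square")
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError(f"{name} must be symmetric")
        if (M < 0).any():
            raise ValueError(f"{name} must be non-negative")
    if A.shape != S.shape:
        raise ValueError(f"A and S shapes differ: {A.shape} vs {S.shape}")
    return A, S


def objective(
    state: FactorizationState,
    A: np.ndarray,
    S: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Evaluate the coupled objective Q for the current factors."""
    W, H1, H2 = state.W, state.H1, state.H2
    if A.shape != (W.shape[0], H1.shape[1]) or S.shape != (W.shape[0], H2.shape[1]):
        raise ValueError("factor shapes inconsistent with A/S")
    ra = A - W @ H1
    rs = S - W @ H2
    return float(
        np.sum(ra * ra)
        + alpha * np.sum(rs * rs)
        + beta * (np.sum(H1 * H1) + np.sum(H2 * H2))
    )


def update_step(
    state: FactorizationState,
    A: np.ndarray,
    S: np.ndarray,
    alpha: float,
    beta: float,
    eps: float = 1e-10,
) -> FactorizationState:
    """One multiplicative sweep: W, then H1, then H2, each using the freshest
    factors. Denominators are floored at ``eps`` so exact fixed points are
    preserved while zero denominators stay safe. Raises on NaN/Inf factors.
    """
    W, H1, H2 = state.W, state.H1, state.H2

    num = A @ H1.T + alpha * (S @ H2.T)
    den = W @ (H1 @ H1.T) + alpha * (W @ (H2 @ H2.T))
    W = W * (num / np.maximum(den, eps))

    num = W.T @ A
    den = (W.T @ W) @ H1 + beta * H1
    H1 = H1 * (num / np.maximum(den, eps))

    num = alpha * (W.T @ S)
    den = alpha * ((W.T @ W) @ H2) + beta * H2
    H2 = H2 * (num / np.maximum(den, eps))

    for name, M in (("W", W), ("H1", H1), ("H2", H2)):
        if not np.isfinite(M).all():
            raise FloatingPointError(
                f"non-finite entries in {name} at iteration {state.iteration + 1}"
            )
    return FactorizationState(
        W=W,
        H1=H1,
        H2=H2,
        iteration=state.iteration + 1,
        objective_trace=list(state.objective_trace),
    )


class JointNMF(BaseEstimator):
    """Link predictor factorizing adjacency and auxiliary similarity jointly.

    Parameters
    ----------
    k : int or None, default None
        Latent dimension; None selects ``min(20, n // 5)`` at fit time.
        Should stay well below n/2.
    alpha : float, default 4.0
        Weight of the auxiliary-similarity residual.
    beta : float, default 32.0
        Ridge penalty on the coefficient factors H1, H2.
    max_iter : int, default 500
        Maximum number of multiplicative sweeps.
    rel_tol : float, default 1e-6
        Stop when the relative objective change drops below this; the first
        sweep always runs.
    eps : float, default 1e-10
        Elementwise floor on update denominators.
    random_state : int, default 0
        Seed for the uniform (0, 1] factor initialization.

    Attributes
    ----------
    W_, H1_, H2_ : ndarray
        Fitted non-negative factors.
    n_iter_ : int
        Sweeps performed.
    objective_trace_ : list of float
        Objective value at initialization and after every sweep.
    converged_ : bool
        Whether the relative-change criterion was met before ``max_iter``.
    """

    def __init__(
        self,
        k: int | None = None,
        alpha: float = 4.0,
        beta: float = 32.0,
        max_iter: int = 500,
        rel_tol: float = 1e-6,
        eps: float = 1e-10,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.alpha = alpha
        self.beta = beta
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.eps = eps
        self.random_state = random_state

    def _resolve_k(self, n: int) -> int:
        k = self.k if self.k is not None else default_rank(n)
        if k >= n / 2:
            warnings.warn(
                f"latent dimension k={k} is not far below n/2={n / 2:.0f}; "
                "the low-rank approximation may be meaningless",
                stacklevel=3,
            )
        return k

    def fit(self, A: np.ndarray, S: np.ndarray, init: FactorizationState | None = None):
        """Run multiplicative updates until convergence or ``max_iter``.

        ``init`` overrides the seeded random initialization (used for
        paired comparisons across models).
        """
        A, S = _validate_inputs(A, S)
        n = A.shape[0]
        k = self._resolve_k(n)
        state = (
            init
            if init is not None
            else initialize_factors(n, k, seed=self.random_state)
        )
        q = objective(state, A, S, self.alpha, self.beta)
        state.objective_trace = [q]
        self.converged_ = False
        for _ in range(self.max_iter):
            state = update_step(state, A, S, self.alpha, self.beta, self.eps)
            q_new = objective(state, A, S, self.alpha, self.beta)
            state.objective_trace.append(q_new)
            if q > 0 and abs(q_new - q) / q < self.rel_tol:
                q = q_new
                self.converged_ = True
                break
            q = q_new
        self.W_, self.H1_, self.H2_ = state.W, state.H1, state.H2
        self.n_iter_ = state.iteration
        self.objective_trace_ = state.objective_trace
        self._A = A
        return self

    def predict_scores(self) -> ScoreMatrix:
        """Symmetrized reconstruction of A, masked to unobserved non-self pairs."""
        R = self.W_ @ self.H1_
        values = (R + R.T) / 2
        mask = (self._A == 0) & ~np.eye(self._A.shape[0], dtype=bool)
        return ScoreMatrix(values=values, candidate_mask=mask)

    def fit_predict_scores(self, A, S, init=None) -> ScoreMatrix:
        return self.fit(A, S, init=init).predict_scores()

    @property
    def state_(self) -> FactorizationState:
        return FactorizationState(
            W=self.W_,
            H1=self.H1_,
            H2=self.H2_,
            iteration=self.n_iter_,
            objective_trace=list(self.objective_trace_),
        )


class PlainNMF(BaseEstimator):
    """Two-factor NMF baseline: minimize ``||A - W H||_F^2`` with the
    Lee-Seung multiplicative rules, same stopping criterion as `JointNMF`,
    scores from the symmetrized reconstruction.
    """

    def __init__(
        self,
        k: int | None = None,
        max_iter: int = 500,
        rel_tol: float = 1e-6,
        eps: float = 1e-10,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.eps = eps
        self.random_state = random_state

    def fit(self, A: np.ndarray, y=None, init: FactorizationState | None = None):
        A, _ = _validate_inputs(A, A)
        n = A.shape[0]
        k = self.k if self.k is not None else default_rank(n)
        state = (
            init
            if init is not None
            else initialize_factors(n, k, seed=self.random_state)
        )
        W, H = state.W, state.H1
        r = A - W @ H
        q = float(np.sum(r * r))
        trace = [q]
        self.converged_ = False
        n_iter = 0
        for _ in range(self.max_iter):
            W = W * ((A @ H.T) / np.maximum(W @ (H @ H.T), self.eps))
            H = H * ((W.T @ A) / np.maximum((W.T @ W) @ H, self.eps))
            if not (np.isfinite(W).all() and np.isfinite(H).all()):
                raise FloatingPointError(f"non-finite factors at iteration {n_iter + 1}")
            n_iter += 1
            r = A - W @ H
            q_new = float(np.sum(r * r))
            trace.append(q_new)
            if q > 0 and abs(q_new - q) / q < self.rel_tol:
                q = q_new
                self.converged_ = True
                break
            q = q_new
        self.W_, self.H_ = W, H
        self.n_iter_ = n_iter
        self.objective_trace_ = trace
        self._A = A
        return self

    def predict_scores(self) -> ScoreMatrix:
        R = self.W_ @ self.H_
        values = (R + R.T) / 2
        mask = (self._A == 0) & ~np.eye(self._A.shape[0], dtype=bool)
        return ScoreMatrix(values=values, candidate_mask=mask)

    def fit_predict_scores(self, A, init=None) -> ScoreMatrix:
        return self.fit(A, init=init).predict_scores()


def build_inputs(
    train_graph: Graph,
    attrs: AttributeTable | None,
    mode: str,
    sim_method: str | None = None,
    attr_metric: str = "cosine",
    scale_sim: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the two factor targets for a combination mode.

    A+S couples adjacency with attribute similarity; A+Sim couples adjacency
    with a structural index of the training graph; Sim+S replaces adjacency
    with the structural index and uses attribute similarity as auxiliary.
    Every auxiliary matrix is computed from the training graph only.
    """
    if mode not in COMBINATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; valid: {COMBINATION_MODES}")
    need_attrs = mode in ("A+S", "Sim+S")
    need_sim = mode in ("A+Sim", "Sim+S")
    if need_attrs and attrs is None:
        raise ValueError(f"mode {mode} requires an attribute table")
    if need_sim and sim_method is None:
        raise ValueError(f"mode {mode} requires a structural sim_method")

    A = train_graph.adjacency()
    if mode == "A+S":
        S = attribute_similarity(attrs, metric=attr_metric).values
        return A, S
    sim = structural_similarity(train_graph, sim_method, scaled=scale_sim).values
    if mode == "A+Sim":
        return A, sim
    S = attribute_similarity(attrs, metric=attr_metric).values
    return sim, S
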