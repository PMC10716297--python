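"""Learning rules for embedding bipolar patterns as Hopfield fixed points.

One-shot rules (Hebbian, projection), incremental rules (Storkey with
optional few-shot repetition), iterative perceptron-style rules driven by
the pattern-embedding conditions h_i^k xi_i^k > T (Rule I / "iterative
Hebbian" IH, Rule II with proportional increments, the row-normalized GKM
variant, a gradient solver with an exponential-barrier objective DEB), and
IRPUSH: the symmetric, randomly-partial iterative Hebbian rule designed for
oscillator hardware whose couplings must be bidirectional and low precision.

All rules produce zero-diagonal matrices; the iterative rules sweep patterns
in training-set order and neurons in ascending index, recomputing margins
from the live weights. Thresholds T are on the raw (unnormalized) margin
scale: increments are Hebbian terms scaled by 1/(N-1), so one update raises
the failing neuron's own margin by exactly 1, and the classic unit threshold
of Rule I corresponds to T = N here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import WeightMatrix, embedding_margins
from .patterns import PatternSet

__all__ = [
    "TrainingConfig",
    "TrainingResult",
    "hebbian_train",
    "storkey_train",
    "projection_train",
    "ih_train",
    "rule2_train",
    "gkm_train",
    "deb_train",
    "irpush_train",
    "train",
    "RULES",
]

MAX_EPOCHS_DEFAULT = 2000


@dataclass
class TrainingConfig:
    """Parameters selecting and tuning a learning rule.

    T is the embedding-condition threshold, PF the fraction of a failing
    neuron's connections updated per event (IRPUSH only), `repetitions`
    the number of training-set presentations for few-shot Storkey.
    """

    rule: str = "irpush"
    T: float = 0.0
    PF: float = 1.0
    repetitions: int = 1
    max_epochs: int = MAX_EPOCHS_DEFAULT
    seed: int = 0
    deb_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not 0 < self.PF <= 1:
            raise ValueError("PF must be in (0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class TrainingResult:
    """Weights plus the convergence record of an iterative rule."""

    weights: WeightMatrix
    converged: bool
    epochs_used: int
    updates_performed: int
    min_margin: float


def _min_margin(W: np.ndarray, ps: PatternSet) -> float:
    return float(embedding_margins(W, ps).min())


def hebbian_train(ps: PatternSet) -> WeightMatrix:
    """One-shot outer-product rule: w_ij = sum_k xi_i^k xi_j^k, w_ii = 0."""
    X = ps.patterns.astype(np.int64)
    W = (X.T @ X).astype(float)
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, symmetric=True, integer_valued=True)


def storkey_train(ps: PatternSet, repetitions: int = 1,
                  nu: int | None = None) -> WeightMatrix:
    """Incremental Storkey rule, optionally presented few-shot.

    Sequential per-pattern updates
    ``dw_ij = [xi_i xi_j - xi_i h_ji - h_ij xi_j] / nu`` with the partial
    local field ``h_ij = sum_{l != i,j} w_il xi_l``, which subtracts the
    crosstalk of already-stored attractors. The training set is presented
    `repetitions` times in order; more than one presentation markedly
    raises capacity on correlated patterns. `nu` defaults to N-1, matching
    the scaling of the iterative rules.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    N = ps.N
    nu = (N - 1) if nu is None else nu
    W = np.zeros((N, N))
    for _ in range(repetitions):
        for xi in ps.patterns.astype(float):
            h = W @ xi
            # Hij[i, j] = sum_{l != i, j} w_il xi_l  (w_ii = 0 already)
            Hij = h[:, None] - W * xi[None, :]
            S = xi[:, None] * Hij.T        # S[i,j] = xi_i h_ji ; S.T is the mirror term
            dW = (np.outer(xi, xi) - S - S.T) / nu
            W = W + (dW + dW.T) / 2        # exact elementwise symmetry

            np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, symmetric=True)


def projection_train(ps: PatternSet) -> WeightMatrix:
    """Orthogonal projection (pseudoinverse) rule.

    W = Xi' (Xi Xi')^{-1} Xi projects onto the span of the stored patterns;
    the diagonal is zeroed afterwards. Requires linearly independent
    patterns.
    """
    X = ps.patterns.astype(float)
    G = X @ X.T
    try:
        C = np.linalg.solve(G, X)
    except np.linalg.LinAlgError as e:
        raise ValueError("patterns are linearly dependent; projection "
                         "rule requires an invertible Gram matrix") from e
    W = X.T @ C
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2   # exact symmetry despite roundoff
    return WeightMatrix(W, symmetric=True)


def _row_iterative(ps: PatternSet, T: float, max_epochs: int,
                   normalized: bool) -> TrainingResult:
    """Shared driver for the Heaviside-gated row-update rules IH / GKM.

    Weights are accumulated as integer counts of the +-1 Hebbian events and
    divided by (N-1) only at the end, so margin comparisons against T are
    exact: one update raises the failing neuron's own (unnormalized) margin
    by exactly 1. Only row i of W changes per event, so within a pattern
    only h_i moves and the live fields are maintained incrementally.
    """
    N = ps.N
    X = ps.patterns.astype(np.int64)
    Wi = np.zeros((N, N), dtype=np.int64)    # (N-1) * W, exact
    T_scaled = T * (N - 1)
    norms = np.zeros(N)                      # row norms of Wi, for gkm
    updates = 0
    epochs = 0
    converged = False
    for epoch in range(max_epochs):
        epochs = epoch + 1
        updated = False
        for xi in X:
            h = Wi @ xi                      # (N-1) * local field, exact
            for i in range(N):
                m = h[i] * xi[i]
                if normalized:
                    # margin / ||w_i|| is scale-free; zero rows fail
                    fail = norms[i] == 0.0 or m / norms[i] <= T
                else:
                    fail = m <= T_scaled
                if not fail:
                    continue
                inc = xi[i] * xi
                inc_i = inc[i]
                Wi[i] += inc
                Wi[i, i] -= inc_i            # keep the diagonal at zero
                h[i] += inc @ xi - inc_i * xi[i]
                if normalized:
                    norms[i] = np.linalg.norm(Wi[i])
                updated = True
                updates += 1
        if not updated:
            converged = True
            break
    W = Wi / (N - 1)
    return TrainingResult(WeightMatrix(W, symmetric=False), converged,
                          epochs, updates, float(_int_min_margin(Wi, X) / (N - 1)))


def _int_min_margin(Wi: np.ndarray, X: np.ndarray) -> int:
    """Minimum embedding margin of an integer-accumulated weight matrix."""
    H = X @ Wi.T
    return int((H * X).min())


def _rule2_iterative(ps: PatternSet, T: float,
                     max_epochs: int) -> TrainingResult:
    """Proportional-increment driver for Rule II (inherently real-valued).

    A single update drives the failing margin exactly to T, so the update
    condition uses a small positive tolerance on the deficit; at
    convergence all margins are >= T up to that tolerance.
    """
    N = ps.N
    X = ps.patterns.astype(float)
    W = np.zeros((N, N))
    scale = 1.0 / (N - 1)
    tol = 1e-9 * max(1.0, T)
    updates = 0
    epochs = 0
    converged = False
    for epoch in range(max_epochs):
        epochs = epoch + 1
        updated = False
        for xi in X:
            h = W @ xi
            for i in range(N):
                m = h[i] * xi[i]
                if (T - m) <= tol:
                    continue
                inc = (T - m) * scale * xi[i] * xi
                inc_i = inc[i]
                W[i] += inc
                W[i, i] -= inc_i
                h[i] += inc @ xi - inc_i * xi[i]
                updated = True
                updates += 1
        if not updated:
            converged = True
            break
    return TrainingResult(WeightMatrix(W, symmetric=False), converged,
                          epochs, updates, _min_margin(W, ps))


def ih_train(ps: PatternSet, T: float = 0.0,
             max_epochs: int = MAX_EPOCHS_DEFAULT) -> TrainingResult:
    """Rule I ("iterative Hebbian"): Heaviside-gated Hebbian row updates.

    Whenever h_i^k xi_i^k <= T, row i receives dw_ij = xi_i xi_j / (N-1),
    raising that margin by exactly 1. The matrix is asymmetric: updating
    neuron i never touches other rows.
    """
    return _row_iterative(ps, T, max_epochs, normalized=False)


def rule2_train(ps: PatternSet, T: float = 0.0,
                max_epochs: int = MAX_EPOCHS_DEFAULT) -> TrainingResult:
    """Rule II: increments proportional to the margin deficit (T - m).

    A single update drives the failing margin exactly to T, so updates are
    applied while the deficit exceeds a small tolerance; at convergence all
    margins are >= T up to that tolerance.
    """
    return _rule2_iterative(ps, T, max_epochs)


def gkm_train(ps: PatternSet, T: float = 1.0,
              max_epochs: int = MAX_EPOCHS_DEFAULT) -> TrainingResult:
    """Rule I with Gardner row-norm alignment normalization.

    The update test uses the normalized margin h_i^k xi_i^k / ||w_i||_2
    (rows of zero norm count as failing), so T plays the role of the
    perceptron stability kappa; increments stay plain Hebbian / (N-1).
    """
    return _row_iterative(ps, T, max_epochs, normalized=True)


def deb_train(ps: PatternSet, T: float = 0.0, learning_rate: float = 0.1,
              beta: float = 0.1, max_iters: int = 5000) -> TrainingResult:
    """Gradient descent on the exponential-barrier loss.

    Minimizes L(W) = sum_{k,i} exp(-beta * h_i^k xi_i^k) over symmetric
    zero-diagonal W (the gradient is symmetrized and its diagonal projected
    out each step). The barrier pushes hardest on the worst-aligned neuron,
    so minimizing L drives all margins positive; iteration stops once every
    margin exceeds T.

    Raises
    ------
    RuntimeError
        If the loss increases beyond tolerance (divergent step size).
    """
    if learning_rate <= 0 or beta <= 0:
        raise ValueError("learning_rate and beta must be positive")
    N = ps.N
    X = ps.patterns.astype(float)
    W = np.zeros((N, N))
    prev_loss = np.inf
    iters = 0
    converged = False
    for it in range(max_iters):
        iters = it + 1
        M = (X @ W.T) * X                       # margins, P x N
        if (M > T).all():
            converged = True
            break
        with np.errstate(over="ignore"):        # inf is caught as divergence
            E = np.exp(-beta * M)               # P x N barrier terms
        loss = float(E.sum())
        if loss > prev_loss * (1 + 1e-9):
            raise RuntimeError("exponential-barrier descent diverged; "
                               "reduce learning_rate")
        prev_loss = loss
        # dL/dw_ij = -beta * sum_k E[k,i] xi_i^k xi_j^k ; symmetrize
        G = -beta * (E * X).T @ X
        G = (G + G.T) / 2
        np.fill_diagonal(G, 0.0)
        W -= learning_rate * G
    return TrainingResult(WeightMatrix(W, symmetric=True), converged,
                          iters, iters, _min_margin(W, ps))


def irpush_train(ps: PatternSet, T: float = 0.0, PF: float = 1.0,
                 rng: np.random.Generator | None = None,
                 max_epochs: int = MAX_EPOCHS_DEFAULT,
                 _check_symmetry: bool = False) -> TrainingResult:
    """Iterative Random Partial Update Symmetric Hebbian rule.

    Like Rule I, but every update is mirrored (w_ij and w_ji change
    together, keeping W symmetric for bidirectional couplings) and only a
    random fraction PF of the failing neuron's connections is touched per
    event. Each neuron i keeps a persistent update set U_i of candidate
    partner indices; a failing neuron draws c = max(1, round(PF*(N-1)))
    partners uniformly without replacement from U_i, applies the Hebbian
    increment xi_i xi_j / (N-1) to both w_ij and w_ji, removes the drawn
    indices, and U_i is refilled to {j != i} once fewer than c remain.
    The randomized partial updates spread the stored information across
    synapses, which is what makes the converged matrices robust to coarse
    quantization. With PF = 1 the draw always covers every partner and the
    result is seed-independent.

    Non-convergence within `max_epochs` passes is reported via
    ``converged=False``, not raised: above capacity the embedding
    conditions may simply be unsatisfiable.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if not 0 < PF <= 1:
        raise ValueError("PF must be in (0, 1]")
    rng = np.random.default_rng(0) if rng is None else rng
    N = ps.N
    X = ps.patterns.astype(np.int64)
    Wi = np.zeros((N, N), dtype=np.int64)    # (N-1) * W: exact arithmetic
    c = max(1, round(PF * (N - 1)))
    T_scaled = T * (N - 1)
    others = [np.delete(np.arange(N), i) for i in range(N)]
    update_sets = [set(others[i].tolist()) for i in range(N)]
    updates = 0
    epochs = 0
    converged = False
    for epoch in range(max_epochs):
        epochs = epoch + 1
        updated = False
        for xi in X:
            h = Wi @ xi                      # (N-1) * local field
            for i in range(N):
                if h[i] * xi[i] > T_scaled:
                    continue
                pool = np.fromiter(update_sets[i], dtype=np.int64,
                                   count=len(update_sets[i]))
                pool.sort()                  # set order must not leak in
                drawn = pool if len(pool) == c else rng.choice(
                    pool, size=c, replace=False)
                inc = xi[i] * xi[drawn]
                Wi[i, drawn] += inc
                Wi[drawn, i] += inc
                h[i] += inc @ xi[drawn]
                h[drawn] += inc * xi[i]
                update_sets[i].difference_update(drawn.tolist())
                if len(update_sets[i]) < c:
                    update_sets[i] = set(others[i].tolist())
                updated = True
                updates += 1
                if _check_symmetry and not (Wi == Wi.T).all():
                    raise AssertionError("symmetry broken mid-training")
        if not updated:
            converged = True
            break
    W = Wi / (N - 1)
    return TrainingResult(WeightMatrix(W, symmetric=True), converged,
                          epochs, updates,
                          float(_int_min_margin(Wi, X) / (N - 1)))


def train(ps: PatternSet, cfg: TrainingConfig) -> TrainingResult:
    """Dispatch a TrainingConfig to its rule.

    One-shot rules are wrapped in a TrainingResult with ``converged`` set
    by whether their margins clear cfg.T.
    """
    rule = cfg.rule
    if rule == "hebbian":
        wm = hebbian_train(ps)
    elif rule == "storkey":
        wm = storkey_train(ps, cfg.repetitions)
    elif rule == "projection":
        wm = projection_train(ps)
    elif rule == "ih":
        return ih_train(ps, cfg.T, cfg.max_epochs)
    elif rule == "rule2":
        return rule2_train(ps, cfg.T, cfg.max_epochs)
    elif rule == "gkm":
        return gkm_train(ps, cfg.T, cfg.max_epochs)
    elif rule == "deb":
        return deb_train(ps, cfg.T, **cfg.deb_params)
    elif rule == "irpush":
        return irpush_train(ps, cfg.T, cfg.PF,
                            np.random.default_rng(cfg.seed), cfg.max_epochs)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    mm = _min_margin(wm.W, ps)
    return TrainingResult(wm, bool(mm > cfg.T), 1, ps.P, mm)


RULES = ("hebbian", "storkey", "projection", "ih", "rule2", "gkm", "deb",
         "irpush")
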