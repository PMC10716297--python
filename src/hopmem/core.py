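"""Discrete synchronous Hopfield dynamics.

A network of N bipolar neurons fully connected by a zero-diagonal weight
matrix W updates all states simultaneously, s_i <- sign(sum_j w_ij s_j).
With symmetric W the quadratic energy E = -1/2 s'Ws is a Lyapunov-like
function for the doubled map, so every trajectory ends in a fixed point or a
period-2 cycle; both terminations are detected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import PatternSet, _as_bipolar, hamming

__all__ = [
    "WeightMatrix",
    "InferenceResult",
    "local_field",
    "sync_step",
    "energy",
    "run_inference",
    "classify_outcome",
    "embedding_margins",
    "nearest_stored",
    "read_weights",
    "write_weights",
]

MAX_STEPS_DEFAULT = 100


@dataclass
class WeightMatrix:
    """N x N synaptic matrix with zero diagonal.

    `symmetric` asserts W == W.T exactly; `integer_valued` marks quantized
    matrices (entries are integers stored as floats or ints).
    """

    W: np.ndarray
    symmetric: bool = True
    integer_valued: bool = False

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if np.diagonal(W).any():
            raise ValueError("diagonal of W must be zero")
        if self.symmetric and not (W == W.T).all():
            raise ValueError("W flagged symmetric but W != W.T")
        if self.integer_valued and not (W == np.round(W)).all():
            raise ValueError("W flagged integer-valued but has fractional entries")
        self.W = W

    @property
    def N(self) -> int:
        return self.W.shape[0]


@dataclass
class InferenceResult:
    """Outcome of iterating the synchronous map from one initial state."""

    final_state: np.ndarray
    steps: int
    terminal: str                      # fixed_point | two_cycle | max_steps
    cycle_pair: tuple[np.ndarray, np.ndarray] | None = None
    outcome_class: str | None = field(default=None)


def _weights(W) -> np.ndarray:
    return W.W if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)


def local_field(W, s) -> np.ndarray:
    """Hidden potentials h_i = sum_j w_ij s_j (the diagonal contributes 0)."""
    Wm = _weights(W)
    s = np.asarray(s, dtype=float).ravel()
    if s.shape[0] != Wm.shape[0]:
        raise ValueError("state length does not match network size")
    return Wm @ s


def sync_step(W, s, tie_rule: str = "retain") -> np.ndarray:
    """One synchronous update of all neurons, s'_i = sign(h_i).

    sign(0) is resolved by `tie_rule`: "retain" keeps the previous state
    (the default, bias-free convention), "plus"/"minus" force a sign.
    """
    s = _as_bipolar(s, "state").ravel()
    h = local_field(W, s)
    if tie_rule == "retain":
        zero_fill = s
    elif tie_rule == "plus":
        zero_fill = 1
    elif tie_rule == "minus":
        zero_fill = -1
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return np.where(h > 0, 1, np.where(h < 0, -1, zero_fill)).astype(np.int8)


def energy(W, s) -> float:
    """Hamiltonian E = -1/2 sum_ij w_ij s_i s_j = -1/2 sum_i h_i s_i."""
    s = np.asarray(s, dtype=float).ravel()
    return float(-0.5 * s @ local_field(W, s))


def run_inference(W, s0, max_steps: int = MAX_STEPS_DEFAULT,
                  tie_rule: str = "retain") -> InferenceResult:
    """Iterate the synchronous map until a fixed point or 2-cycle.

    Stops at the first t with s_{t+1} == s_t (fixed point) or
    s_{t+2} == s_t != s_{t+1} (two-cycle); `steps` counts the synchronous
    updates actually applied.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    s = _as_bipolar(s0, "initial state").ravel().copy()
    prev: np.ndarray | None = None
    for t in range(max_steps):
        s_new = sync_step(W, s, tie_rule)
        if (s_new == s).all():
            return InferenceResult(s, t, "fixed_point")
        if prev is not None and (s_new == prev).all():
            return InferenceResult(prev, t + 1, "two_cycle", cycle_pair=(prev, s))
        prev, s = s, s_new
    return InferenceResult(s, max_steps, "max_steps")


def nearest_stored(test_input, stored: PatternSet) -> tuple[int, bool]:
    """Index and inversion flag of the stored pattern (or inverse) closest
    to `test_input` by Hamming distance.

    Ties are broken by lowest pattern index, base before inverse.
    """
    x = _as_bipolar(test_input, "test input").ravel()
    best: tuple[int, int, int] | None = None   # (hd, index, inverted)
    for k, xi in enumerate(stored.patterns):
        for inv in (0, 1):
            hd = hamming(x, -xi if inv else xi)
            key = (hd, k, inv)
            if best is None or key < best:
                best = key
    return best[1], bool(best[2])


def classify_outcome(res: InferenceResult, stored: PatternSet,
                     test_input) -> str:
    """Assign the retrieval outcome class of an inference trajectory.

    retrieved_correct: fixed point equal (HD=0) to the stored pattern or
    pattern-inverse nearest to the test input; wrong_stored: fixed point
    equal to a different stored pattern/inverse; spurious: a fixed point
    matching none (trajectories exhausting the step budget are counted
    here too, as unsuccessful); limit_cycle: period-2 termination.
    """
    if res.terminal == "two_cycle":
        return "limit_cycle"
    k_star, inv_star = nearest_stored(test_input, stored)
    if res.terminal == "fixed_point":
        s = res.final_state
        for k, xi in enumerate(stored.patterns):
            for inv in (False, True):
                target = -xi if inv else xi
                if (s == target).all():
                    if k == k_star and inv == inv_star:
                        return "retrieved_correct"
                    return "wrong_stored"
    return "spurious"


def embedding_margins(W, ps: PatternSet) -> np.ndarray:
    """P x N matrix of pattern-embedding margins h_i^k * xi_i^k.

    All entries strictly above a threshold T means every stored pattern
    (and, by sign symmetry, every inverse) is a fixed point with margin T.
    """
    Wm = _weights(W)
    if ps.N != Wm.shape[0]:
        raise ValueError("pattern length does not match network size")
    X = ps.patterns.astype(float)
    H = X @ Wm.T           # H[k, i] = sum_j w_ij xi_j^k
    return H * X


def write_weights(wm: WeightMatrix, path) -> None:
    """Write a weight matrix as a full N x N TSV of numeric literals."""
    fmt = "%d" if wm.integer_valued else "%.12g"
    arr = wm.W.astype(int) if wm.integer_valued else wm.W
    lines = ["\t".join(fmt % v for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_weights(path, require_symmetric: bool = False) -> WeightMatrix:
    """Read a TSV weight matrix; validates squareness and zero diagonal."""
    rows = [l.split("\t") for l in
            Path(path).read_text(encoding="utf-8").strip().splitlines()]
    W = np.array([[float(v) for v in r] for r in rows])
    symmetric = bool((W == W.T).all()) if W.ndim == 2 and W.shape[0] == W.shape[1] else False
    if require_symmetric and not symmetric:
        raise ValueError("weight matrix is not symmetric")
    return WeightMatrix(W, symmetric=symmetric,
                        integer_valued=bool((W == np.round(W)).all()))
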