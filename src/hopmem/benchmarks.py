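"""Capacity, noise-robustness and rule-comparison benchmarks.

Reproducible runners for the three standard experiments on the bundled
A-J character set: the incremental capacity sweep, retrieval accuracy on a
noise-corrupted test set (by default 10 draws x 20 bases x 40 noise levels
= 8,000 inputs), and the partial-factor battery for the randomized IRPUSH
rule. Retrieval is scored with the zero-Hamming-distance criterion against
the stored pattern (or its inverse) truly nearest to each test input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import MAX_STEPS_DEFAULT, WeightMatrix, sync_step
from .patterns import PatternSet, corrupt
from .quantization import QuantizationSpec, quantize
from .rules import TrainingConfig, TrainingResult, irpush_train, train

__all__ = [
    "NoiseTestSet",
    "BenchmarkReport",
    "capacity_sweep",
    "count_stored",
    "make_noise_testset",
    "noise_accuracy",
    "partial_battery",
    "compare_rules",
]


@dataclass(frozen=True)
class NoiseTestSet:
    """Corrupted cues for the retrieval benchmark.

    Row i of `inputs` was generated by flipping exactly `noise_levels[i]`
    random pixels of stored pattern `base_indices[i]` (its inverse when
    `inverted[i]`).
    """

    inputs: np.ndarray          # (M, N) bipolar
    base_indices: np.ndarray    # (M,) int
    inverted: np.ndarray        # (M,) bool
    noise_levels: np.ndarray    # (M,) int
    base_labels: tuple[str, ...]

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class BenchmarkReport:
    """Results of one benchmark run; unused fields stay None."""

    capacity: int | None = None
    accuracy_overall: float | None = None
    accuracy_by_level: dict[int, float] | None = None
    tolerance_at_95: int | None = None
    battery_stats: dict[str, float] | None = None
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _is_fixed(W, s) -> bool:
    return bool((sync_step(W, s) == np.asarray(s, dtype=np.int8).ravel()).all())


def count_stored(W, ps: PatternSet) -> int:
    """Number of patterns whose pattern AND inverse are network fixed points."""
    return sum(1 for xi in ps.patterns
               if _is_fixed(W, xi) and _is_fixed(W, -xi))


def _trained_weights(cfg: TrainingConfig, ps: PatternSet) -> WeightMatrix:
    res = train(ps, cfg)
    return res.weights if isinstance(res, TrainingResult) else res


def capacity_sweep(rule_cfg: TrainingConfig, charset: PatternSet,
                   nbit: int | None = None) -> int:
    """Largest P such that the net trained on the first P characters holds
    all P patterns and their inverses as fixed points.

    Trains one network per prefix P = 1..P_total in set order (A..J for the
    bundled fixture), optionally quantizing the converged weights before the
    fixed-point test. Non-monotone pass/fail across P is resolved by
    reporting the largest passing P.
    """
    best = 0
    for P in range(1, charset.P + 1):
        sub = charset.subset(P)
        wm = _trained_weights(rule_cfg, sub)
        if nbit is not None:
            wm = quantize(wm, QuantizationSpec(nbit))
        if count_stored(wm, sub) == P:
            best = P
    return best


def make_noise_testset(charset: PatternSet, levels=range(1, 41),
                       per_pattern: int = 10,
                       rng: np.random.Generator | None = None) -> NoiseTestSet:
    """Noise test set: `per_pattern` corrupted copies of every stored
    pattern and every inverse at each noise level.

    Defaults reproduce the standard benchmark: 10 x (10 patterns + 10
    inverses) x 40 levels = 8,000 inputs, 200 per level.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    levels = list(levels)
    if levels and max(levels) >= charset.N:
        raise ValueError("noise level must be below the pattern length")
    inputs, base_idx, inv, lev = [], [], [], []
    for k, xi in enumerate(charset.patterns):
        for inverted in (False, True):
            base = -xi if inverted else xi
            for level in levels:
                for _ in range(per_pattern):
                    inputs.append(corrupt(base, level, rng))
                    base_idx.append(k)
                    inv.append(inverted)
                    lev.append(level)
    return NoiseTestSet(np.array(inputs, dtype=np.int8),
                        np.array(base_idx), np.array(inv, dtype=bool),
                        np.array(lev), charset.labels)


def _batch_retrieve(W, S0: np.ndarray, max_steps: int = MAX_STEPS_DEFAULT):
    """Synchronous dynamics for a batch of initial states.

    Returns (final_states, fixed_mask): `fixed_mask[i]` is True when
    trajectory i reached a fixed point within `max_steps`; two-cycles and
    exhausted budgets count as not fixed.
    """
    Wm = W.W if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    S = S0.astype(np.int8).copy()
    M = S.shape[0]
    fixed = np.zeros(M, dtype=bool)
    done = np.zeros(M, dtype=bool)
    prev = None
    for _ in range(max_steps):
        act = ~done
        if not act.any():
            break
        H = S[act].astype(float) @ Wm.T
        S_new = np.where(H > 0, 1, np.where(H < 0, -1, S[act])).astype(np.int8)
        same = (S_new == S[act]).all(axis=1)
        if prev is not None:
            cyc = (S_new == prev[act]).all(axis=1) & ~same
        else:
            cyc = np.zeros(same.shape, dtype=bool)
        idx = np.flatnonzero(act)
        fixed[idx[same]] = True
        done[idx[same | cyc]] = True
        if prev is None:
            prev = S.copy()
        else:
            prev[act] = S[act]
        S[act] = S_new
    return S, fixed


def _nearest_candidates(stored: PatternSet):
    """Candidate matrix interleaving each pattern with its inverse, so that
    argmin over candidate HD implements the (pattern index, base-first)
    tie-break."""
    P, N = stored.patterns.shape
    cand = np.empty((2 * P, N), dtype=np.int8)
    cand[0::2] = stored.patterns
    cand[1::2] = -stored.patterns
    return cand


def noise_accuracy(W, ts: NoiseTestSet, stored: PatternSet,
                   max_steps: int = MAX_STEPS_DEFAULT) -> BenchmarkReport:
    """Retrieval accuracy of a trained network on a noise test set.

    Each input is relaxed under synchronous dynamics; retrieval succeeds
    when the trajectory reaches a fixed point equal (HD = 0) to the stored
    pattern or pattern-inverse nearest to the input. Reports the overall
    success percentage, the per-noise-level curve, and the largest level L
    with accuracy above 95% at every level up to L.
    """
    cand = _nearest_candidates(stored)
    X = ts.inputs.astype(np.int64)
    hd = (stored.N - X @ cand.T.astype(np.int64)) // 2
    nearest = hd.argmin(axis=1)
    finals, fixed = _batch_retrieve(W, ts.inputs, max_steps)
    success = fixed & (finals == cand[nearest]).all(axis=1)
    acc_by_level: dict[int, float] = {}
    for level in np.unique(ts.noise_levels):
        m = ts.noise_levels == level
        acc_by_level[int(level)] = 100.0 * success[m].mean()
    tol95 = 0
    for level in sorted(acc_by_level):
        if acc_by_level[level] > 95.0:
            tol95 = level
        else:
            break
    return BenchmarkReport(
        accuracy_overall=100.0 * success.mean(),
        accuracy_by_level=acc_by_level,
        tolerance_at_95=tol95,
    )


def partial_battery(charset: PatternSet, T: float, PF: float,
                    repeats: int = 100, base_seed: int = 0,
                    nbit: int | None = None,
                    testset: NoiseTestSet | None = None,
                    max_epochs: int | None = None) -> BenchmarkReport:
    """Battery of IRPUSH trainings with distinct seeds on a fixed test set.

    Each repeat trains IRPUSH(T, PF) with its own seed, optionally
    quantizes, and measures noise accuracy on the shared test set. Reports
    max/mean/std of the overall accuracy across repeats (std is 0 at PF=1,
    where the rule is deterministic) and keeps the best run's per-level
    curve and capacity.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if testset is None:
        testset = make_noise_testset(charset, rng=np.random.default_rng(base_seed))
    kwargs = {} if max_epochs is None else {"max_epochs": max_epochs}
    accs = []
    best = None
    for r in range(repeats):
        rng = np.random.default_rng(base_seed + r)
        res = irpush_train(charset, T=T, PF=PF, rng=rng, **kwargs)
        wm = res.weights
        if nbit is not None:
            wm = quantize(wm, QuantizationSpec(nbit))
        rep = noise_accuracy(wm, testset, charset)
        rep.capacity = count_stored(wm, charset)
        accs.append(rep.accuracy_overall)
        if best is None or rep.accuracy_overall > best.accuracy_overall:
            best = rep
    accs = np.array(accs)
    best.battery_stats = {"max": float(accs.max()), "mean": float(accs.mean()),
                          "std": float(accs.std())}
    best.config = {"T": T, "PF": PF, "repeats": repeats,
                   "base_seed": base_seed, "nbit": nbit}
    return best


def compare_rules(charset: PatternSet, configs: list[TrainingConfig],
                  nbits=(None, 5, 4, 3),
                  testset: NoiseTestSet | None = None) -> list[dict]:
    """Capacity and accuracy of several rules at several precisions.

    One row per (rule config, precision): the incremental-sweep capacity
    and, only when the full-set network stores all patterns, the overall
    accuracy on a shared test set. None in `nbits` means full precision.
    """
    if testset is None:
        testset = make_noise_testset(charset, rng=np.random.default_rng(0))
    rows = []
    for cfg in configs:
        wm_fp = _trained_weights(cfg, charset)
        for nbit in nbits:
            wm = wm_fp if nbit is None else quantize(wm_fp, QuantizationSpec(nbit))
            stored = count_stored(wm, charset)
            row = {"rule": cfg.rule, "T": cfg.T, "PF": cfg.PF,
                   "repetitions": cfg.repetitions,
                   "nbit": nbit, "capacity": capacity_sweep(cfg, charset, nbit),
                   "stored_full_set": stored, "accuracy_overall": None}
            if stored == charset.P:
                row["accuracy_overall"] = noise_accuracy(
                    wm, testset, charset).accuracy_overall
            rows.append(row)
    return rows
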