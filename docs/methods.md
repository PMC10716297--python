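# Methods

## Model

The network is a discrete, synchronous, bias-free Hopfield model: N bipolar
neurons, a real N×N weight matrix W with zero diagonal, and the parallel
update `s'_i = sign(Σ_j w_ij s_j)`. Bias terms are deliberately absent —
the oscillator hardware this model abstracts has no constant-phase
contribution — and `sign(0)` retains the previous state, which injects no
fixed polarity and preserves the ±ξ attractor symmetry. Because `−W(−s) =
Ws`, a pattern is a fixed point exactly when its inverse is; all capacity
and retrieval accounting therefore treats pattern inverses as valid
attractors.

For symmetric W, parallel dynamics admits the bilinear Lyapunov function
`E₂(t) = −s_tᵀ W s_{t+1}`, which is non-increasing (also under the
tie-retain rule), so every trajectory ends in a fixed point or a 2-cycle.
Note that the quadratic energy `E(s) = −½ sᵀWs` itself is *not* monotone
along parallel trajectories, not even sampled every second step — we found
counterexamples on random symmetric matrices — which is why the tests
assert monotonicity of E₂, and why inference simply detects fixed points
and 2-cycles directly (default ceiling 100 synchronous steps; N = 96 nets
settle in under 20 in practice).

A pattern set is *embedded* at threshold T when every margin
`m_i^k = h_i^k ξ_i^k` exceeds T. Margins are linear in W, so embedding at
any T ≥ 0 implies all patterns and inverses are fixed points; raising T
widens basins of attraction at the cost of larger weights.

## Learning rules

All rules zero the self-couplings (`w_ii = 0` throughout): self-feedback
has no counterpart in coupling-based hardware, and the iterative updates
are defined over `j ≠ i`.

* **Hebbian** — one-shot outer-product sum; integer weights.
* **Storkey** — sequential per-pattern updates
  `Δw_ij = [ξ_iξ_j − ξ_i h_ji − h_ij ξ_j]/ν` with the partial field
  `h_ij = Σ_{l≠i,j} w_il ξ_l`; ν defaults to N−1 to match the scaling of
  the iterative rules (switchable to N; retrieval behaviour is
  scale-invariant). The `repetitions` parameter re-presents the training
  set: on the bundled character set one presentation stores 4 of 10
  characters in the incremental sweep, three presentations embed all ten.
* **Projection (pseudoinverse)** — `W = Ξᵀ(ΞΞᵀ)⁻¹Ξ` with the diagonal
  zeroed afterwards; requires linearly independent patterns.
* **Rule I / "iterative Hebbian" (IH)** — sweep patterns in set order and
  neurons in index order; whenever `m_i^k ≤ T`, add the Hebbian row
  increment `ξ_i^kξ_j^k/(N−1)` to row i only (asymmetric). One update
  raises the failing margin by exactly 1.
* **Rule II** — same sweep with proportional increments
  `(T − m)·ξ_iξ_j/(N−1)`, which drive the failing margin exactly to T; the
  update gate uses a small tolerance on the deficit (1e-9·max(1,T)), since
  a literal `m ≤ T` gate would re-fire forever on margins that sit exactly
  at T. Convergence for this rule means margins ≥ T up to that tolerance.
* **GKM** — Rule I with the gate applied to the row-normalized margin
  `m_i^k / ‖w_i‖₂` (zero-norm rows count as failing), so T acts as a
  perceptron stability κ. Default κ = 1.5: at that operating point the
  converged network survives 5- and 4-bit quantization of the character
  set but not 3-bit, which is the regime this comparator is meant to
  represent.
* **DEB** — full-gradient descent on the exponential barrier
  `L(W) = Σ_{k,i} exp(−β m_i^k)` over symmetric zero-diagonal matrices
  (gradient symmetrized, diagonal projected out), stopping once all
  margins exceed T. Defaults `learning_rate = 0.1`, `β = 0.1`,
  `max_iters = 5000` descend stably on the character set; the benchmark
  configuration uses a margin target T = 50 so the solution is robust to
  quantization rather than barely feasible.
* **IRPUSH** — the package's central rule; Rule-I sweeps, but every update
  is mirrored (`Δw_ij = Δw_ji`, W symmetric after every single update) and
  touches only `c = max(1, round(PF·(N−1)))` randomly drawn partners of
  the failing neuron. Each neuron keeps a persistent update set of
  candidate partners; drawn indices are removed and the set refills to
  `{j ≠ i}` once fewer than c remain, so partner coverage is balanced over
  time. With PF = 1 the draw always covers all partners and the result is
  seed-independent; with PF < 1 each seed yields a different valid
  solution, which the battery runner exploits.

Thresholds for IH/IRPUSH/Rule II are on the raw margin scale: since
increments carry 1/(N−1), the classic unit threshold corresponds to
T ≈ N − 1 (95 for the bundled set).

### Numerical choices

The Heaviside-gated rules (IH, GKM, IRPUSH) accumulate weights as exact
integer event counts, dividing by N−1 only when the final matrix is
emitted. Margin-vs-threshold comparisons during training are therefore
exact integer comparisons — no floating-point drift can mis-fire or
mis-skip an update — and at convergence the true minimum margin exceeds T
by at least 1/(N−1), comfortably clear of roundoff when margins are
recomputed in floating point. Fields are maintained incrementally within a
pattern presentation (an update changes only h_i for row rules, h_i and
the drawn h_j for IRPUSH) and recomputed from W at each pattern switch.

`max_epochs` defaults to 2000 full passes; non-convergence is reported via
`converged=False` rather than raised, because above capacity the embedding
conditions are simply unsatisfiable. Convergence is declared when a full
pass performs no update, which by construction is equivalent to all
margins strictly exceeding T (normalized margins for GKM).

## Quantization

Post-training only: `q_ij = round((2^(nbit−1)−1)·w_ij/max|W|)`, rounding
half away from zero (sign-symmetric, so quantization commutes with the ±ξ
symmetry). One bit holds the sign; nbit = 3 leaves the seven levels
{−3,…,+3}. The map is scale-invariant, monotone, sign-preserving, and
idempotent at fixed precision. There is no quantization-aware training and
no per-row scaling.

## Benchmarks and the synthetic test set

* **Capacity sweep** — train on the first P characters (A..J order) for
  P = 1..10, optionally quantize, and test that all P patterns and
  inverses are fixed points; the reported capacity is the largest passing
  P (pass/fail need not be monotone in P).
* **Noise test set** — for each stored pattern and each inverse, at every
  noise level 1..40, draw 10 corrupted copies with exactly that many
  uniformly chosen pixels flipped: 8,000 cues, 200 per level, fully
  determined by one RNG seed. Retrieval succeeds when synchronous dynamics
  reaches a fixed point identical (Hamming distance 0) to the stored
  pattern or inverse *nearest to the cue*; nearest-target ties break by
  lowest pattern index, base before inverse. Reported quantities: overall
  accuracy (%), the per-level curve, and the largest level L with
  accuracy > 95% at every level up to L.
* **Partial battery** — repeated seeded IRPUSH trainings at fixed (T, PF)
  evaluated on one shared test set; reports max/mean/std of overall
  accuracy. The acceptance script uses an 8-seed battery and the test
  suite a 3-seed battery; at PF = 1 the variance is exactly zero.
* **Rule comparison** — one row per (rule, precision): sweep capacity plus
  overall accuracy, the latter only when the full-set network stores all
  ten patterns (low-capacity rules are excluded from accuracy, as their
  failures would measure storage, not recall).

The generator emulates uniform pixel noise on a fixed glyph set. It does
not model correlated or structured noise, partial occlusion, analog phase
noise in real oscillator hardware, or deviations of physical couplings
from their programmed values — passing benchmarks bound retrieval quality
under idealized i.i.d. corruption only.

### The bundled character set

The 12×8 A–J glyphs (N = 96) ship both as a code constant and as a pattern
file (`fixtures/charset_aj.txt`, format: `>LABEL rows cols` headers over
0/1 rasters). The set is canonically defined by its 45 pairwise Hamming
distances (asserted exactly in the tests); the close pairs B–D (10), E–F
(13) and C–G (16) are what makes outer-product rules fail early on it
(one-shot Hebbian stores 3 characters, one-shot Storkey 4).

## Known limitations

* At 3-bit precision the benefit of partial updates (PF < 1) is modest in
  this implementation: for T = 150, PF = 33% the best battery run reaches
  ~76% overall accuracy with a 95%-tolerance of ~16 pixels, versus ~70%
  and ~7–11 for PF = 100%. The cause is structural: run to convergence,
  the embedding problem at T = 150 forces a heavy-tailed weight
  distribution (≈0.5% of weights at |w| ≈ 33 against a median ≈ 3.5)
  concentrated on the pixels discriminating the near-duplicate character
  pairs, and the global-max normalization of the quantizer then flattens
  most weights to zero. The signed accumulation on those connections is
  invariant to the update schedule — fresh random draws, no-replacement
  cycling, and candidate-scaled increments all produce the same tails — so
  partiality redistributes *when* connections are updated but not their
  converged magnitudes. Earlier stopping (all patterns stored but margins
  still below T) or clipping the top percentile of weights before
  quantization both remove the effect, at the price of an additional
  parameter the algorithm as specified does not have.
* Capacity and accuracy figures are specific to the bundled correlated
  character set; uncorrelated random patterns store far more easily.
* Only synchronous dynamics is implemented (no asynchronous or
  continuous-time variants, no bias terms), and the mapping from trained
  weights to physical coupling conductances is out of scope.
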