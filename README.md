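# hopmem

Hopfield associative memory with hardware-constrained learning rules.

Single-layer oscillatory neural networks (ONNs) built from coupled
nano-oscillators behave like discrete Hopfield networks: bipolar neuron
states `s_i ∈ {−1,+1}`, synchronous updates `s_i ← sign(Σ_j w_ij s_j)`, and
stored patterns as attractor fixed points. Physical couplings, however,
force two constraints that most classical Hopfield training rules ignore:
the weight matrix must be **symmetric** (couplings are bidirectional) and
**low precision** (only a few distinguishable coupling strengths).

`hopmem` is for researchers studying associative-memory training under
those constraints. Its core is **IRPUSH** (Iterative Random Partial Update
Symmetric Hebbian): a perceptron-style iterative rule that drives every
pattern-embedding condition

```
h_i^k ξ_i^k = Σ_j w_ij ξ_j^k ξ_i^k > T      for all neurons i, patterns k
```

above a margin threshold `T` using fixed Hebbian increments
`Δw_ij = Δw_ji = ξ_i^k ξ_j^k /(N−1)` applied, per failing neuron, to a
random fraction `PF` of its connections (drawn without replacement from a
persistent per-neuron update set). Symmetry holds after every single
update; larger `T` buys larger basins of attraction.

The package also provides the standard comparators — one-shot Hebbian,
Storkey (with few-shot repetition), the pseudoinverse/projection rule,
Rule I ("iterative Hebbian") and Rule II, a row-norm-regularized variant
(GKM), and an exponential-barrier gradient solver (DEB) — plus n-bit weight
quantization (`round((2^(nbit−1)−1)·w/max|W|)`), synchronous inference with
fixed-point/2-cycle detection, and reproducible capacity and
noise-robustness benchmarks on a bundled 12×8-pixel A–J character set
(N = 96, ten correlated glyphs; close pairs such as B–D at Hamming
distance 10 make the set deliberately hard).

## Worked example

Train a symmetric network on the ten characters with margin `T = 150`,
quantize it to 3-bit couplings, and recall a character from a badly
corrupted cue:

```
$ hopmem train --rule irpush --t 150 --pf 1.0 --out-weights w150.tsv
{
  "PF": 1.0,
  "T": 150.0,
  "converged": true,
  "epochs_used": 700,
  "min_margin": 150.0421052631579,
  "rule": "irpush",
  "stored": 10,
  "updates_performed": 86836
}

$ hopmem quantize --nbit 3 w150.tsv w150_q3.tsv
$ hopmem bench-capacity --rule irpush --t 150 --nbit 3
{
  "PF": 1.0,
  "T": 150.0,
  "capacity": 10,
  "nbit": 3,
  "rule": "irpush"
}

$ hopmem infer --weights w150_q3.tsv --cue E --flips 20 --seed 7
{"terminal": "fixed_point", "steps": 1, "outcome": "retrieved_correct"}
```

Training converged after 700 passes with every embedding margin above 150;
all ten characters (and their inverses, which are automatically attractors
too) remain fixed points even with weights restricted to the seven integer
levels {−3,…,+3}; and a cue with 20 of 96 pixels flipped relaxes back onto
the stored "E" in one synchronous step.

The same machinery is available as a library (`hopmem.irpush_train`,
`hopmem.quantize`, `hopmem.noise_accuracy`, …), and
`hopmem bench-noise / bench-partial / bench-compare` run the full
noise-robustness benchmark: an 8,000-cue test set (10 random corruptions ×
20 stored patterns and inverses × noise levels 1–40 pixels), scored by
exact retrieval (Hamming distance 0) of the stored pattern nearest to each
cue.

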