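"""n-bit weight quantization for precision-limited synapses.

Hardware couplings can realize only a small number of distinct strengths.
Weights are quantized post-training: normalize by the largest magnitude,
scale by the largest representable integer, and round. One bit holds the
sign, so an n-bit weight takes integer values in
[-(2^(n-1)-1), 2^(n-1)-1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import WeightMatrix

__all__ = ["QuantizationSpec", "quantize"]


@dataclass(frozen=True)
class QuantizationSpec:
    """Target precision: `nbit` total bits, MSB dedicated to the sign."""

    nbit: int

    def __post_init__(self):
        if self.nbit < 2:
            raise ValueError("nbit must be >= 2 (sign bit plus magnitude)")

    @property
    def max_level(self) -> int:
        return 2 ** (self.nbit - 1) - 1


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # symmetric in sign, preserving the +-pattern attractor symmetry
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize(wm: WeightMatrix, spec: QuantizationSpec) -> WeightMatrix:
    """Quantize a weight matrix to signed n-bit integers.

    q_ij = round((2^(nbit-1) - 1) * w_ij / max|W|), rounding half away
    from zero. Zero diagonal and symmetry are preserved; scaling the input
    by any positive constant leaves the result unchanged.
    """
    scale = float(np.abs(wm.W).max())
    if scale == 0.0:
        raise ValueError("cannot quantize an all-zero weight matrix")
    Q = _round_half_away(spec.max_level * wm.W / scale)
    return WeightMatrix(Q, symmetric=wm.symmetric, integer_valued=True)
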