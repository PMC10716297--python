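"""Bipolar pattern sets, Hamming distance, noise corruption and pattern I/O.

Patterns are the memory content of the network: vectors over {-1, +1}. The
module also bundles the canonical 12x8 A-J character set used by the capacity
and noise-robustness benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._charset import CHARSET_COLS, CHARSET_GLYPHS, CHARSET_ROWS

__all__ = [
    "PatternSet",
    "builtin_charset",
    "hamming",
    "corrupt",
    "random_patterns",
    "read_patterns",
    "write_patterns",
]


def _as_bipolar(arr, name: str = "pattern") -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (-1, 1)).all():
        raise ValueError(f"{name} entries must be -1 or +1")
    return a.astype(np.int8)


@dataclass(frozen=True)
class PatternSet:
    """P bipolar vectors of length N with unique labels.

    Parameters
    ----------
    patterns
        (P, N) array over {-1, +1}.
    labels
        P unique label strings.
    shape
        Optional (rows, cols) raster hint for display/serialization;
        rows * cols must equal N when given.
    """

    patterns: np.ndarray
    labels: tuple[str, ...]
    shape: tuple[int, int] | None = field(default=None)

    def __post_init__(self):
        pats = _as_bipolar(self.patterns)
        if pats.ndim != 2:
            raise ValueError("patterns must be a P x N matrix")
        P, N = pats.shape
        if P < 1 or N < 2:
            raise ValueError("need P >= 1 patterns of length N >= 2")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != P:
            raise ValueError("one label per pattern required")
        if len(set(labels)) != P:
            raise ValueError("labels must be unique")
        if self.shape is not None:
            r, c = self.shape
            if r * c != N:
                raise ValueError("shape hint inconsistent with pattern length")
            object.__setattr__(self, "shape", (int(r), int(c)))
        object.__setattr__(self, "patterns", pats)
        object.__setattr__(self, "labels", labels)

    @property
    def P(self) -> int:
        return self.patterns.shape[0]

    @property
    def N(self) -> int:
        return self.patterns.shape[1]

    def subset(self, count: int) -> "PatternSet":
        """First `count` patterns, preserving order and shape hint."""
        return PatternSet(self.patterns[:count], self.labels[:count], self.shape)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.patterns[self.labels.index(label)]

    def hamming_matrix(self) -> np.ndarray:
        """P x P matrix of pairwise Hamming distances."""
        G = self.patterns.astype(np.int64) @ self.patterns.T.astype(np.int64)
        return (self.N - G) // 2


def builtin_charset() -> PatternSet:
    """The bundled 12x8 (N=96) character set A..J.

    Ten correlated letter bitmaps; several pairs (B-D, E-F, C-G) are close in
    Hamming distance, which is what makes this set hard for outer-product
    learning rules.
    """
    labels = tuple(sorted(CHARSET_GLYPHS))
    rows = []
    for lab in labels:
        bits = "".join(CHARSET_GLYPHS[lab])
        rows.append([1 if ch == "1" else -1 for ch in bits])
    return PatternSet(np.array(rows, dtype=np.int8), labels,
                      (CHARSET_ROWS, CHARSET_COLS))


def hamming(a, b) -> int:
    """Hamming distance between two equal-length bipolar vectors.

    HD(a, b) = (N - a.b) / 2: the number of disagreeing components.
    """
    a = _as_bipolar(a, "a").ravel()
    b = _as_bipolar(b, "b").ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return int((a.shape[0] - int(a.astype(np.int64) @ b.astype(np.int64))) // 2)


def corrupt(p, n_flips: int, rng: np.random.Generator) -> np.ndarray:
    """Copy of `p` with exactly `n_flips` distinct positions sign-flipped.

    Positions are drawn uniformly without replacement, so
    hamming(p, corrupt(p, k, rng)) == k always.
    """
    p = _as_bipolar(p).ravel()
    n = p.shape[0]
    if not 0 <= n_flips <= n:
        raise ValueError(f"n_flips must be in [0, {n}], got {n_flips}")
    out = p.copy()
    idx = rng.choice(n, size=n_flips, replace=False)
    out[idx] *= -1
    return out


def random_patterns(P: int, N: int, rng: np.random.Generator) -> PatternSet:
    """P i.i.d. uniform bipolar patterns of length N, labelled p0..p{P-1}."""
    if P < 1 or N < 2:
        raise ValueError("need P >= 1, N >= 2")
    pats = rng.choice(np.array([-1, 1], dtype=np.int8), size=(P, N))
    return PatternSet(pats, tuple(f"p{i}" for i in range(P)))


def write_patterns(ps: PatternSet, path) -> None:
    """Write a pattern set in the plain-text glyph format.

    Each record is a header line ``>LABEL rows cols`` followed by `rows`
    lines of `cols` characters, '1' for +1 and '0' for -1; records are
    separated by blank lines.
    """
    rows, cols = ps.shape if ps.shape is not None else (1, ps.N)
    blocks = []
    for lab, pat in zip(ps.labels, ps.patterns):
        bits = "".join("1" if v > 0 else "0" for v in pat)
        lines = [f">{lab} {rows} {cols}"]
        lines += [bits[r * cols:(r + 1) * cols] for r in range(rows)]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


def read_patterns(path) -> PatternSet:
    """Read a pattern set written by :func:`write_patterns`."""
    text = Path(path).read_text(encoding="utf-8")
    labels: list[str] = []
    pats: list[list[int]] = []
    shape: tuple[int, int] | None = None
    for block in text.strip().split("\n\n"):
        lines = [l.strip() for l in block.strip().splitlines() if l.strip()]
        if not lines:
            continue
        head = lines[0]
        if not head.startswith(">"):
            raise ValueError(f"malformed record header: {head!r}")
        try:
            lab, r, c = head[1:].split()
            r, c = int(r), int(c)
        except ValueError as e:
            raise ValueError(f"malformed record header: {head!r}") from e
        body = lines[1:]
        if len(body) != r:
            raise ValueError(f"record {lab!r}: expected {r} rows, got {len(body)}")
        bits = "".join(body)
        if len(bits) != r * c or set(bits) - {"0", "1"}:
            raise ValueError(f"record {lab!r}: rows must be {c} chars of 0/1")
        if shape is None:
            shape = (r, c)
        elif shape != (r, c):
            raise ValueError(f"record {lab!r}: inconsistent raster {r}x{c}")
        labels.append(lab)
        pats.append([1 if ch == "1" else -1 for ch in bits])
    if not labels:
        raise ValueError("no pattern records found")
    return PatternSet(np.array(pats, dtype=np.int8), tuple(labels), shape)
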