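"""Between-entity interaction attention vector.

A fixed (non-learned) per-token weight prior: tokens in the closed span
[j, k] between the two candidate drug entities draw weights from a high
range, all other tokens from a low range.  Each range is widened by an
oscillation factor sigma, keeping the prior "elastic" while the two
widened intervals stay disjoint.  Defaults: high (0.9, 1.1), low
(0.3, 0.5), sigma 0.1, so the widened intervals are [0.8, 1.2] and
[0.2, 0.6].

The vector scales the rows of the encoder output (diagonal scaling); the
span rows are then averaged, squashed with tanh, and mapped through an
affine head to give the fixed-size interaction feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightRanges",
    "AttentionVector",
    "widen_ranges",
    "build_interaction_vector",
    "apply_interaction",
    "pool_span",
    "pooled_head",
]


@dataclass(frozen=True)
class WeightRanges:
    h_w0: float = 0.9
    h_w1: float = 1.1
    l_w0: float = 0.3
    l_w1: float = 0.5
    sigma: float = 0.1

    def __post_init__(self):
        if not self.h_w0 < self.h_w1:
            raise ValueError("high range requires h_w0 < h_w1")
        if not self.l_w0 < self.l_w1:
            raise ValueError("low range requires l_w0 < l_w1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not self.l_w1 + self.sigma < self.h_w0 - self.sigma:
            raise ValueError(
                "widened low range must stay strictly below widened high range: "
                f"l_w1+sigma={self.l_w1 + self.sigma} >= "
                f"h_w0-sigma={self.h_w0 - self.sigma}"
            )


@dataclass(frozen=True)
class AttentionVector:
    weights: np.ndarray
    span: tuple  # (j, k), closed

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if np.any(self.weights < 0):
            raise ValueError("attention weights must be nonnegative")

    def __len__(self):
        return len(self.weights)


def widen_ranges(ranges: WeightRanges) -> tuple:
    """Widen both ranges by sigma: returns (W_high, W_low) interval pairs."""
    w_high = (ranges.h_w0 - ranges.sigma, ranges.h_w1 + ranges.sigma)
    w_low = (ranges.l_w0 - ranges.sigma, ranges.l_w1 + ranges.sigma)
    if w_low[1] >= w_high[0]:
        raise ValueError("widened intervals overlap")
    return w_high, w_low


def build_interaction_vector(
    n: int,
    j: int,
    k: int,
    ranges: WeightRanges | None = None,
    mode: str = "midpoint",
    seed: int = 13,
) -> AttentionVector:
    """Length-n weight vector: span tokens j..k (inclusive) from the widened
    high interval, the rest from the widened low interval.

    ``midpoint`` mode is deterministic (interval midpoints); ``sampled``
    draws per-token uniform weights from the interval, seeded.
    """
    if ranges is None:
        ranges = WeightRanges()
    if not (0 <= j < k < n):
        raise IndexError(f"need 0 <= j < k < n, got j={j}, k={k}, n={n}")
    w_high, w_low = widen_ranges(ranges)
    in_span = np.zeros(n, dtype=bool)
    in_span[j : k + 1] = True
    if mode == "midpoint":
        weights = np.where(in_span, np.mean(w_high), np.mean(w_low))
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        high = rng.uniform(w_high[0], w_high[1], size=n)
        low = rng.uniform(w_low[0], w_low[1], size=n)
        weights = np.where(in_span, high, low)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AttentionVector(weights=weights, span=(j, k))


def apply_interaction(h_seq: np.ndarray, v: AttentionVector) -> np.ndarray:
    """Scale row i of the n-by-d context matrix by weight i (diag(w) @ H)."""
    h_seq = np.asarray(h_seq, dtype=float)
    if h_seq.shape[0] != len(v):
        raise ValueError(
            f"length mismatch: H has {h_seq.shape[0]} rows, vector has {len(v)}"
        )
    return v.weights[:, None] * h_seq


def pool_span(h_it: np.ndarray, j: int, k: int, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine(tanh(mean of rows j..k inclusive)); divisor is k - j + 1."""
    h_it = np.asarray(h_it, dtype=float)
    if not (0 <= j <= k < h_it.shape[0]):
        raise IndexError(f"need 0 <= j <= k < n, got j={j}, k={k}")
    pooled = h_it[j : k + 1].mean(axis=0)
    return np.asarray(w) @ np.tanh(pooled) + np.asarray(b)


def pooled_head(h_seq: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine(tanh(first-token row)) -- the sentence-level pooled feature."""
    h_seq = np.asarray(h_seq, dtype=float)
    if h_seq.shape[0] == 0:
        raise ValueError("empty sentence")
    return np.asarray(w) @ np.tanh(h_seq[0]) + np.asarray(b)
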