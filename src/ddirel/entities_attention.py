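"""Entity-centred attention weights from windowed distribution masses.

Builds a per-token weight vector that peaks at the two drug-entity
positions and decays with distance, shaped by the probability mass of a
chi-square or Student-t distribution in fixed-width windows.  For the
first entity, a fraction ``before_frac`` of the sentence length is
covered to its left (values assigned right-to-left, highest adjacent to
the entity) and ``after_frac`` to its right (left-to-right, highest
adjacent); the second entity gets the mirror image.  Window masses are
max-normalised, overlaps resolved by elementwise max, entity tokens
pinned to 1, and uncovered tokens receive a small baseline weight.

The resulting vector contracts the encoder output to a single d-vector
(weighted sum over token rows) followed by tanh and an affine head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "EntitiesVector",
    "chi_square_pdf",
    "t_pdf",
    "window_mass",
    "build_entities_vector",
    "apply_entities",
]


@dataclass(frozen=True)
class DistributionSpec:
    family: str  # "chi_square" | "student_t"
    dof: float
    step: float = 1.0

    def __post_init__(self):
        if self.family not in ("chi_square", "student_t"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.dof <= 0:
            raise ValueError("degrees of freedom must be positive")
        if self.step <= 0:
            raise ValueError("window step must be positive")

    def cdf(self, x):
        if self.family == "chi_square":
            return stats.chi2.cdf(x, self.dof)
        return stats.t.cdf(x, self.dof)


#: defaults for the two entities' windows (degrees of freedom and step
#: sizes are free parameters of the prior; these give the peaked,
#: decaying shape on a unit grid)
DEFAULT_LEFT = DistributionSpec("chi_square", dof=4.0, step=1.0)
DEFAULT_RIGHT = DistributionSpec("student_t", dof=5.0, step=1.0)


@dataclass(frozen=True)
class EntitiesVector:
    weights: np.ndarray
    span: tuple  # (j, k)

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("entity attention weights must lie in [0, 1]")

    def __len__(self):
        return len(self.weights)


def chi_square_pdf(x, k: float):
    """Chi-square density: x^(k/2-1) e^(-x/2) / (2^(k/2) Gamma(k/2)) for
    x > 0, zero otherwise."""
    if k <= 0:
        raise ValueError("chi-square dof must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, stats.chi2.pdf(np.maximum(x, 1e-300), k), 0.0)
    return float(out) if out.ndim == 0 else out


def t_pdf(x, n: float):
    """Student-t density with n degrees of freedom,
    Gamma((n+1)/2) / (sqrt(n pi) Gamma(n/2)) (1 + x^2/n)^(-(n+1)/2)."""
    if n <= 0:
        raise ValueError("t dof must be positive")
    out = stats.t.pdf(np.asarray(x, dtype=float), n)
    return float(out) if np.ndim(out) == 0 else out


def window_mass(spec: DistributionSpec, x) -> float:
    """Probability mass CDF(x) - CDF(x - step): the window of width
    ``spec.step`` ending at x."""
    return spec.cdf(x) - spec.cdf(np.asarray(x, dtype=float) - spec.step)


def _window_values(spec: DistributionSpec, width: int) -> np.ndarray:
    """Masses on the unit grid x = step*(rank+1), sorted high-to-low so
    index 0 is assigned nearest the entity."""
    if width <= 0:
        return np.zeros(0)
    grid = spec.step * (np.arange(width) + 1.0)
    masses = np.asarray([window_mass(spec, x) for x in grid], dtype=float)
    return np.sort(masses)[::-1]


def build_entities_vector(
    n: int,
    j: int,
    k: int,
    spec_left: DistributionSpec = DEFAULT_LEFT,
    spec_right: DistributionSpec = DEFAULT_RIGHT,
    before_frac: float = 0.15,
    after_frac: float = 0.25,
    baseline: float = 0.05,
) -> EntitiesVector:
    """Weight vector peaking at entity positions j and k.

    First entity (spec_left): ceil(before_frac*n) tokens to its left and
    ceil(after_frac*n) to its right, masses decaying with distance.  The
    second entity (spec_right) is the mirror image: ceil(after_frac*n)
    on its left, ceil(before_frac*n) on its right.  All masses are scaled
    by the global maximum, entity tokens get exactly 1, overlaps take the
    elementwise max, and uncovered tokens get ``baseline``.
    """
    if not (0 <= j < k < n):
        raise IndexError(f"need 0 <= j < k < n, got j={j}, k={k}, n={n}")
    if not (0 < before_frac < 1 and 0 < after_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if not (0 <= baseline <= 1):
        raise ValueError("baseline must lie in [0, 1]")

    w_before = math.ceil(before_frac * n)
    w_after = math.ceil(after_frac * n)

    # (entity position, left-window width, right-window width, spec)
    plans = [
        (j, w_before, w_after, spec_left),
        (k, w_after, w_before, spec_right),
    ]
    raw = np.zeros(n)
    assignments = []  # (index, value) before normalisation
    for pos, left_w, right_w, spec in plans:
        left_vals = _window_values(spec, left_w)
        for rank, val in enumerate(left_vals):
            idx = pos - 1 - rank
            if idx >= 0:
                assignments.append((idx, val))
        right_vals = _window_values(spec, right_w)
        for rank, val in enumerate(right_vals):
            idx = pos + 1 + rank
            if idx < n:
                assignments.append((idx, val))
    peak = max((val for _, val in assignments), default=0.0)
    weights = np.full(n, float(baseline))
    if peak > 0:
        for idx, val in assignments:
            weights[idx] = max(weights[idx], val / peak)
    weights[j] = 1.0
    weights[k] = 1.0
    weights = np.clip(weights, 0.0, 1.0)
    return EntitiesVector(weights=weights, span=(j, k))


def apply_entities(
    h_seq: np.ndarray,
    v: EntitiesVector,
    w: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """Affine(tanh(v @ H_seq)): weighted sum over token rows, squashed."""
    h_seq = np.asarray(h_seq, dtype=float)
    if h_seq.shape[0] != len(v):
        raise ValueError(
            f"length mismatch: H has {h_seq.shape[0]} rows, vector has {len(v)}"
        )
    pooled = v.weights @ h_seq
    return np.asarray(w) @ np.tanh(pooled) + np.asarray(b)
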