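"""Probability that the spectrum intersection is empty (P_empty).

When the observed intersection is empty, any intersection-based estimator
collapses to r_hat = 1 regardless of the true rate.  P_empty is an a-priori
diagnostic for that regime: the probability, under the i.i.d. substitution
pattern with per-position rate r, that *every* length-k window of a string
with L windows (L + k - 1 positions) contains at least one substitution.

Equivalently: the probability that a sequence of n = L + k - 1 independent
Bernoulli(r) "mutated" flags contains no run of k consecutive unmutated
positions.  This depends only on (L, k, r), not on the sequence itself, and
deliberately ignores repeat structure — it is approximately tight for
non-repetitive sequences and conservative otherwise.

Computed exactly by a Theta(L*k) dynamic program over the trailing run of
unmutated positions, validated against exhaustive enumeration over all 2^n
mutation patterns on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np


@dataclass
class PemptyQuery:
    """Problem instance: L k-mer windows, k-mer length k, substitution rate r."""

    L: int
    k: int
    r: float

    def validate(self) -> None:
        if self.L < 1 or self.k < 1:
            raise ValueError(f"need L >= 1 and k >= 1, got L={self.L}, k={self.k}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must be in [0, 1], got {self.r}")


def p_empty_dp(query: PemptyQuery, *, count_ops: list | None = None) -> float:
    """P_empty by dynamic programming in Theta(L * k) time.

    State after processing position j: the length c in 0..k-1 of the trailing
    run of unmutated positions, restricted to histories in which no run has
    yet reached k.  A substitution (probability r) resets c to 0; otherwise c
    advances, and reaching c = k means some window survived unmutated — that
    probability mass is discarded.  The answer is the mass remaining after
    all L + k - 1 positions.

    ``count_ops``, if given a list, receives the number of inner-loop state
    updates performed (runtime instrumentation for the complexity contract).
    """
    query.validate()
    L, k, r = query.L, query.k, query.r
    if r == 1.0:
        return 1.0
    n = L + k - 1
    state = np.zeros(k, dtype=float)
    state[0] = 1.0  # before any position: empty trailing run
    ops = 0
    for _ in range(n):
        new = np.empty(k, dtype=float)
        new[0] = r * state.sum()
        new[1:] = (1.0 - r) * state[: k - 1]
        # mass that would move to run length k (a clean window) is dropped
        state = new
        ops += k
    if count_ops is not None:
        count_ops.append(ops)
    return float(state.sum())


def p_empty_oracle(query: PemptyQuery) -> float:
    """Exact P_empty by exhaustive enumeration of all 2^(L+k-1) patterns.

    Refuses instances with more than 20 positions.  Exists purely to
    validate :func:`p_empty_dp`.
    """
    query.validate()
    L, k, r = query.L, query.k, query.r
    n = L + k - 1
    if n > 20:
        raise ValueError(f"oracle limited to L+k-1 <= 20 positions, got {n}")
    total = 0.0
    for pattern in product((0, 1), repeat=n):  # 1 = mutated
        # reject patterns with a run of k consecutive unmutated positions
        run = 0
        clean_window = False
        for flag in pattern:
            run = 0 if flag else run + 1
            if run >= k:
                clean_window = True
                break
        if clean_window:
            continue
        m = sum(pattern)
        total += r**m * (1.0 - r) ** (n - m)
    return total


def instability_grid(
    L: int, k_values: Sequence[int], r_values: Sequence[float]
) -> np.ndarray:
    """P_empty over a (k, r) grid for a fixed window count L.

    Returns a matrix of shape (len(k_values), len(r_values)) suitable for a
    heatmap; high cells flag parameter combinations where the estimator is
    expected to destabilize.
    """
    out = np.empty((len(k_values), len(r_values)), dtype=float)
    for i, k in enumerate(k_values):
        for j, r in enumerate(r_values):
            out[i, j] = p_empty_dp(PemptyQuery(L=L, k=k, r=r))
    return out
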