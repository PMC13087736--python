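"""Provable bounds on the estimator's bias.

Three layers, each computable from the source sequence alone:

1. An *expectation sandwich* ``LE <= E[I] <= UE`` on the spectrum
   intersection size, where

       LE = sum_tau (1 - q^sep(tau))
       UE = sum_tau (1 - q^occ(tau) + beta_tau)

   and ``beta_tau`` accounts for a k-mer occurrence mutating into another
   spectrum member ("spurious matches"):

       beta_tau = min( sum_{i: s_i != tau} (1-r)^(k-HD(s_i,tau)) (r/3)^HD(s_i,tau),
                       q^sep(tau) ).

   The first argument of the min is dominated by near-repeat pairs at small
   Hamming distance; ``mode="fast"`` keeps only the q^sep(tau) cap, which is
   a valid but weaker bound and avoids the O(L0^2 k) all-pairs scan.

2. A *variance upper bound* built from the identity
   ``Var[I] = (L0-E[I]) - (L0-E[I])^2 + sum_{tau != v} Pr[!E_tau, !E_v]``
   with each joint-survival term bounded by ``q^sep({tau, v})``.

3. A *bias bracket* on E[q_hat] with f = F^{-1}:

       E[q_hat] <= f(LE)
       E[q_hat] >= f(UE) - U_Var * ( F''(f(UE)) / (2 F'(f(LE))^3) + alpha )

   where ``alpha = max(L0-LE, UE) * max_x (1/6)(F'''F' - 3F''^2)/(-F'^5)``
   bounds the third-order Taylor remainder (clamped at 0 from below: a
   negative remainder coefficient can only help a lower bound).  The
   hypothesis ``a_1 >= 1`` guarantees F'(0) != 0 so every quotient is finite.

Raw bracket endpoints can exit [0, 1] when U_Var is loose; reported values
are clamped to the unit interval since q_hat is a probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .estimator import F_derivatives, F_eval, r_to_q, solve_q_hat
from .spectrum import AbundanceHistogram, SpectrumIndex, abundance_histogram

logger = logging.getLogger(__name__)

#: above this many distinct k-mers, exact-beta mode falls back to fast mode
EXACT_BETA_L0_LIMIT = 20_000

#: grid resolution for the inner maximization in alpha
ALPHA_GRID_POINTS = 4096


@dataclass
class BiasBoundReport:
    """Bias bracket for E[q_hat] at an assumed substitution rate."""

    r: float
    q: float
    LE: float
    UE: float
    beta_total: float
    U_Var: float
    alpha: float
    Eq_lower: float
    Eq_upper: float
    mode: str


def _byte_matrix(spec: SpectrumIndex):
    """Distinct k-mers as an (L0, k) uint8 matrix plus parallel metadata."""
    distinct = list(spec.kmers)
    arr = np.frombuffer("".join(distinct).encode(), dtype=np.uint8).reshape(
        len(distinct), spec.k
    )
    occs = np.array([len(spec.kmers[t]) for t in distinct], dtype=np.int64)
    return distinct, arr, occs


def _sep_counts(spec: SpectrumIndex) -> np.ndarray:
    """sep(tau) per distinct k-mer, in spectrum iteration order."""
    out = np.empty(len(spec.kmers), dtype=np.int64)
    for idx, pos in enumerate(spec.kmers.values()):
        count, next_free = 0, -(10**18)
        for p in pos:  # positions are already sorted
            if p >= next_free:
                count += 1
                next_free = p + spec.k
        out[idx] = count
    return out


def expectation_bounds(
    spec: SpectrumIndex, r: float, mode: str = "exact"
) -> Tuple[float, float, float]:
    """Sandwich ``LE <= E[I] <= UE``; returns ``(LE, UE, beta_total)``.

    ``mode="exact"`` evaluates the Hamming-distance sum in beta_tau over all
    distinct k-mer pairs weighted by occurrence counts; ``mode="fast"`` uses
    the q^sep(tau) cap only.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"r must be in (0, 1), got {r}")
    if mode not in ("exact", "fast"):
        raise ValueError(f"mode must be 'exact' or 'fast', got {mode!r}")
    if mode == "exact" and spec.L0 > EXACT_BETA_L0_LIMIT:
        logger.warning(
            "L0=%d exceeds exact-beta limit %d; switching to fast mode",
            spec.L0,
            EXACT_BETA_L0_LIMIT,
        )
        mode = "fast"

    k = spec.k
    q = r_to_q(r, k)
    seps = _sep_counts(spec)
    occs = np.array([len(p) for p in spec.kmers.values()], dtype=np.int64)

    q_sep = q**seps.astype(float)
    LE = float(np.sum(1.0 - q_sep))

    if mode == "fast":
        beta = q_sep.copy()
    else:
        _, arr, _ = _byte_matrix(spec)
        # weight of a single position mutating to a k-mer at Hamming distance d
        d_range = np.arange(k + 1, dtype=float)
        w = (1.0 - r) ** (k - d_range) * (r / 3.0) ** d_range
        n = arr.shape[0]
        beta_raw = np.empty(n, dtype=float)
        for i in range(n):
            d = (arr != arr[i]).sum(axis=1)
            contrib = occs * w[d]
            beta_raw[i] = contrib.sum() - contrib[i]  # drop the d=0 self term
        beta = np.minimum(beta_raw, q_sep)

    UE = float(np.sum(1.0 - q ** occs.astype(float) + beta))
    return LE, UE, float(beta.sum())


def _greedy_sep(merged: np.ndarray, k: int) -> int:
    count, next_free = 0, -(10**18)
    for p in merged:
        if p >= next_free:
            count += 1
            next_free = p + k
    return count


def _pair_term_bruteforce(spec: SpectrumIndex, q: float) -> float:
    """Reference O(L0^2) pair term: sum over ordered tau != v of q^sep."""
    pos_lists = [np.asarray(p, dtype=np.int64) for p in spec.kmers.values()]
    k = spec.k
    total = 0.0
    for i in range(len(pos_lists) - 1):
        for j in range(i + 1, len(pos_lists)):
            merged = np.sort(np.concatenate((pos_lists[i], pos_lists[j])))
            total += q ** _greedy_sep(merged, k)
    return 2.0 * total  # the double sum counts each unordered pair twice


def _sep_with_inserted_positions(P: np.ndarray, k: int, S: np.ndarray) -> np.ndarray:
    """sep(P + {p}) for every p in S at once, via incremental greedy.

    The left-to-right greedy over the merged positions visits P's prefix
    below p unchanged, may or may not pick p depending on the prefix's
    next-free point, and then resumes on P's suffix.  Prefix states and
    greedy-from-index suffix counts are precomputed in O(|P|), so each
    insertion is O(log |P|).
    """
    m = len(P)
    # prefix greedy state before index j: picks so far, next-free position
    cnt_prefix = np.zeros(m + 1, dtype=np.int64)
    cur_prefix = np.full(m + 1, -(10**18), dtype=np.int64)
    for j in range(1, m + 1):
        if P[j - 1] >= cur_prefix[j - 1]:
            cnt_prefix[j] = cnt_prefix[j - 1] + 1
            cur_prefix[j] = P[j - 1] + k
        else:
            cnt_prefix[j] = cnt_prefix[j - 1]
            cur_prefix[j] = cur_prefix[j - 1]
    # g[idx]: greedy picks over P[idx:] when P[idx] is pickable
    g = np.zeros(m + 1, dtype=np.int64)
    nxt = np.searchsorted(P, P + k, side="left")
    for idx in range(m - 1, -1, -1):
        g[idx] = 1 + g[nxt[idx]]
    sep_alone = cnt_prefix[m]

    j = np.searchsorted(P, S, side="left")
    cur = cur_prefix[j]
    take = S >= cur
    resume = np.searchsorted(P, S + k, side="left")
    out = np.where(take, cnt_prefix[j] + 1 + g[resume], sep_alone)
    return out


def _pair_term(spec: SpectrumIndex, q: float) -> float:
    """sum over ordered pairs tau != v of q^sep({tau, v}).

    Decomposed for speed: singleton-singleton pairs (the bulk) have sep = 2
    unless their positions are within k (then 1), countable by a two-pointer
    sweep; repeated-singleton pairs use the vectorized incremental greedy;
    only repeated-repeated pairs fall back to explicit merges.
    """
    k = spec.k
    singles: List[int] = []
    repeated: List[np.ndarray] = []
    for pos in spec.kmers.values():
        if len(pos) == 1:
            singles.append(pos[0])
        else:
            repeated.append(np.asarray(pos, dtype=np.int64))
    S = np.sort(np.array(singles, dtype=np.int64))
    m = len(S)

    # singleton-singleton: pairs with |p - p'| < k overlap (sep = 1)
    close = int(np.sum(np.searchsorted(S, S + k, side="left") - np.arange(1, m + 1)))
    n_pairs = m * (m - 1) // 2
    total = close * q + (n_pairs - close) * q**2

    S_unsorted = np.array(singles, dtype=np.int64)
    for P in repeated:
        seps = _sep_with_inserted_positions(P, k, S_unsorted)
        total += float(np.sum(q ** seps.astype(float)))

    for i in range(len(repeated) - 1):
        for j in range(i + 1, len(repeated)):
            merged = np.sort(np.concatenate((repeated[i], repeated[j])))
            total += q ** _greedy_sep(merged, k)

    return 2.0 * total


def variance_upper(
    spec: SpectrumIndex, r: float, E_bounds: Tuple[float, float]
) -> float:
    """Upper bound U_Var on Var[I].

    Combines the joint-survival pair term with the Bernoulli-sum term
    ``x - x^2`` at ``x = L0 - UE`` when that is at least 1/2 (the function is
    decreasing there, so plugging the lower bound on x is valid), and with
    the global maximum 1/4 otherwise.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"r must be in (0, 1), got {r}")
    LE, UE = E_bounds
    q = r_to_q(r, spec.k)
    pair = _pair_term(spec, q)
    x = spec.L0 - UE
    if x >= 0.5:
        bern = x - x * x
    else:
        bern = 0.25
    return pair + bern


def alpha_term(hist: AbundanceHistogram, E_bounds: Tuple[float, float]) -> float:
    """Third-order remainder coefficient of the bias lower bound.

    ``alpha = max(L0 - LE, UE) * max_{x in (0,1)} phi(x)`` with
    ``phi(x) = (1/6) (F'''(x) F'(x) - 3 F''(x)^2) / (-F'(x)^5)``,
    the third derivative of f = F^{-1} expressed through F.  The inner
    maximization uses a dense grid plus golden-section refinement around the
    grid argmax.  Clamped at 0 from below.

    Requires ``a_1 >= 1`` so that F'(x) is bounded away from 0 near x = 0.
    """
    if hist.a.get(1, 0) < 1:
        raise ValueError(
            "bias bounds require at least one singleton k-mer (a_1 >= 1)"
        )
    LE, UE = E_bounds

    def phi(x: float) -> float:
        d1 = F_derivatives(hist, x, 1)
        d2 = F_derivatives(hist, x, 2)
        d3 = F_derivatives(hist, x, 3)
        return (d3 * d1 - 3.0 * d2 * d2) / (6.0 * (-(d1**5)))

    xs = np.linspace(1e-6, 1.0 - 1e-6, ALPHA_GRID_POINTS)
    vals = np.array([phi(x) for x in xs])
    i = int(np.argmax(vals))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, len(xs) - 1)]
    # golden-section refinement of the bracketing interval
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = phi(c), phi(d)
    for _ in range(60):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = phi(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = phi(d)
        if b - a < 1e-12:
            break
    inner = max(vals[i], fc, fd, 0.0)
    return max(hist.L0 - LE, UE) * inner


def bias_bounds_q(spec: SpectrumIndex, r: float, mode: str = "exact") -> BiasBoundReport:
    """Bracket ``[Eq_lower, Eq_upper]`` on E[q_hat] at substitution rate r.

    Endpoints are clamped to [0, 1]; the raw lower bound can drop below 0
    when U_Var is loose (heavily repetitive spectra at small r).
    """
    hist = abundance_histogram(spec)
    if hist.a.get(1, 0) < 1:
        raise ValueError(
            "bias bounds require at least one singleton k-mer (a_1 >= 1)"
        )
    q = r_to_q(r, spec.k)
    LE, UE, beta_total = expectation_bounds(spec, r, mode=mode)
    U_Var = variance_upper(spec, r, (LE, UE))
    alpha = alpha_term(hist, (LE, UE))

    # f = F^{-1} is only defined on [0, L0]; UE may exceed L0 slightly
    f_LE = solve_q_hat(hist, min(max(LE, 0.0), hist.L0))
    f_UE = solve_q_hat(hist, min(max(UE, 0.0), hist.L0))

    Eq_upper = f_LE
    d2 = F_derivatives(hist, f_UE, 2)
    d1 = F_derivatives(hist, f_LE, 1)
    Eq_lower = f_UE - U_Var * (d2 / (2.0 * d1**3) + alpha)

    return BiasBoundReport(
        r=r,
        q=q,
        LE=LE,
        UE=UE,
        beta_total=beta_total,
        U_Var=U_Var,
        alpha=alpha,
        Eq_lower=min(max(Eq_lower, 0.0), 1.0),
        Eq_upper=min(max(Eq_upper, 0.0), 1.0),
        mode=f"{mode}_beta",
    )
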