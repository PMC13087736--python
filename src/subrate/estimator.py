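"""Repeat-aware substitution-rate estimation by inverting F(q).

Model: ``t`` is derived from ``s`` by substituting each position
independently with probability ``r`` (uniform over the three other bases).
With ``q = 1 - (1-r)^k`` — the chance a k-mer window carries at least one
substitution — the expected spectrum intersection is approximately

    F(q) = L0 - sum_i a_i * q^i

where ``a_i`` is the abundance histogram of ``s``.  The estimator plugs the
observed intersection size in place of the expectation and solves
``F(q_hat) = I_obs`` for the unique root in [0, 1] (F is strictly decreasing
there), then maps back via ``r_hat = 1 - (1 - q_hat)^(1/k)``.

The repeat-oblivious comparator ``r_obl = 1 - (I_obs / L)^(1/k)`` is the
estimator one obtains under a no-repeat assumption (the Mash-style
derivation); it coincides with ``r_hat`` exactly when all k-mers are
singletons and overestimates the rate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectrum import AbundanceHistogram

#: absolute tolerance on |F(q_hat) - I_obs|
SOLVER_TOL = 1e-12
#: iteration cap for the safeguarded Newton / bisection solver
SOLVER_MAXITER = 200


@dataclass
class EstimateResult:
    """Outcome of one estimation: rates plus solver diagnostics."""

    r_hat: float
    q_hat: float
    iterations: int
    residual: float
    method: str  # "newton", "bisection_fallback" or "boundary"


def F_eval(hist: AbundanceHistogram, q: float) -> float:
    """Evaluate ``F(q) = L0 - sum_i a_i q^i``.

    ``F(0) = L0``, ``F(1) = 0`` and F is strictly decreasing on [0, 1].
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return hist.L0 - sum(c * q**i for i, c in hist.a.items())


def F_derivatives(hist: AbundanceHistogram, q: float, order: int) -> float:
    """Termwise derivative of F at ``q`` (order 1, 2 or 3).

    F'(q) = -sum i a_i q^{i-1} < 0 on (0, 1]; F'' <= 0; F''' <= 0.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if order == 1:
        return -sum(i * c * q ** (i - 1) for i, c in hist.a.items())
    if order == 2:
        return -sum(i * (i - 1) * c * q ** (i - 2) for i, c in hist.a.items() if i >= 2)
    if order == 3:
        return -sum(
            i * (i - 1) * (i - 2) * c * q ** (i - 3)
            for i, c in hist.a.items()
            if i >= 3
        )
    raise ValueError(f"order must be 1, 2 or 3, got {order}")


def _solve(hist: AbundanceHistogram, I_obs: float):
    """Root of F(q) = I_obs on [0, 1] with diagnostics (q, iters, res, method)."""
    if I_obs < 0 or I_obs > hist.L0:
        raise ValueError(f"I_obs={I_obs} outside [0, L0={hist.L0}]")
    if I_obs == hist.L0:
        return 0.0, 0, 0.0, "boundary"
    if I_obs == 0:
        return 1.0, 0, 0.0, "boundary"

    # Safeguarded Newton: keep a bracket [lo, hi] with g(lo) > 0 > g(hi)
    # where g(q) = F(q) - I_obs; bisect whenever Newton leaves the bracket.
    lo, hi = 0.0, 1.0
    q = 0.5
    method = "newton"
    for it in range(1, SOLVER_MAXITER + 1):
        g = F_eval(hist, q) - I_obs
        if abs(g) <= SOLVER_TOL:
            return q, it, abs(g), method
        if g > 0:
            lo = q
        else:
            hi = q
        dg = F_derivatives(hist, q, 1)
        step_ok = False
        if dg < 0:
            q_new = q - g / dg
            if lo < q_new < hi:
                q = q_new
                step_ok = True
        if not step_ok:
            q = 0.5 * (lo + hi)
            method = "bisection_fallback"
        if hi - lo <= 1e-17:
            break
    g = F_eval(hist, q) - I_obs
    return q, SOLVER_MAXITER, abs(g), method


def solve_q_hat(hist: AbundanceHistogram, I_obs: float) -> float:
    """Unique q in [0, 1] with F(q) = I_obs; boundary inputs short-circuit."""
    return _solve(hist, I_obs)[0]


def q_to_r(q: float, k: int) -> float:
    """Map window-mutation probability q to per-base rate r = 1-(1-q)^{1/k}."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return -((1.0 - q) ** (1.0 / k)) + 1.0


def r_to_q(r: float, k: int) -> float:
    """Inverse of :func:`q_to_r`: q = 1 - (1-r)^k."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    return -((1.0 - r) ** k) + 1.0


def estimate_r(hist: AbundanceHistogram, I_obs: float) -> EstimateResult:
    """Repeat-aware estimate of the substitution rate from I_obs.

    ``I_obs`` may be fractional (the sketched variant feeds a scaled
    intersection through the same solver).
    """
    q_hat, iters, res, method = _solve(hist, I_obs)
    return EstimateResult(
        r_hat=q_to_r(q_hat, hist.k),
        q_hat=q_hat,
        iterations=iters,
        residual=res,
        method=method,
    )


def r_oblivious(I_obs: float, L: int, k: int) -> float:
    """Repeat-oblivious estimator r_obl = 1 - (I_obs / L)^(1/k)."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    if not 0 <= I_obs <= L:
        raise ValueError(f"I_obs={I_obs} outside [0, L={L}]")
    return 1.0 - (I_obs / L) ** (1.0 / k)


def q_oblivious(I_obs: float, L: int) -> float:
    """Companion window-level repeat-oblivious estimate q_obl = 1 - I_obs/L."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    return 1.0 - I_obs / L
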