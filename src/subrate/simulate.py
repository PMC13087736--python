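"""Substitution-process simulator and synthetic repetitive sequences.

The mutation model substitutes each position independently with probability
r, uniformly over the three other bases.  The generators emulate the regimes
a genomic user encounters, from easy to hard for k-mer intersection methods:

* ``random`` — i.i.d. uniform bases; essentially repeat-free at usual k,
  so nearly all k-mers are singletons.
* ``tandem`` — a simple tandem repeat: one random unit (e.g. ~545 nt) copied
  a possibly fractional number of times (~4.2), each copy independently
  diverged; k-mers interior to the unit occur once per copy.
* ``hor``    — an alpha-satellite-like higher-order repeat: ~171 nt monomers,
  themselves diverged copies of one ancestral monomer, concatenated into a
  higher-order unit that is then tandem-copied at low divergence.  This
  yields many high-multiplicity k-mers (L0 << L) plus a heavy low
  Hamming-distance "near-repeat" shoulder — the hardest regime.

``run_replicates`` and ``error_grid`` drive replicated estimation
experiments comparing the repeat-aware estimator with the repeat-oblivious
one.  One root seed spawns independent per-replicate streams, so replicate i
does not depend on the total replicate count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .estimator import estimate_r, r_oblivious
from .spectrum import abundance_histogram, build_spectrum, kmer_set

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII code -> 0..3, 255 for anything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mutate(sequence: str, r: float, seed: SeedLike) -> str:
    """Apply the substitution process at rate r; deterministic given seed.

    Each ACGT position is kept with probability 1-r, otherwise replaced by
    one of the three *other* bases uniformly (a substitution never maps a
    base to itself).  Non-ACGT characters are left untouched.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    rng = _rng(seed)
    codes = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)].copy()
    valid = codes != 255
    hit = (rng.random(len(codes)) < r) & valid
    # offset 1..3 from the current base, mod 4, never lands on itself
    offsets = rng.integers(1, 4, size=int(hit.sum()))
    codes[hit] = (codes[hit] + offsets) % 4
    out = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    out[valid] = _BASES[codes[valid]]
    return out.tobytes().decode()


def random_sequence(length: int, seed: SeedLike) -> str:
    """i.i.d. uniform ACGT string."""
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class RepeatSpec:
    """Recipe for a synthetic source sequence.

    ``unit_length`` is the repeat-unit length for ``tandem`` and the monomer
    length for ``hor``.  ``copy_number`` may be fractional (the final copy is
    truncated); when None it is derived from ``total_length``.  ``divergence``
    is the per-copy substitution probability applied independently to each
    tandem copy.  For ``hor``, ``monomers_per_unit`` monomers — each a
    ``monomer_divergence``-diverged copy of one ancestral monomer — form the
    higher-order unit that is tandem-copied.
    """

    kind: str  # "random", "tandem" or "hor"
    total_length: int
    unit_length: int = 545
    copy_number: Optional[float] = None
    divergence: float = 0.02
    seed: int = 0
    monomers_per_unit: int = 12
    monomer_divergence: float = 0.20

    def validate(self) -> None:
        if self.kind not in ("random", "tandem", "hor"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.kind != "random" and self.total_length < self.unit_length:
            raise ValueError("total_length must be at least unit_length")
        if self.copy_number is not None and self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


def _tandem_copies(unit: str, copy_number: float, divergence: float,
                   seeds: np.random.SeedSequence) -> str:
    n_full = int(copy_number)
    frac = copy_number - n_full
    n_copies = n_full + (1 if frac > 0 else 0)
    children = seeds.spawn(n_copies)
    parts: List[str] = []
    for i in range(n_full):
        parts.append(mutate(unit, divergence, np.random.default_rng(children[i])))
    if frac > 0:
        tail = mutate(unit, divergence, np.random.default_rng(children[-1]))
        parts.append(tail[: int(round(frac * len(unit)))])
    return "".join(parts)


def generate(spec: RepeatSpec) -> str:
    """Materialize the synthetic source sequence described by ``spec``."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    if spec.kind == "random":
        return random_sequence(spec.total_length, np.random.default_rng(root))

    if spec.kind == "tandem":
        unit_seed, copy_seed = root.spawn(2)
        unit = random_sequence(spec.unit_length, np.random.default_rng(unit_seed))
        copies = (
            spec.copy_number
            if spec.copy_number is not None
            else spec.total_length / spec.unit_length
        )
        return _tandem_copies(unit, copies, spec.divergence, copy_seed)

    # hor: related monomers -> higher-order unit -> tandem copies
    anc_seed, mono_seed, copy_seed = root.spawn(3)
    ancestor = random_sequence(spec.unit_length, np.random.default_rng(anc_seed))
    mono_children = mono_seed.spawn(spec.monomers_per_unit)
    unit = "".join(
        mutate(ancestor, spec.monomer_divergence, np.random.default_rng(s))
        for s in mono_children
    )
    copies = (
        spec.copy_number
        if spec.copy_number is not None
        else spec.total_length / len(unit)
    )
    return _tandem_copies(unit, copies, spec.divergence, copy_seed)


@dataclass
class ExperimentSummary:
    """Replicated estimation experiment: per-replicate estimates + summaries."""

    r_true: float
    k: int
    n_replicates: int
    r_hat: List[float] = field(default_factory=list)
    r_obl: List[float] = field(default_factory=list)
    mean_r_hat: float = math.nan
    mean_r_obl: float = math.nan
    sd_r_hat: float = math.nan
    sd_r_obl: float = math.nan
    mean_rel_abs_error: float = math.nan  # (1/n) sum |r_hat_i - r| / r

    def validate(self) -> None:
        if len(self.r_hat) != self.n_replicates or len(self.r_obl) != self.n_replicates:
            raise ValueError("per-replicate lists must have length n_replicates")


def run_replicates(
    source: str, k: int, r: float, n: int, seed: SeedLike
) -> ExperimentSummary:
    """Mutate ``source`` n times at rate r; estimate r both ways each time."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    spec_s = build_spectrum(source, k)
    hist = abundance_histogram(spec_s)
    s_set = frozenset(spec_s.kmers)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n)

    r_hats: List[float] = []
    r_obls: List[float] = []
    for child in children:
        t = mutate(source, r, np.random.default_rng(child))
        I_obs = len(s_set & kmer_set(t, k))
        r_hats.append(estimate_r(hist, I_obs).r_hat)
        r_obls.append(r_oblivious(I_obs, spec_s.L, k))

    rh = np.array(r_hats)
    ro = np.array(r_obls)
    summary = ExperimentSummary(
        r_true=r,
        k=k,
        n_replicates=n,
        r_hat=r_hats,
        r_obl=r_obls,
        mean_r_hat=float(rh.mean()),
        mean_r_obl=float(ro.mean()),
        sd_r_hat=float(rh.std(ddof=1)) if n > 1 else math.nan,
        sd_r_obl=float(ro.std(ddof=1)) if n > 1 else math.nan,
        mean_rel_abs_error=float(np.abs(rh - r).mean() / r) if r > 0 else math.nan,
    )
    summary.validate()
    return summary


def error_grid(
    source: str,
    k_values: Sequence[int],
    r_values: Sequence[float],
    n: int,
    seed: int,
    *,
    cap: float = 1.0,
) -> np.ndarray:
    """Mean relative absolute error of r_hat over a (k, r) grid, capped.

    Each cell is ``(1/n) sum_i |r_hat_i - r| / r`` truncated at ``cap``.
    Cells with r = 0 are refused (relative error is undefined there).
    """
    if any(r <= 0 for r in r_values):
        raise ValueError("relative error is undefined at r = 0; drop such cells")
    root = np.random.SeedSequence(seed)
    cells = root.spawn(len(k_values) * len(r_values))
    out = np.empty((len(k_values), len(r_values)), dtype=float)
    idx = 0
    for i, k in enumerate(k_values):
        for j, r in enumerate(r_values):
            summary = run_replicates(source, k, r, n, cells[idx])
            out[i, j] = min(summary.mean_rel_abs_error, cap)
            idx += 1
    return out
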