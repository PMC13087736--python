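"""k-mer spectra, abundance histograms and occurrence statistics.

A sequence ``s`` of length ``n`` has ``L = n - k + 1`` k-mer windows (fewer
when windows containing non-ACGT characters are dropped).  The *k-spectrum*
is the set of its distinct k-mers; the *abundance histogram* counts, for each
multiplicity ``i``, the number ``a_i`` of distinct k-mers occurring exactly
``i`` times, so that ``L0 = sum(a_i)`` and ``L = sum(i * a_i)``.

Two occurrence statistics drive the repeat-aware analysis:

* ``occ(tau)`` — the number of windows equal to ``tau``;
* ``sep(K)``  — the maximum number of pairwise non-overlapping occurrences of
  a k-mer set ``K`` (start positions at least ``k`` apart).

All positions reported by this module are 1-based, matching the usual
string-indexing convention of the underlying math.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
from scipy.stats import binom

_VALID = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


@dataclass
class SpectrumIndex:
    """Distinct k-mers of a sequence with their sorted occurrence positions.

    Attributes
    ----------
    k : int
        k-mer length.
    L : int
        Total number of valid k-mer windows.
    kmers : dict
        Maps each distinct k-mer to its strictly increasing list of 1-based
        start positions.
    """

    k: int
    L: int
    kmers: Dict[str, List[int]] = field(default_factory=dict)

    @property
    def L0(self) -> int:
        """Number of distinct k-mers."""
        return len(self.kmers)

    def distinct(self) -> Iterable[str]:
        return self.kmers.keys()

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        total = 0
        for kmer, pos in self.kmers.items():
            if len(kmer) != self.k or not set(kmer) <= _VALID:
                raise ValueError(f"bad k-mer {kmer!r}")
            if not pos or any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"positions of {kmer!r} not strictly increasing")
            total += len(pos)
        if total != self.L:
            raise ValueError(f"sum of occ = {total} != L = {self.L}")


@dataclass
class AbundanceHistogram:
    """Sparse abundance histogram: multiplicity ``i`` -> count ``a_i``.

    ``L0 = sum(a_i)`` distinct k-mers, ``L = sum(i * a_i)`` total windows.
    """

    k: int
    a: Dict[int, int]
    L: int
    L0: int

    def validate(self) -> None:
        if any(c < 1 or i < 1 for i, c in self.a.items()):
            raise ValueError("histogram entries must have i >= 1, a_i >= 1")
        if sum(self.a.values()) != self.L0:
            raise ValueError("L0 != sum(a_i)")
        if sum(i * c for i, c in self.a.items()) != self.L:
            raise ValueError("L != sum(i * a_i)")

    @classmethod
    def from_counts(cls, k: int, counts: Mapping[int, int]) -> "AbundanceHistogram":
        """Build from a map multiplicity -> count, deriving L and L0."""
        a = {int(i): int(c) for i, c in counts.items() if c > 0}
        L = sum(i * c for i, c in a.items())
        L0 = sum(a.values())
        return cls(k=k, a=a, L=L, L0=L0)


def build_spectrum(sequence: str, k: int, *, canonical: bool = False) -> SpectrumIndex:
    """Index every valid k-mer window of ``sequence``.

    The input is upper-cased; windows containing characters outside ACGT are
    skipped and do not count towards ``L``.  With ``canonical=True`` each
    window is replaced by the lexicographic minimum of itself and its reverse
    complement (off by default: the model treats strings literally).

    Raises
    ------
    ValueError
        If ``k <= 0`` or the sequence is shorter than ``k``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        raise ValueError(f"sequence length {n} shorter than k={k}")

    kmers: Dict[str, List[int]] = {}
    L = 0
    # rightmost invalid character index seen so far (−1 if none in window)
    last_bad = -1
    for i in range(n):
        if seq[i] not in _VALID:
            last_bad = i
        start = i - k + 1
        if start < 0 or last_bad >= start:
            continue
        kmer = seq[start : i + 1]
        if canonical:
            rc = _revcomp(kmer)
            if rc < kmer:
                kmer = rc
        kmers.setdefault(kmer, []).append(start + 1)
        L += 1
    return SpectrumIndex(k=k, L=L, kmers=kmers)


def abundance_histogram(spec: SpectrumIndex) -> AbundanceHistogram:
    """Abundance histogram of a spectrum."""
    counts = Counter(len(pos) for pos in spec.kmers.values())
    hist = AbundanceHistogram(k=spec.k, a=dict(counts), L=spec.L, L0=spec.L0)
    hist.validate()
    return hist


def occ(spec: SpectrumIndex, kmer: str) -> int:
    """Number of occurrences of ``kmer`` in the indexed sequence (0 if absent)."""
    if len(kmer) != spec.k:
        raise ValueError(f"k-mer length {len(kmer)} != k={spec.k}")
    return len(spec.kmers.get(kmer.upper(), ()))


def sep(spec: SpectrumIndex, kmers: Iterable[str]) -> int:
    """Maximum number of pairwise non-overlapping occurrences of a k-mer set.

    Occurrences at positions i, j are non-overlapping when ``|j - i| >= k``.
    Computed by a left-to-right greedy sweep over the merged sorted position
    lists; greedy is optimal because all occurrence intervals have the same
    length ``k`` (earliest-finishing-first interval scheduling).
    """
    positions: List[int] = []
    for kmer in kmers:
        positions.extend(spec.kmers.get(kmer.upper(), ()))
    positions.sort()
    count = 0
    next_free = -(10**18)
    for p in positions:
        if p >= next_free:
            count += 1
            next_free = p + spec.k
    return count


def intersection_size(spec_a: SpectrumIndex, spec_b: SpectrumIndex) -> int:
    """Size of the set intersection of two k-spectra (multiplicity ignored)."""
    if spec_a.k != spec_b.k:
        raise ValueError(f"mismatched k: {spec_a.k} != {spec_b.k}")
    small, big = (spec_a, spec_b) if spec_a.L0 <= spec_b.L0 else (spec_b, spec_a)
    return sum(1 for kmer in small.kmers if kmer in big.kmers)


def kmer_set(sequence: str, k: int) -> frozenset:
    """Fast path: the k-spectrum of a clean ACGT string as a set."""
    return frozenset(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def pairwise_hd_histogram(spec: SpectrumIndex) -> Dict[int, int]:
    """All-vs-all Hamming distances between *distinct* k-mers of a spectrum.

    Returns counts over unordered pairs; distances lie in 1..k.  Quadratic in
    the number of distinct k-mers — intended for diagnostics on moderate
    spectra, where a heavy low-distance shoulder signals "near-repeats" that
    inflate the estimator's bias.
    """
    distinct = list(spec.kmers)
    if len(distinct) < 2:
        return {}
    # byte matrix lets numpy do the O(n^2 k) comparisons
    arr = np.frombuffer("".join(distinct).encode(), dtype=np.uint8).reshape(
        len(distinct), spec.k
    )
    out: Counter = Counter()
    for i in range(len(distinct) - 1):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1)
        vals, cnts = np.unique(d, return_counts=True)
        for v, c in zip(vals, cnts):
            out[int(v)] += int(c)
    return dict(out)


def hd_reference_pmf(k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Hamming-distance distribution between two uniform random k-mers.

    Two independent uniform k-mers disagree at each position with probability
    3/4, so HD ~ Binomial(k, 3/4).  Returns ``(distances, probabilities)``
    for plotting against :func:`pairwise_hd_histogram`.
    """
    d = np.arange(k + 1)
    return d, binom.pmf(d, k, 0.75)
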