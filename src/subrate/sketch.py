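"""FracMinHash sketching of k-mer spectra and sketched estimation.

A FracMinHash sketch keeps exactly those k-mers whose seeded 64-bit hash,
normalized to (0, 1), falls below a threshold theta.  The sketched
intersection I_theta of two sequences then has expectation theta * I over
the hashing process, so the full estimator applies unchanged to the plug-in
I_theta / theta — with one caveat: at very low mutation rates the scaled
intersection can exceed L0, in which case the estimate is hard-coded to 0.

Hashing uses blake2b keyed with the seed, truncated to 64 bits; membership
is a deterministic function of (k-mer, seed, theta), and sketches nest:
theta' < theta implies sketch(theta') is a subset of sketch(theta) under the
same seed.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field
from typing import List

from .estimator import EstimateResult, estimate_r, q_to_r
from .spectrum import AbundanceHistogram, SpectrumIndex

_HASH_DENOM = float(2**64)


@dataclass(frozen=True)
class SketchConfig:
    """FracMinHash parameters: threshold theta, hash seed, canonical flag."""

    theta: float
    hash_seed: int = 0
    canonical: bool = False

    def __post_init__(self):
        if not 0.0 < self.theta <= 1.0:
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")


@dataclass
class Sketch:
    """Retained k-mers of a spectrum, stored as sorted 64-bit hash values."""

    k: int
    theta: float
    hash_seed: int
    hashes: List[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hashes)

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "theta": self.theta, "hash_seed": self.hash_seed,
             "hashes": self.hashes}
        )

    @classmethod
    def from_json(cls, text: str) -> "Sketch":
        d = json.loads(text)
        return cls(k=d["k"], theta=d["theta"], hash_seed=d["hash_seed"],
                   hashes=list(d["hashes"]))


def kmer_hash(kmer: str, seed: int) -> int:
    """Seeded 64-bit hash of a k-mer (uniform over [0, 2^64))."""
    key = struct.pack("<Q", seed & 0xFFFFFFFFFFFFFFFF)
    digest = hashlib.blake2b(kmer.encode(), digest_size=8, key=key).digest()
    return struct.unpack("<Q", digest)[0]


def sketch(spec: SpectrumIndex, cfg: SketchConfig) -> Sketch:
    """FracMinHash sketch: k-mers with normalized hash below theta."""
    cutoff = cfg.theta * _HASH_DENOM
    kept = sorted(
        h for kmer in spec.kmers if (h := kmer_hash(kmer, cfg.hash_seed)) < cutoff
    )
    return Sketch(k=spec.k, theta=cfg.theta, hash_seed=cfg.hash_seed, hashes=kept)


def sketch_intersection(a: Sketch, b: Sketch) -> int:
    """|members(a) & members(b)|; configs must match exactly."""
    if (a.k, a.theta, a.hash_seed) != (b.k, b.theta, b.hash_seed):
        raise ValueError("sketches built with different (k, theta, hash_seed)")
    return len(set(a.hashes) & set(b.hashes))


def estimate_from_sketch(
    hist: AbundanceHistogram, I_theta: int, cfg: SketchConfig
) -> EstimateResult:
    """Estimate r from a sketched intersection via the plug-in I_theta/theta.

    If the scaled intersection exceeds L0 (possible at very low rates), the
    estimate is hard-coded to r_hat = 0.
    """
    if I_theta < 0:
        raise ValueError(f"I_theta must be non-negative, got {I_theta}")
    scaled = I_theta / cfg.theta
    if scaled > hist.L0:
        return EstimateResult(
            r_hat=0.0, q_hat=0.0, iterations=0, residual=0.0, method="boundary"
        )
    return estimate_r(hist, scaled)
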