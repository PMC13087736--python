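# Methods

## Model and estimator

Let `s` be a nucleotide source string and `t` the outcome of an i.i.d.
substitution process: each position of `s` is independently changed with
probability `r`, uniformly to one of the three other bases. For a k-mer size
`k`, write `L` for the number of k-mer windows of `s`, `L0` for the number
of distinct k-mers, and `a_i` for the number of distinct k-mers occurring
exactly `i` times (`L0 = Σ a_i`, `L = Σ i·a_i`). Let
`q = 1 − (1−r)^k` be the probability that one window carries at least one
substitution, and `I` the size of the *set* intersection of the k-spectra of
`s` and `t` (multiplicities ignored).

Under two approximations — (i) a k-mer occurrence never mutates into another
spectrum member, and (ii) occurrences of the same k-mer do not overlap — the
survival probability of a k-mer with `occ(τ) = i` occurrences is `1 − q^i`,
so

    E[I] ≈ F(q) = L0 − Σ_i a_i q^i.

The repeat-aware estimator plugs the observed intersection `I_obs` into this
moment equation and solves `F(q̂) = I_obs` for the unique root in `[0, 1]`
(`F` is strictly decreasing), then maps back through
`r̂ = 1 − (1−q̂)^{1/k}`. The repeat-oblivious comparator is the Mash-style
`r_obl = 1 − (I_obs/L)^{1/k}`, which is the same formula when every k-mer is
a singleton and otherwise over-estimates the rate, because
`occ·(1−q) > 1 − q^occ` whenever `occ > 1`: treating a repeated k-mer as
`occ` independent singletons under-predicts the intersection, so the
inversion blames too many mutations. The estimator needs only the abundance
histogram of `s` and `I_obs`, never the multiplicities of `t`.

### Numerical inversion

`solve_q_hat` runs Newton from `q₀ = 0.5`, with the bracket `[lo, hi]`
around the root updated every iteration; any Newton step that would leave
the bracket (or hit a non-negative derivative) is replaced by bisection, so
convergence is guaranteed. Tolerance is `1e-12` on `|F(q̂) − I_obs|`, cap
200 iterations. `I_obs = 0` and `I_obs = L0` short-circuit to the exact
boundary answers `q̂ = 1` and `q̂ = 0` rather than iterating near a possibly
vanishing derivative. `I_obs` is accepted as a real number so that the
sketched plug-in `I_θ/θ` reuses the identical solver.

## Bias and variance bounds

Everything is bounded for `q̂` rather than `r̂` (the monotone map between
them is applied afterwards by the caller if desired). With
`sep(K)` the maximum number of pairwise non-overlapping occurrences of a
k-mer set `K` (start positions ≥ k apart; computed by the greedy sweep,
which is optimal for equal-length intervals):

* **Expectation sandwich.** `LE = Σ_τ (1 − q^sep(τ))` and
  `UE = Σ_τ (1 − q^occ(τ) + β_τ)` with
  `β_τ = min( Σ_{i: s_i ≠ τ} (1−r)^{k−HD(s_i,τ)} (r/3)^{HD(s_i,τ)}, q^sep(τ) )`.
  The Hamming sum is dominated by near-repeat pairs at small distance; the
  `exact` mode evaluates it over all distinct-k-mer pairs weighted by
  occurrence counts (O(L0²k), vectorized row-by-row), the `fast` mode keeps
  only the `q^sep(τ)` cap (valid since β is a min). `exact` auto-switches to
  `fast` above `L0 = 20 000` with a logged warning.

* **Variance.** From the indicator identity
  `Var[I] = (L0−E[I]) − (L0−E[I])² + Σ_{τ≠v} Pr[¬E_τ, ¬E_v]` and the bound
  `Pr[¬E_τ, ¬E_v] ≤ q^sep({τ,v})`:
  `U_Var = Σ_{τ≠v} q^sep({τ,v}) + [(L0−UE) − (L0−UE)²` if `L0−UE ≥ ½`, else
  `¼]`. Since `x − x²` is decreasing beyond ½, substituting the lower bound
  `L0−UE` for `L0−E[I]` is valid exactly in that branch. The ordered double
  sum is computed as twice the unordered sum (the summand is symmetric).

* **Bias bracket.** With `f = F⁻¹` (evaluated by the same solver):
  `E[q̂] ≤ f(LE)` (Jensen, f decreasing concave), and

      E[q̂] ≥ f(UE) − U_Var · ( F″(f(UE)) / (2·F′(f(LE))³) + α ),
      α = max(L0−LE, UE) · max_{x∈(0,1)} (1/6)·(F‴F′ − 3F″²)/(−F′⁵),

  a third-order Taylor expansion of `f` around `E[I]` with the remainder
  bounded through `E|I−E[I]|³ ≤ max(L0−E[I], E[I])·Var[I]`. The inner
  maximand is `f‴/6` expressed through `F`; it is maximized on a 4096-point
  grid over `[1e-6, 1−1e-6]` followed by golden-section refinement around
  the grid argmax (a grid is robust here: the maximand is a smooth rational
  function but root-finding on its derivative would need sign analysis of a
  high-degree polynomial). `α` is clamped at 0 from below — when the
  maximand is everywhere negative the remainder term is non-negative and may
  simply be dropped from a lower bound. The hypothesis `a₁ ≥ 1` guarantees
  `F′(0) = −a₁ ≠ 0`, keeping every quotient finite.

Both endpoints are clamped to `[0, 1]` before reporting, since `q̂` is a
probability: the raw lower bound can leave the unit interval when `U_Var` is
loose (heavily repetitive spectra at small r); the clamp is flagged by the
fact that the reported endpoint sits exactly at 0 or 1.

`UE` may exceed `L0` by the β terms; when evaluating `f` it is clamped to
`L0` (equivalently `f(UE) = 0` there), which only loosens the lower bound.

## Empty-intersection diagnostic

`P_empty(L, k, r)` is the probability that every one of the `L` windows of
an `L+k−1`-position i.i.d. substitution pattern contains at least one
substitution — equivalently, that no run of `k` consecutive positions stays
unmutated. It is computed exactly for this pattern model by a Θ(L·k)
dynamic program whose state is the trailing run length of unmutated
positions (0..k−1); mass reaching run length `k` is discarded. Because the
quantity ignores the repeat structure of `s` (it depends only on `L, k, r`),
it upper-bounds the stability of *any* intersection-based estimator and is
approximately tight for non-repetitive sequences. The implementation's
contract is agreement to `1e-12` with exhaustive enumeration over all
`2^{L+k−1}` patterns on every instance with `L+k−1 ≤ 14`; the DP is the
package's reconstruction from the statement of the claim, and the
enumeration oracle is what defines correctness in the tests. High `P_empty`
(say > 0.99) flags `(k, r)` cells where the estimate will sit at 100%
regardless of the truth; on simulated grids those cells coincide with
relative error at the cap.

## Synthetic sequence generators

Three regimes, mirroring the repetitiveness spectrum of genomic test data.
The defaults are the package's standing study conditions:

* `random` — i.i.d. uniform bases. At `k = 20` and 100 kb, well under 1% of
  k-mers are non-singletons: the repeat-free regime where both estimators
  agree.
* `tandem` — one uniform-random unit (default 545 nt) copied a possibly
  fractional number of times (default derived from `total_length`; the
  final copy is truncated, so 4.2 copies means 4 full copies plus a 20%
  tail), each copy independently mutated at `divergence` (default 2%).
  Interior k-mers occur about once per copy.
* `hor` — an alpha-satellite-like higher-order repeat array:
  `monomers_per_unit` (default 12) monomers of `unit_length` (default
  171 nt), each a `monomer_divergence` (default 20%, typical inter-monomer
  divergence within an alpha-satellite higher-order unit) mutant of a single
  ancestral monomer, concatenated into a higher-order unit that is then
  tandem-copied at `divergence`. Related monomers produce the heavy
  low-Hamming-distance "near-repeat" pair mass, and near-identical
  higher-order copies the heavy multiplicity mass (`L0 ≪ L`), that make
  this the hardest regime. The acceptance script's 100 kb hardest-regime
  analogue uses 0.5% copy divergence, reflecting the near-identity of
  active higher-order repeat arrays; the 20 kb recovery experiments use 2%.

All randomness flows from one root `numpy` `SeedSequence`; replicate `i` of
an experiment spawns child stream `i`, so it is invariant to the total
replicate count.

What the generators do *not* emulate: indels, transition/transversion bias,
phylogenetically correlated divergence between repeat copies (each copy is
mutated independently from its template), sequencing error, and the exact
monomer phylogeny of real centromeric arrays. Passing tests therefore
demonstrate correctness of the estimator and bounds under the substitution
model and robustness to repeat structure of the modeled kinds — not
performance under indels or on real reads.

## Experiment harness

`run_replicates` reports the repeat-aware and repeat-oblivious estimates
side by side for `n` independent mutation replicates; `error_grid` maps the
mean relative absolute error `(1/n) Σ |r̂_i − r| / r` over a `(k, r)` grid,
capped at 1.0, refusing `r = 0` cells where the quantity is undefined.

## Sketching

A FracMinHash sketch keeps the k-mers whose seeded 64-bit hash
(`blake2b` keyed with the seed, truncated to 8 bytes), normalized by `2⁶⁴`,
falls below `θ`. Sketches store sorted hash values; intersection requires
identical `(k, θ, seed)`. `E[I_θ] = θ·I` over the hashing process, so the
estimator is applied to `I_θ/θ`; if that exceeds `L0` (possible at very low
rates) the estimate is hard-coded to 0. Sketching adds variance but no
systematic bias; variance shrinks as `θ` grows.

## Problem sizes and tolerances

Simulation experiments in the tests and the acceptance script use sources of
2–100 kb, 50–500 replicates, and the exact-β bound mode on spectra up to a
few thousand distinct k-mers; these sizes give Monte-Carlo standard errors
small enough for 3·SE containment checks while keeping every run desk-scale.
Stochastic checks use a 3-standard-error band throughout; algebraic
identities are checked to 1e-9–1e-12; the `r ↔ q` round trip is validated
where `(1−r)^k` stays well above the double-precision rounding floor (beyond
it `q` rounds to 1 and no inverse map can recover `r`).

## Known limitations

* Confidence intervals are out of scope; the bracket bounds the *mean* of
  `q̂`, not its distribution.
* The variance bound `U_Var` is loose on heavily repetitive spectra at small
  r, which can push the raw bias lower bound out of `[0, 1]` (hence the
  clamp).
* The exact-β mode is quadratic in `L0`; above 20 000 distinct k-mers the
  fast mode is used automatically.
* Reverse-complement canonicalization is off by default (the model treats
  strings literally); a `canonical` flag exists on spectrum construction for
  users comparing assembled genomes of unknown strandedness.
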