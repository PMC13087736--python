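# subrate

**Repeat-aware estimation of the substitution rate between two sequences
from their k-mer spectra.**

K-mer set comparison is the workhorse of alignment-free sequence analysis:
given a source sequence *s* and a copy *t* that diverged from it by point
substitutions at per-base rate *r*, the number of k-mers the two sequences
share carries enough signal to estimate *r* without an alignment. The
classical Mash-style estimator

&nbsp;&nbsp;&nbsp;&nbsp;*r*<sub>obl</sub> = 1 − (*I*/*L*)<sup>1/k</sup>

(*I* shared k-mers, *L* k-mer windows) is derived under the assumption that
*s* has no repeats. On repetitive sequences — tandem repeats, and most
dramatically the alpha-satellite higher-order repeat (HOR) arrays of
centromeres — that assumption fails badly and *r*<sub>obl</sub> can be off
by an order of magnitude.

`subrate` implements a repeat-aware estimator. With *a<sub>i</sub>* the
abundance histogram of *s* (number of distinct k-mers occurring exactly *i*
times, so *L*<sub>0</sub> = Σ*a<sub>i</sub>* distinct k-mers) and
*q* = 1 − (1 − *r*)<sup>k</sup> the probability that a k-mer window carries
at least one substitution, the expected spectrum intersection is
approximately

&nbsp;&nbsp;&nbsp;&nbsp;E[*I*] ≈ ℱ(*q*) = *L*<sub>0</sub> − Σ<sub>i</sub> *a<sub>i</sub>* *q*<sup>i</sup>,

because a k-mer with *i* occurrences survives unless all *i* copies are
hit. The estimator solves ℱ(*q̂*) = *I*<sub>obs</sub> by safeguarded Newton
iteration and reports *r̂* = 1 − (1 − *q̂*)<sup>1/k</sup>. It needs only the
abundance histogram of the source and the observed intersection size — not
the k-mer multiplicities of *t*.

Around the estimator the package provides:

* **provable bias and variance bounds** — an expectation sandwich
  LE ≤ E[*I*] ≤ UE from separated-occurrence counts and Hamming-distance
  "near-repeat" terms, a variance upper bound U<sub>Var</sub>, and a
  computable bracket on E[*q̂*], so a user can decide *a priori* whether to
  trust the estimate on a given source sequence;
* **an instability diagnostic** — P<sub>empty</sub>(L, k, r), the
  probability that every window is hit (empty intersection, where any
  intersection-based estimator collapses to 100%), computed by an exact
  Θ(L·k) dynamic program;
* **FracMinHash sketching** — the same estimator applied to the scaled
  sketched intersection I<sub>θ</sub>/θ, trading variance for sketch size;
* **a simulation laboratory** — seeded substitution-process replicates and
  synthetic sequence generators (uniform random, tandem simple repeats,
  alpha-satellite-like HOR arrays) spanning the repetitiveness spectrum.

See `docs/methods.md` for the model, the bound derivations as implemented,
and the generators' scope.

## Worked example

```python
import subrate as sr

# source: alpha-satellite-like higher-order repeat array, 20 kb
source = sr.generate(sr.RepeatSpec(kind="hor", total_length=20_000,
                                   unit_length=171, divergence=0.02, seed=7))
mutated = sr.mutate(source, r=0.01, seed=8)

k = 21
spec_s = sr.build_spectrum(source, k)
spec_t = sr.build_spectrum(mutated, k)
hist = sr.abundance_histogram(spec_s)
I_obs = sr.intersection_size(spec_s, spec_t)

result = sr.estimate_r(hist, float(I_obs))
r_obl = sr.r_oblivious(I_obs, hist.L, k)
print(f"L = {hist.L}, L0 = {hist.L0}, I_obs = {I_obs}")
print(f"repeat-aware     r_hat = {result.r_hat:.4f}")
print(f"repeat-oblivious r_obl = {r_obl:.4f}")
```

prints

```
L = 19980, L0 = 8660, I_obs = 7573
repeat-aware     r_hat = 0.0087
repeat-oblivious r_obl = 0.0451
```

The true rate is 0.01: the repeat-aware estimate lands within 13% of it on a
single replicate, while the repeat-oblivious estimator reads 4.5× too high —
it interprets every one of the ~11,000 redundant k-mer occurrences lost to
repetition as evidence of mutation. Averaged over 100 replicates
(`sr.run_replicates(source, 21, 0.01, 100, seed)`) the repeat-aware mean
settles within a few percent of the truth.

The bias bracket and the stability diagnostic for the same source:

```python
tandem = sr.generate(sr.RepeatSpec(kind="tandem", total_length=2290,
                                   unit_length=545, copy_number=4.2,
                                   divergence=0.02, seed=3))
rep = sr.bias_bounds_q(sr.build_spectrum(tandem, 10), r=0.01, mode="exact")
print(f"E[q_hat] in [{rep.Eq_lower:.4f}, {rep.Eq_upper:.4f}]"
      f"  (true q = {sr.r_to_q(0.01, 10):.4f})")

from subrate.pempty import PemptyQuery
print(f"P_empty(k=21, r=0.30) = {sr.p_empty_dp(PemptyQuery(19980, 21, 0.30)):.3f}")
```

```
E[q_hat] in [0.0801, 0.0956]  (true q = 0.0956)
P_empty(k=21, r=0.30) = 0.035
```

The bracket pins the estimator's mean to within a few percent of the true
window-mutation probability, and P<sub>empty</sub> says that at r = 30% and
k = 21 this source still has a 96.5% chance of a non-empty intersection —
the estimate is not yet in the unstable regime.

The same operations are available from the shell:

```bash
subrate estimate --source s.fa --mutated t.fa -k 21
subrate bounds --source s.fa -k 20 --r-grid 0.001:0.33:40 --mode exact
subrate pempty -L 100000 -k 30 --r-grid 0.01:0.40:40
subrate simulate --spec hor --length 20000 -k 21 -r 0.01 -n 100 --seed 1
subrate sketch-estimate --source s.fa --mutated t.fa -k 21 --theta 0.1
```

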