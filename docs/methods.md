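# Methods

## The sketch model

A FracMinHash sketch of a k-mer set A is the set of hash values of A's
members that fall at or below a fixed fraction of the hash range:

    FRAC_s(A) = { h(a) : a ∈ A, h(a) ≤ ⌊s·H⌋ },    H = 2⁶⁴,  0 ≤ s ≤ 1.

Unlike classical MinHash, the sketch size is not fixed: it scales with the
input, E[X_A] = s·|A| where X_A = |FRAC_s(A)|. All estimation theory in this
package treats membership of each element in the sketch as an independent
Bernoulli(s) event, which is exact for a hash function drawn from a strongly
2-universal family. In practice the hash is MurmurHash3 (x64_128 variant,
first 64-bit word, seed 42, applied to the uppercase ASCII bytes of the
canonical k-mer) — the convention shared by sourmash and frac-kmc, so that
sketches are interchangeable between tools. MurmurHash3 carries no
universality guarantee; the test suite checks empirical uniformity
(chi-square over 100 bins at significance 0.01) and the Monte-Carlo
experiments confirm that the theory's predictions hold through the real
hash path.

Canonical form is the lexicographic minimum of a k-mer and its reverse
complement; windows containing any character outside {A,C,G,T} are skipped,
not substituted. Sketches are sets — abundances are not tracked.

### Boundary convention

The acceptance rule is the inclusive `v ≤ ⌊s·H⌋`, taken literally from the
sketch definition. Writers using a strict `<` differ only on a single
measure-zero boundary value; the signature reader compares hash sets, so
either convention loads identically.

## Estimators

All supported measures (Jaccard, containment, cosine/Otsuka–Ochiai,
Kulczynski-1/2, Whittaker, Sorensen, Bray–Curtis) are ratios of the three
cardinalities |A|, |B|, |A∩B|. The **plug-in estimator** substitutes the
sketch cardinalities X_A, X_B, X_{A∩B}. The plug-in Jaccard and containment
are biased low by the factor 1 − (1−s)ⁿ (n = |A∪B|, resp. |A|): the
**corrected estimator** divides by that factor, with the convention 0/0 = 0
for empty-denominator sketches (under which the correction is exactly
unbiased — verified by the Monte-Carlo harness). Kulczynski-2 is the mean of
the two corrected containments and the Whittaker distance its complement.
The factor is computed as `-1/expm1(n·log1p(−s))`, which is accurate for
the tiny s and huge n of genomic practice. Corrections use the exact source
cardinality recorded at sketch time when available, otherwise the X/s
estimate (logged).

No unbiased estimator is known for cosine, Kulczynski-1, Sorensen or
Bray–Curtis. For these the package provides probability lower bounds derived
from Chernoff concentration of the sketch size:

    Pr[|X_A − s|A|| ≥ ε·s|A|] ≤ 2·exp(−s|A|ε²/3)

propagated through the ratio gives, for cosine (and identically Sorensen and
Bray–Curtis),

    Pr[|cosθ′ − cosθ| ≤ ε·cosθ] ≥ 1 − 6·exp(−s|A∩B|ε² / [3(2+ε)²]),

and for Kulczynski-1 the same with coefficient 4 and min{|A∩B|, |AΔB|}.
Raw bounds can be negative when s·|A∩B| is small; they are clamped to 0
(the guarantee is then vacuous, as it must be: for nearly-disjoint sets a
near-zero estimate already reports the dissimilarity, but no multiplicative
guarantee is possible).

## Recommended scale factor

Inverting the cosine bound for a tolerable relative error ε and confidence
α gives the minimum safe scale factor

    s ≥ 3(2+ε)² ln[6/(1−α)] / (ε² · m),   capped at 1,

with m = min{|A|,|B|} by default (the sharper m = min{|A|,|B|,|A∩B|} is
available as an option; it is not the default because the intersection size
is rarely known in advance, and for highly dissimilar pairs the plug-in
estimate is already informative). The (2+ε)² factor carries the ε↔δ
substitution from the proof of the bound, so the "tolerable error" of the
rendered tables is passed directly as ε — this reproduces all reference
table cells to the four printed decimals. Table rendering rounds half-up to
4 decimals.

One published worked example claims a minimum scale factor of 0.0005 for
sets of ~4.8M k-mers at ε = 0.1, α = 0.95; direct evaluation of the formula
gives ≈ 1.3 × 10⁻³. The formula is implemented as printed; the discrepancy
in that prose example is left unresolved.

## Simulation harness

The Monte-Carlo harness draws a universe of N integers (default 1M), per
trial samples two uniform random subsets without replacement, computes the
true cosine from the full sets and the plug-in cosine from sketches, and
reports per size-pair the fraction of repetitions with
|est − true| ≤ ε·true. Two element modes exist:

* `hashed` (default): elements are 8-byte little-endian integers run
  through the real MurmurHash3 path (vectorised), so the full stack is
  exercised;
* `uniform`: each trial draws a fresh idealized hash function (i.i.d.
  uniform 64-bit values), matching the theory's assumption of a hash drawn
  from a strongly universal family.

The two modes give statistically indistinguishable coverage, which is
itself evidence that MurmurHash3 behaves uniformly enough here. Trials with
an empty sampled intersection have true cosine 0; they are counted as
"within tolerance" exactly when the estimate is also 0, and their count is
reported per cell. Every trial derives its generator from the tuple
(seed, cell index, trial index), so results replay exactly and any cell can
be recomputed independently.

The unbiasedness experiment fixes one sampled set pair (so the true value is
known by construction) and takes the Monte-Carlo expectation over fresh
idealized hash functions — the expectation in which the corrected estimators
are unbiased. The concentration experiment draws sketch sizes the same way
and compares tail frequencies against the Chernoff bound.

What the synthetic universes do **not** emulate: k-mer composition bias,
sequencing errors (which inject spurious k-mers), shared-substring structure
between related genomes, or abundance information. Passing tests show that
the estimators and bounds behave as derived for random sets under the stated
hash model; accuracy on real genomic data additionally depends on those
unmodelled features only through the sizes |A|, |B|, |A∩B|, which is exactly
the model's claim.

## Problem sizes and numerical choices

Default experiment sizes follow the reference conditions: universe 1M, set
sizes 100K–500K, 1000 repetitions per coverage cell, 2000 repetitions for
unbiasedness, 5000 for concentration. The bias-demonstration configuration
uses 150-element sets in a 220-element universe at s = 0.005, chosen so the
bias factor 1 − (1−s)^|A∪B| ≈ 0.6 is far from 1 and the effect is
unmistakable against Monte-Carlo noise. A `--fast` style scaled-down run
(e.g. 200 repetitions) is available through the CLI's `--reps` flag.

Coverage comparisons against the reference experiment grid use tolerance
bands of 3 standard errors on the *difference* of two independent 1000-rep
binomial fractions (plus printed rounding), fixed in advance of
measurement. One reference cell (100K×100K at s = 0.001, printed 0.09) sits
below what both this harness (0.125 ± 0.010) and an independent
hypergeometric/binomial distributional model (0.135, 200K draws, no sketch
code) compute for those conditions; the implementation follows the model,
and the band absorbs the difference.

Other numerical conventions: probability bounds clamp to [0,1]; ε is
restricted to (0,1); α = 1 is rejected (no finite scale factor gives
certainty); s = 0 sketches are empty and cardinality estimation and bias
correction are undefined there; Kulczynski-1 of identical sets is reported
as +inf (serialised as the literal `inf` in matrices) rather than an error,
so pairwise matrices remain writable; empty-sketch denominators on the
sketch path return similarity 0 with a warning, while on the exact-set path
they raise, since there the value is truly undefined.

## Known limitations

* Hash collisions are ignored: the sketch of A∩B is identified with the
  intersection of the two sketches. At 64 bits and desk-scale inputs the
  collision probability is negligible, but it is a model approximation.
* Protein k-mers, abundance-weighted (multiset) sketches, and
  Chord/Hellinger/Jensen–Shannon distances are out of scope.
* The scale recommendation targets the cosine-family bound; metrics with
  unbiased estimators need no scale recommendation, and none is offered.
* Sketching large files is pure Python over Biopython parsing — correct and
  adequate for desk-scale inputs, but not engineered for multi-GB FASTQ
  throughput.
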