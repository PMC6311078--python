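# Methods

## Model and inference procedure

The package infers direct residue–residue couplings from an MSA under a
maximum-entropy Potts model with three-body terms.  The pipeline is:

1. **Read & filter.**  Aligned FASTA is normalized (`.` → `-`; the
   ambiguity codes B, J, O, U, X, Z → gap), sequences whose gap fraction
   *strictly exceeds* `max_gap` are dropped, and the alphabet is shrunk
   to the symbols actually present (canonical order: the 20 amino acids
   alphabetically by one-letter code, then the gap).  Whether the
   gap-fraction rule should be strict or non-strict is not decidable
   from first principles; we use strict inequality, so a sequence
   exactly at the threshold is kept.
2. **Reweighting.**  w_b = 1/|{a : d_H(a,b)/N ≤ θ}|, with gaps counted
   as ordinary states in the Hamming distance; B_eff = Σ w_b.
3. **Frequencies.**  One-, two- and (reduced-alphabet) three-point
   tensors with pseudocount mass λ_c = `pseudocount` · B_eff spread as
   λ_c/q, λ_c/q², λ_c/q³ per state tuple.  This uniform-by-order
   pattern is exactly what makes the marginalization chain
   Σ_γ f³ = f², Σ_β f² = f¹, Σ_α f¹ = 1 hold with pseudocounts active
   (asserted to 1e-12 in the tests).  Reduced tensors are class sums
   over the map μ; the triplet pseudocount in reduced space therefore
   carries the class-size multiplicity |μ⁻¹(α)||μ⁻¹(β)||μ⁻¹(γ)|.
4. **Covariance & inversion.**  The connected two-point covariance is
   built over the truncated state range 1..q−1 and inverted as one
   dense N(q−1)-dimensional symmetric system (blockwise inversion would
   be wrong).  Same for the reduced alphabet.
5. **Three-body correction.**  The connected three-point covariance
   e³ᵣₑₔ (truncated reduced states) is contracted with three copies of
   the reduced inverse to give g³ᵣₑₔ, whose (k, n)-sum against f_k(n)
   corrects the pairwise couplings.  The position sums of the inverse
   relation run over *all* sites, self-terms included; repeated-position
   entries of the frequency/covariance tensors are defined by
   delta-collapse (see below).
6. **Gauge, norm, APC.**  Couplings (augmented by the class-averaged,
   k-summed three-body terms V = −g³ᵣₑₔ lifted through μ and divided by
   q_red) are double-centered per (i,j) block, which enforces the
   zero-sum identity exactly.  Frobenius norms — gap state included by
   default, dropped with `ignore_last` — are APC-corrected and reported
   for pairs j ≥ i+2, 1-based.

## Conventions for diagonal and repeated indices

Two-point frequencies at i = j are defined as f_ii(l,m) = δ_lm f_i(l)
rather than by the generic pair formula; this is the standard mean-field
DCA convention and the one under which the pseudocount-dominated
covariance has the closed-form diagonal blocks (1/q)(δ_lm − 1/q) and is
positive definite.  Triplet entries with repeated positions collapse
analogously (f³[i,i,k] = δ_αβ f²[i,k], f³[i,i,i] = δ_αβ δ_βγ f¹[i]).
Consequently the connected three-point covariance vanishes for
independent columns at all genuinely three-position entries, but the
i = j = k diagonal retains the (nonzero) third cumulant of a single
site — an unavoidable property of the exact connected-covariance
formula, and the reason the independence test exempts that diagonal.

States involving the last (truncated) symbol get zero couplings before
the gauge step; correspondingly, three-body inverse entries whose class
argument is the dropped reduced class are taken as zero.  Full states
whose class is the dropped class simply receive no three-body
correction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap` | 0.9 | drop sequences with gap fraction > 0.9 |
| `theta` | 0.2 | Hamming-fraction similarity threshold for reweighting |
| `pseudocount` | 4.0 | λ_c = pseudocount · B_eff; large values are safe (they shrink toward uniform) and guarantee invertibility |
| `workers` | 1 | threads for the triplet-frequency loop; results are bit-identical for any count |
| `ignore_last` | false | exclude the gap state from the Frobenius norm (with reduced alphabets, gap contributions mix into residue classes, so they are kept by default) |
| `map` / `map-row` | none / 1 | reduction-map CSV and 1-based row; no map ⇒ identity reduction |

The map file convention (21 columns in canonical symbol order, positive
integer labels, one candidate mapping per row) is this package's own
choice; classes that become empty after alphabet shrinkage are compacted
away in first-appearance order.

## Determinism

Results are reproducible to the bit: frequency accumulation runs in a
canonical (lexicographic) sequence order and B_eff is summed in
sorted-value order, so permuting the input sequences changes nothing;
the triplet-frequency workers write disjoint output slices computed with
identical summation order, so the worker count changes nothing; all
einsum contractions use fixed paths.

## Synthetic generator

`make_model` plants sparse pairwise (and optionally three-body)
interaction tables, drawn zero-mean (each table centered along every
axis) so the zero-sum gauge is exercised nontrivially, with every
planted index tuple separated by ≥ 2 positions so all planted edges are
scoreable.  `sample_msa` draws sequences by single-site Metropolis
updates in systematic sweeps with burn-in and thinning; proposals are
uniform over all q states (including the current one) — a flip-only
proposal would be accepted deterministically at field-free binary sites
and make the chain periodic.  The sampler is validated against exact
Boltzmann enumeration (N=4, q=2) by χ² goodness of fit.

Defaults for the recovery experiment (N=20, q=4, 12 planted pairs,
B=2000, θ=0.2, pseudocount 4.0) represent a moderately sized protein
family; `coupling_strength=1.0` was fixed once in a pilot as the middle
of the regime where recovery is reliable but not saturated at tiny B.
What the generator does *not* emulate: phylogenetic descent (sequences
are thinned samples of one chain, not a tree), gap structure (synthetic
alignments are gap-free), and alignment error.  A green recovery test
therefore establishes correctness of the inference chain on
well-specified data, not robustness to real-MSA artifacts such as the
correlated gap-padded termini that the `gap_gap_frequencies` diagnostic
is provided to reveal.

## Numerical choices and limitations

- Covariance matrices are symmetrized (0.5·(E+Eᵀ)) before inversion;
  singular or non-finite inversions raise an error advising a larger
  pseudocount.
- The three-point tensor is stored only on the strict wedge i<j<k
  (six-fold memory saving); a configurable memory cap (default 2 GiB)
  refuses configurations whose triplet tensors would not fit.
- The einsum chain for the three-body contraction costs O(N⁴ q_red³)
  time and O(N² q_red²) extra memory; it never materializes the
  six-index g³ᵣₑₔ.  For alignments of several hundred positions this
  quartic term dominates; reduce q_red (e.g. a 4-class polarity-style
  map) for long proteins.
- With q_red = 1 the correction vanishes identically and the pipeline
  reduces to plain mean-field DCA; this limit is checked against an
  independently coded mfDCA to 1e-10.
- APC divides by the mean raw score; an all-zero score matrix skips the
  correction with a warning instead of dividing by zero.
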