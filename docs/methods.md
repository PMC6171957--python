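# Methods

## Scope and model

`compscan` characterizes a proteome by *local compositional enrichment*
rather than by a binary low-complexity call. The unit of analysis is the
triple (amino acid of interest, window size, composition bin): every protein
long enough for a window size is assigned, per residue, the maximum count of
that residue over all contiguous windows, and binned by the corresponding
maximum percent composition. All downstream statistics are run on these
partitions. The pipeline makes no assumption about what generated the
sequences; the statistical machinery assumes only exchangeability under the
null (rank tests, exact tests on 2×2 tables).

## Scanning and binning

- Window sizes default to 10–100 in steps of 10; bins are 5% wide; all 20
  canonical residues are scanned (20 × 10 = 200 partitions of the proteome).
- The stored statistic is the exact integer pair (max count, window).
  The bin label is `bin_width · ⌊100·count / (bin_width·window)⌋`; the label
  space is {0, 5, …, 100} with 100 attained only by a saturated window.
  The half-open-interval convention at bin edges is a deliberate choice —
  integer arithmetic makes binning exact and re-runs byte-identical.
- Maximum composition is **not monotone** in window size ("AGA" for A:
  100%, 50%, 66.7% at windows 1, 2, 3), so each window size is scanned
  independently; no shortcut across window sizes is valid, and the test
  suite pins this counter-example.
- Proteins shorter than a window are excluded from that window's partition
  (figures-style comparisons are always against "all proteins of length ≥
  the window size").
- Unknown residues (anything outside the 20 canonical symbols maps to `X`
  on read) occupy window positions but never count toward a target residue,
  and never form or extend homopolymer runs. This is conservative: unknowns
  can only dilute, never inflate, enrichment.

## Domain classifiers

**Low-complexity windows.** Shannon entropy of every 12-mer,
`SE = −Σ (nᵢ/L) log₂(nᵢ/L)` with L = 12, called at SE ≤ 2.2 bits — the
first-pass criterion of the SEG algorithm. Only this first pass is
implemented; SEG's later boundary extension/refinement is out of scope.
Each call is assigned to every residue whose count ties the window maximum
(`n_AAoI ≥ n_max`), so a 6A/6G window is both an A-call and a G-call. A
protein is "SEG-positive for X" if any of its calls assigns X.

**Statistical bias.** Per protein, the minimum over residues, window sizes
w ∈ [25, min(2500, length)] (step 1 — exhaustive; a coarser step exists as
an optimization toggle, off by default) and window positions of the
binomial point mass `C(w,n)·f^n·(1−f)^(w−n)`, where f is the residue's
frequency computed from the analyzed proteome itself (overridable by file).
The scan is vectorized: per window size, rolling counts for all residues
come from a cumulative one-hot sum, and log-probabilities from a
precomputed log-factorial table, so nothing combinatorial is recomputed per
position. Threshold calibration: OLS slope of log₁₀P_min on log₁₀length;
the intercept is set to the (⌊0.15·n⌋+1)-th smallest residual, which makes
the strictly-below-line count the largest value ≤ ⌊0.15·n⌋ (maximality is
asserted in tests); the length-independent cap p_abs is the type-1 lower
0.15-quantile of the P_min values (the value at 1-based index ⌈0.15·n⌉ of
the sorted list — no convention is canonical here, so this one is stated
explicitly). A protein is biased iff P_min is *strictly* below
min(line(length), p_abs). Because both pieces use strict inequality, the
classified fraction can fall slightly under 15%, never over.

**Homopolymers.** Maximal runs of ≥ 5 identical canonical residues.

**CED sets.** For each residue X, every (window, bin) cell in which ≥ 75%
of the occupants are SEG-positive for X is pooled; the union over all
windows and bins is the X-CED set. Pooling spans all window sizes and all
bins — qualification is driven entirely by the 75% occupancy rule, with no
extra composition floor. Single-CED sets remove any protein present in ≥ 2
residues' CED sets and are therefore pairwise disjoint by construction.

## Translation efficiency

Whole-gene efficiency is the geometric mean of per-codon weights,
`(Π w_k)^(1/l)`, computed in log space; stop codons (TAA, TAG, TGA) are
excluded from both the product and the codon count l. The per-codon weight
scale itself (tRNA gene copy numbers, wobble efficiency, codon usage) is an
*input table*, not re-derived here. Internal stop codons are excluded like
terminal ones and surfaced as anomalies rather than errors, since real ORF
collections contain them. Useful invariants (all tested): permutation
invariance, scale equivariance (weights ×k ⇒ values ×k), and min ≤ value ≤
max over counted weights.

## Statistics

**Bin-vs-rest.** Two-sided Mann-Whitney U with midranks, tie-corrected
variance and continuity correction (the standard asymptotic routine; the
exact enumeration test exists in the suite only as an oracle for small n).
For each (residue, window, nonempty bin), in-group = bin ∩ property
coverage, out-group = (eligible ∩ coverage) \ bin; rows are emitted only
when both groups are nonempty (minimum group size 1 by default — tiny bins
are reported, not suppressed; a min-n filter is available). Bonferroni
families are the rows emitted per (residue, window) pair by default,
matching a per-residue-panel presentation; a per-window family pooling all
residues is available as an option. Direction is the sign of the median
difference at adjusted p ≤ α.

**Threshold scan.** For thresholds t ∈ {0, 5, …, 100}, the pool is every
eligible protein with `100·count ≥ t·window` (exact integers), giving pools
that shrink weakly as t rises; each pool is tested against the target set
with one-sided (greater) Fisher's exact test over the length-eligible
background. Uncorrected p-values are the default reporting convention for
composition-profile scans (isolated significant points should be read with
skepticism; consecutive runs of them are the signal); Bonferroni within
window is available for compartment-style analyses. Per-term annotation
enrichment uses the same Fisher machinery with Bonferroni across terms, and
significant terms can be pooled across window sizes into a non-redundant
list.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical structure* the analysis assumes:

- background residues drawn i.i.d. from a yeast-like frequency table
  (bundled; a uniform option exists — the table is a realistic default, not
  a claim about any particular proteome release);
- a fraction π of proteins carries one planted domain of length d in which
  each position is the target residue with probability ρ (probabilistic
  planting makes realized compositions straddle bin edges, exercising the
  exact binning);
- per-protein property values are log-normal,
  `value = exp(μ + β·1[enriched] + ε)`, ε ~ N(0, σ²), where "enriched"
  means the realized domain composition reaches τ; β defaults to +log 2
  for A/G/V and −log 2 for the other residues, mirroring the direction
  pattern reported for translation efficiency, abundance and half-life in
  yeast;
- membership sets include enriched proteins with probability = sensitivity
  (default 0.8) and others with probability = 1 − specificity (default
  0.99).

Default study conditions: n = 2000 proteins, lengths uniform on [50, 400]
(chosen so the d = 30 domain fits every protein and window sizes up to 100
have substantial eligible sets), π = 0.1, ρ = 0.5, d = 30, |β| = log 2,
σ = 0.5, τ = 0.35 (a composition below the classical-domain regime, chosen
once to encode the premise that property effects begin before classical
thresholds). All three generators are deterministic functions of the seed;
the property and membership streams are derived (seed+1, seed+2) so adding
one output never perturbs another.

What it does **not** emulate: positional autocorrelation beyond the single
planted domain, multiple domains per protein, co-enrichment of several
residues, length-composition coupling, codon-level sequence structure (the
translation-efficiency tests use hand-built fixtures), or annotation-term
hierarchies. Passing tests therefore demonstrate the machinery recovers
planted effects under the stated model — not that real proteomes satisfy
that model.

## Interpreting bin-vs-rest signs on planted data

With a single planted residue, significant *opposite-direction* calls
appear in low/mid-composition bins at small windows: those bins hold almost
exclusively unplanted proteins, so their out-groups contain the planted
(shifted) ones, and the complement's median moves instead. This is a
property of the bin-vs-rest design, not a sign error. Sign-recovery checks
are therefore evaluated on bins at or above the planted target composition
ρ, where the planted proteins actually reside; the suite also asserts that
no significant call in that region ever carries the wrong sign.

## Numerical choices

- All composition comparisons are integer-exact; no float ever decides a
  bin or a pool.
- Binomial point masses and geometric means are computed in log space;
  normalization Σₙ P(w,n,f) = 1 is asserted to 1e-9.
- Strict `<` defines "below" for both bias thresholds; ties at a threshold
  are not biased.
- Degenerate inputs: empty proteomes, empty property tables, all-stop
  genes, and all-equal-length bias fits raise; short sequences yield empty
  call lists or absent results, never errors.
- Mann-Whitney uses the asymptotic approximation uniformly, including for
  tiny bins (n = 1 groups are testable); agreement with exact enumeration
  is within 0.03 for group sizes ≤ 8 (tested).

## Problem sizes

The test suite and the reproduction script run the synthetic study at
n = 2000 proteins with the planted residue's partition, ten seeds for the
recovery rates, 2000 replicates for the null calibration, and n = 300
proteins (lengths 50–250) for the exhaustive bias scan — sizes at which the
whole suite completes in well under a minute while every code path,
including the exhaustive w = 25…2500 scan logic, is exercised.

## Known limitations

- The bias scan is O(Σ_w (L−w) · 20) per protein; for proteomes of
  multi-thousand-residue proteins a coarser window step is available but
  changes results and is off by default.
- CED pooling uses all bins, including bin 0; in practice bin-0 cells never
  reach 75% SEG-positivity for a residue, but pathological inputs (e.g. a
  proteome that is one homopolymer family) can make CED sets large.
- Fisher's two-sided convention follows the standard sum-of-≤-likely-tables
  definition; other conventions exist and differ in edge cases.
- The per-codon weight table is trusted as given; no wobble or usage model
  is fit here.
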