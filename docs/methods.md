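# Methods

This note records the model, the numerical choices, and the design decisions
behind `hmmstitch`, at the level of detail a maintainer or a careful user
needs. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

The aligner treats multiple sequence alignment as *extension*: a high-quality
alignment and unrooted tree on a full-length backbone define a fixed column
space, and every remaining sequence is placed into that space independently.
Placement never revises the backbone, which is why the final alignment error
is expected to track the backbone's own error — a property the acceptance
study measures directly rather than assumes.

### Backbone selection

Sequences within `length_tolerance` (default 0.25) of the typical length are
eligible. The typical length is the median input length unless the user
declares the locus length (`typical_length`). If more than `backbone_size`
sequences are eligible, a uniform random sample (seeded) is drawn; if fewer,
all eligible sequences are used and the quota is deliberately *not* filled
with out-of-window sequences, preserving the full-length guarantee. With the
restriction disabled every sequence is eligible (a variant useful only for
studying why the restriction matters).

A caveat found during testing: when exactly half the input is fragmentary at
half the typical length, the *median* falls into the gap between the two
length modes and the 25 % window can be empty or, worse, admit fragments.
The method's own rule covers this — declare the locus length when it is
known — and the simulated studies do exactly that (the simulation's root
length is the locus length). `select_backbone` raises an actionable error
when the window is empty rather than guessing.

### Built-in backbone estimator (stand-in)

Backbone quality drives final quality, so the interface accepts an external
backbone alignment and tree (`-a`/`-t`), validated and passed through
unchanged. The built-in estimator exists so the pipeline is self-contained:

* guide tree: neighbor joining (scikit-bio) on one-minus-shared-k-mer-fraction
  distances (k = 5 nucleotide, k = 3 amino acid);
* progressive profile–profile alignment along the guide tree: global
  Needleman–Wunsch/Gotoh on column frequency profiles with score
  +1 match / −1 mismatch, gap open 3, gap extend 1 — arbitrary but fixed;
  profile columns weight residues by frequency (gaps and ambiguity codes
  carry no mass);
* returned tree: neighbor joining on normalized Hamming distances (gapless
  column pairs only) of the final alignment.

The Gotoh horizontal-gap state is evaluated with a running-maximum trick that
is exact whenever `gap_open >= gap_extend` (re-opening a gap can then never
beat extending it). Traceback prefers substitution over vertical over
horizontal moves at ties.

### Profile HMMs

One match state per column containing at least one residue (the
`--symfrac 0.0` convention); all-gap columns within a subset are dropped and
`column_map` records each match state's backbone column, which is what makes
transitive placement trivial.

Estimation is add-α (Laplace, `pseudocount`, default 1.0) on residue counts
and on the M/D transition paths implied by each row, with uniform sequence
weights. Two consequences worth knowing:

* under the all-columns match rule, training rows contain no insert states,
  so insert emissions and insert-involving transitions are pure pseudocount
  (uniform). Insert emissions over a size-A alphabet are 1/A;
* insert transitions therefore cost roughly `log2(n)+log2(3)` bits for an
  n-row subset, which is much harsher than HMMER's Dirichlet-prior defaults.
  Viterbi paths consequently prefer a local early exit over paying for an
  insertion unless the flanking match signal is strong; the tests
  demonstrate both regimes. This is a deliberate simplification: Dirichlet
  mixtures and entropy weighting are out of scope, and the pseudocount is
  configurable.

The null model is the (pseudocounted) residue frequency of the backbone
alignment; the ensemble builder passes the *full* backbone's frequencies to
every subset HMM so that bit scores are comparable across the ensemble.

Architecture: simplified Plan7, uni-hit local. Paths are
`flank* → entry → M_b → core(M/I/D) → M_e → exit → flank*` with uniform entry
probability 1/K over match states, unit exit weight, and flanking residues
emitted at null frequency (net log-odds zero). Uni-hit suffices because each
query is placed exactly once and scoring is run unfiltered (no E-value or
bit-score threshold). The exact local-entry distribution used by HMMER is
not public in this form; uniform entry is the documented choice.

### Scoring numerics

The Forward bit score `log2 Σ_paths P(path, q) / P_null(q)` is computed in
probability (odds) space with lazy per-row rescaling: lattice rows are
divided by their maximum whenever it leaves `[1e-100, 1e100]` and the applied
factor is accumulated in log2. This is exact up to float rounding, avoids
transcendental calls in the inner loop (the kernel is numba-compiled), and
cannot underflow for queries up to 10^4 residues. Per-row exit masses are
combined with `logaddexp2` at the end. Viterbi runs in log2 space with a
prefix-maximum evaluation of the within-row delete chain; traceback
re-derives each argmax with tolerance 1e-9 and breaks ties preferring
M over D over I (maximising residues in match columns), with fresh local
entry considered last. Both routines are checked against an explicit
enumerate-all-paths oracle to 1e-9 bits on ≥ 200 random models per run.

### Decomposition and placement

The centroid edge minimises the larger side of the split; ties are broken by
the lexicographically least leaf label on the smaller side (then by the full
sorted smaller side), making the decomposition reproducible. Recursion
operates on the induced subtree (degree-2 nodes suppressed; branch lengths
kept but unused) until subsets have at most `subset_max` (default 10)
leaves. `hierarchical` keeps every level including the full set (the
default), `none` keeps only the full-set HMM, `disjoint` only the leaf
subsets. Clade-based ensembles are a non-goal (equal-or-worse accuracy at
higher cost).

Ties in bit score go to the lowest subset id, i.e. the full-set model first.
Insert- and flank-emitted residues map to the insertion slot adjacent to the
nearest matched backbone column (left flank: before the first matched
column). Adjacent insertion sites are combined into one minimal block per
slot — a single column cannot hold two residues of one sequence — sized by
the maximum demand over queries, left-justified, queries in input order.
Any packing is acceptable because insertion columns assert no homology and
are masked before phylogenetic use.

## Evaluation metrics

SPFN/SPFP are set differences of homology-pair sets keyed by
(sequence id, position in the ungapped sequence); INSERTION columns
contribute no pairs. A 0/0 rate is defined as 0 so degenerate inputs never
crash. TC compares reference columns with ≥ 2 residues by residue-*set*
identity (not column position), so interleaved insertion blocks cannot
affect it; an alignment with no such reference columns scores TC 100.
`sp_scores` counts pairs per column in linear time instead of materialising
them; a brute-force pair-enumeration oracle cross-checks it in the tests.
One subtlety: masking removes insertion residues and shifts ungapped
indices, so the masked/unmasked pair-set identity is checked after re-keying
residues by their index among match-column residues.

Tree error is the FN (missing branch) rate over internal-edge bipartitions;
ΔFN subtracts the FN rate of the tree built on the true alignment and may be
negative.

## Synthetic data

The simulator evolves a root sequence (uniform over the canonical alphabet)
down a tree whose branch lengths are expected substitutions per site:
Jukes–Cantor substitutions (uniform replacement for amino acids), and per
site insertion/deletion probability `indel_rate × branch length` with
geometric lengths (parameter `indel_p`). Every site carries a persistent
identity, so the true alignment of the leaves is exact by construction.
Fragmentation replaces `round(fraction × n)` sequences (round half up) with
contiguous substrings whose target lengths are normal draws — non-positive
draws redrawn, overlong draws clamped — at uniform positions; the benchmark
convention is N(500, 60) at fractions 12.5/25/50 %.

What the simulator does *not* emulate: site-rate heterogeneity, indel-length
distributions fitted to real data, base-composition bias, alignment-error
correlation along the sequence. Passing the desk-scale studies therefore
shows the machinery is correct and the qualitative robustness claims hold
under a clean indel model, not that error rates on real ribosomal or protein
benchmarks would match.

## Study conditions (acceptance script and heavy tests)

Chosen once as a moderate-difficulty benchmark emulation and kept fixed:
200 taxa on a random-join topology with exponential branch lengths (mean
0.04 substitutions/site — root-to-leaf paths of ~8 edges give average
pairwise divergence around 0.5–0.7), root length 500, indel rate 0.02 per
site per unit branch length, geometric indel lengths with p = 0.5; backbone
size 100, subset max 10. Fragmentation uses the benchmark's N(500, 60)
scaled to half the simulated locus length, i.e. N(250, 30), at fraction 0.5.
Problem sizes are deliberately desk-scale (hundreds of sequences, length
~500) so the whole study re-runs in minutes on one CPU; the method itself
has no dependence on these sizes.

## Known limitations

* The stand-in backbone aligner is far weaker than a modern MSA tool; its
  purpose is self-containment. Supply `-a`/`-t` from a strong aligner for
  real work — the pipeline's accuracy tracks whatever backbone it is given.
* Laplace pseudocounts make insertions expensive for large subsets (see
  above); queries whose placement hinges on long internal insertions are
  aligned conservatively.
* No HMMER `.hmm` file compatibility, E-values, or multi-hit parsing; model
  serialization uses a versioned plain-text format of this package.
* Scoring every query against every ensemble member is the dominant cost and
  is embarrassingly parallel across (query, HMM) pairs, but the
  implementation is serial.
* Checkpointing and distributed execution are out of scope.
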