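# Methods

## The statistic

For a column-aligned MSA *M* with *N* rows, `msaneff` computes

    NEFF(M) = f · Σₙ 1 / (1 + #{m ≠ n : S(m,n) ≥ θ})

Each sequence *n* receives weight 1/nₙ, where nₙ counts the sequences
(itself included) whose similarity to it reaches the threshold θ; the
comparison is inclusive (≥). The factor *f* is 1/L by default, with L the
column count after preprocessing — under default query-gap removal this is
exactly the query's residue count — or 1/√L, or 1 (`norm="none"`). The
unnormalized value satisfies 1 ≤ NEFF ≤ N and is invariant under row
permutation and under duplicating the whole alignment.

## Similarity

Two constructions are offered, because the tools that popularized NEFF
split on this axis:

* **symmetric** (default): S(i,j) = (# columns with identical codes) / L,
  with gap-aligned-to-gap counting as identical, so S(i,j) = S(j,i);
* **asymmetric**: S(m→n) = (# columns where the codes match *and* row n
  holds a residue) / (row n's non-gap length). The weight of row n counts
  rows m with S(m→n) ≥ θ. A row with no residues gets similarity 0 into it
  (logged, not raised).

Numerators and denominators are exact integer counts; the only
floating-point operation is the final division. The production path builds
the match-count matrix as a sum of indicator-matrix products (one per
symbol code, exact in float64 far below 2⁵³), so it agrees *bit-for-bit*
with a naive O(N²L) double loop — the test suite asserts exact equality of
weights, not approximate.

## Preprocessing

Applied in a fixed, documented order, because the order changes results:

1. **depth cap** (`depth`, off by default): keep the first `depth` rows,
   always retaining the query row;
2. **query-gap removal** (on by default): drop every column where the query
   holds a gap — these are columns created by insertions in other
   sequences;
3. **gappy-column removal** (`gap_cutoff`, default 1.0 = disabled): drop
   columns whose gap fraction strictly exceeds the cutoff (a fraction
   cannot exceed 1, so the default is a no-op).

A `column_map` tracks surviving columns back to original coordinates;
removing every column is an error, not a silent zero.

## Alphabets and non-standard residues

Protein: the 20 standard amino acids, with non-standard set {B, J, O, U, X,
Z}. DNA/RNA: A,C,G,T / A,C,G,U, with the IUPAC ambiguity letters plus X as
the non-standard set. The permitted non-standard sets are a design choice
of this package: IUPAC is the defensible closure of "non-standard residue".
Two policies govern them: `as_standard` (default — each keeps its own code,
so X matches X) and `as_gap` (all collapse onto the gap code). `-` and `.`
are interchangeable gaps everywhere except inside A2M/A3M insertion-state
semantics; `*` and anything else is rejected with the record and column
named. Case never matters outside A2M/A3M.

## Formats

FASTA, A2M, A3M, Stockholm 1.0, Clustal, PFAM, ALN. Where a dialect is
underdetermined in the wild we pin it: PFAM is one `id whitespace sequence`
line per record (a header-less Stockholm body); ALN is bare aligned rows,
one per line, ids synthesized as `seq_1…seq_N`; written FASTA wraps at 60
columns (configurable). A3M insertion resolution offers `remove` (match
columns only — the view NEFF consumes, and the default when converting to
a column-aligned format) and `expand` (insertion runs become full columns,
left-aligned, gap-padded to the longest run between the same match-column
pair). Converting A3M→A2M passes case semantics through without
synthesizing `.` padding. Stockholm `#=` lines ride along as opaque
annotations and survive Stockholm→Stockholm round trips; writing a format
that cannot carry them logs a warning naming what is dropped.

Merging concatenates inputs in the given order and removes duplicates,
where the duplicate key is the gap-normalized, uppercased sequence string
(ids are ignored; first occurrence wins). By default all inputs must share
one query sequence; `require_same_query=False` overrides. A single input
MSA is *not* deduplicated by `compute_neff` — deduplication is a merge
behaviour.

## Per-residue NEFF

The value at column j is the sum of the *global* sequence weights of rows
holding a residue there; weights are computed once, never per column.
Values are reported against original column coordinates and are
unnormalized by default — a per-column 1/L factor has no per-column
meaning — with the normalization applicable on request.

## Multimer NEFF

A multimer MSA concatenates per-chain alignments column-wise. Chain
boundaries are supplied explicitly as column counts (nothing is inferred
from gap structure — explicit lengths are unambiguous). A non-query row is
*paired* iff ≥ 2 of its chain segments contain a residue, otherwise
unpaired for its single occupied chain; rows that are all-gap everywhere
are dropped and logged. Reported blocks: overall (full width, retained
rows), paired (query + paired rows, full width), and per-chain (chain k's
columns over rows with residues there — all-gap-in-chain rows carry no
signal for that chain and would distort weights). For homomers an option
stacks the chain sub-MSAs, deduplicates, and reports one per-entity NEFF.
Pairwise chain-pair NEFF for heteromers is out of scope.

## Synthetic generator

`generate_msa` draws a root sequence, derives cluster centers by mutating
the root at a fixed divergence of 0.5 per column (far below the θ = 0.8
identity threshold, so clusters stay separated), and fills rows by mutating
their center at `mutation_rate` with per-cell gaps at `gap_rate`;
substitutions are uniform over the other standard symbols. Row 0 is the
first cluster's center, kept gap-free, so query-gap removal is a no-op
unless gaps are injected deliberately and the expected unnormalized NEFF
sits near `n_clusters` when `mutation_rate` is small. The multimer variant
places exactly `round(paired_fraction·(N−1))` paired rows and cycles the
rest over chains, guaranteeing at least one residue per intended segment so
classification counts are exact. Randomness is numpy's PCG64
(`default_rng`), which is specified and portable across platforms.

What the generator does **not** emulate: phylogenetic tree structure,
indel processes (gaps are i.i.d. per cell), positional conservation
heterogeneity, and realistic amino-acid substitution preferences. Passing
tests therefore demonstrate correctness of the computation and the format
plumbing on controllable inputs, not calibration of NEFF against any
particular biological database search pipeline.

## Numerical and scale choices

* Thresholding is done on exact-count ratios in float64; no tolerance is
  needed because numerators are integers.
* The scalability check runs N = 2000 × L = 300 (eight clusters, 10%
  mutation, 5% gaps) — deep enough to exercise the blocked vectorized path,
  small enough that the whole suite stays interactive — and spot-checks 50
  rows against direct per-pair recounting.
* Reference-agreement tests use N ≤ 50, L ≤ 40 so the pure-Python naive
  oracle stays fast while covering the full option grid (3 alphabets × 4 θ
  × sym/asym × 3 normalizations × 2 gap cutoffs).

## Known limitations

* Entropy-based and HHsuite cluster-weighting NEFF variants are not
  implemented; the normalization enum is the only family of variants
  offered.
* Alphabet content is validated, not auto-detected; DNA↔RNA translation is
  out of scope.
* PHYLIP/MSF/NEXUS formats and compressed I/O are not supported.
* The asymmetric-similarity construction is the standard directional
  normalization by target non-gap length; other tools' asymmetric variants
  may differ in their treatment of non-standard residues.
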