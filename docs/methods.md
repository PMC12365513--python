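# Methods

## The problem

Temporal-abstraction pipelines turn heterogeneous clinical time series
(regularly sampled laboratory panels, irregularly logged care events)
into *symbolic time intervals* (STIs): triples `(symbol, start, end)`
such as `Glucose.High` over `[3, 7]`. Frequent *time-interval-related
patterns* (TIRPs) mined from an STI database summarise how such
intervals co-occur: a TIRP is an ordered symbol sequence plus a
conjunction of Allen temporal relations between every pair, stored as an
upper-triangular (Höppner) matrix. The mining output is an enumeration
tree — level *k* holds the size-*k* frequent patterns, each child a
single-STI forward extension of its parent — which routinely contains
thousands of nodes.

The package's core contribution is *bidirectional associative
exploration* over such a tree: a user fixes a sequence of STIs and asks
which patterns extend it one STI later (forward) or earlier (backward),
a question the tree's parent/child structure alone cannot answer,
because backward extensions live in other branches.

## The relation calculus

Because every instance's STIs are totally ordered by
`(start, end, symbol)`, the seven non-inverse Allen relations suffice:
before (`b`), meets (`m`), overlaps (`o`), starts (`s`), contains
(`c`), finished-by (`f`), equals (`e`). Classification treats
timestamps within `epsilon` of each other as equal (default 0; raise it
for noisy real timestamps) and applies the *maximal gap*: a `before`
pair whose gap exceeds `max_gap` is *unrelated*, which invalidates any
candidate instance containing it. The gap rule binds every pair, not
only adjacent ones — the constraint belongs to the relation itself.
Intervals are closed; zero-duration STIs (`start == end`) are legal and
model instantaneous events such as a logged fall.

## Mining

The miner is deliberately correctness-first. Level 1 keeps every symbol
supported by at least `min_vs` transactions (a fractional `min_vs` is
converted once, with ceiling; ties count as frequent). A size-*k* node
is extended by scanning each supporting instance for STIs
lexicographically after its last element, reading the new relation
column off the actual intervals, grouping candidates by
`(symbol, column)` and keeping groups above threshold. Relations are
observed, never inferred from transitivity tables, so the output is
provably identical to exhaustive subset enumeration (the test suite
checks exact equality of pattern sets, vertical supports and
per-transaction horizontal supports on small random databases).
Scalability parity with KarmaLego-family miners is an explicit
non-goal; the index and exploration layers, not the miner, are designed
for tens of thousands of nodes.

Metrics per node: VS (distinct supporting transactions), relative VS,
MHS (mean over supporting transactions of the per-transaction instance
count) and MMD (mean over supporting transactions of the mean instance
span). An instance's span is `max(end) − min(start)`: for a `contains`
pair the lexicographically last STI can end first, so "last end" is
read as the maximum end (the literal last element's end is a
configurable alternative a future version could expose; the maximum is
the only choice that makes the span monotone under extension).

## Bidirectional indexing

One pass over the tree records, for every *consecutive* position pair
`(i, i+1)` of every TIRP, an entry `(node, i, relation)` in a forward
map keyed `earlier → later` and a backward map keyed `later → earlier`.
"One after the other" is read as adjacent positions: that is what the
worked bucket contents require, and it keeps the entry count exactly
`Σ (size − 1) ≤ N·(Lmax − 1)` — the build counter is asserted equal to
that sum, the operational shadow of the O(N·Lmax) build time and
O(M·M·N) space over an alphabet of M symbols.

A lookup for a fixed sequence gathers candidates from the bucket of its
rarest consecutive pair (all buckets keyed by its single symbol when
m = 1), then verifies the full relation sub-matrix at the implied match
position and requires a free position after (forward) or before
(backward) the match. Matching is strict on both symbols and relations;
a symbols-only mode exists because chain-style command-line queries
cannot state non-adjacent relations. The index is an accelerator only:
results are defined — and tested, on seeded random trees — to equal an
index-free linear scan of every node. A pattern matching a sequence at
several positions yields several rows, deduplicated by (node,
extending position). Panel rows order by VS descending, then symbol,
then node id; the ordering is a package choice, as is the optional row
cap.

## Exploration semantics

A session starts at a single frequent symbol; panels are the forward
and backward lookups of the fixed sequence. Selecting a row extends the
fixed sequence at that end (relations copied from the row's pattern),
re-bases the center index when prepending, recomputes the opposite
panel, and keeps the same-side panel with the chosen row marked.
Shifting the focus moves only the center: sides that still have fixed
neighbours collapse to a single marked row, a boundary side shows fresh
extensions of the *whole* fixed sequence. This reconciles the two panel
behaviours visible in the interface narrative: full candidate list
right after a selection, single fixed row after a shift. Each row's R
is the relation between the current center STI and the extending STI
read from the full matrix (they need not be adjacent), and the size
label X/Y is the extending STI's position over the pattern size. Undo
pops the last selection or shift; it is provided because re-selection
is clearly intended by the interface even though no mechanism is
specified.

The KLW-style positional query (`first` / `intermediate` / `last`) is
kept as the baseline comparator. Its semantics here: `first` anchors
position 1; `intermediate` must occur at a strictly interior position;
`last` must occur after the matched intermediate, but not necessarily
at the final position. The last point is a deliberate design choice:
the query language cannot express "immediately before", and the
property the package maintains (and tests) is that every backward
lookup's answer set is a subset of the corresponding positional query's
— the query can only over-return. Anchoring `last` to the final
position would break that guarantee for patterns that extend beyond the
queried symbol.

## Synthetic data

The planted-pattern generator emulates the structure of private
clinical STI databases. Defaults are the standard study conditions used
throughout the tests: n = 200 transactions, plant rate 0.6, a 3-STI
clinical template (low fluids overlapping low appetite, both before an
instantaneous fall event), Poisson(3) background intervals per
transaction from a 6-symbol pool disjoint from the template, and
max_gap 20 time units. Planting applies a rigid uniform time shift
only: per-STI jitter is off by default because naive jitter flips
meets/overlaps boundaries and silently changes the planted matrix.
Disjoint noise makes the planted pattern's true VS equal the planted
count exactly, so recovery tests have a closed-form binomial reference
(3·√(π(1−π)/n) ≈ 0.104 at these settings).

What the generator does not emulate: realistic marginal symbol
frequencies, within-patient autocorrelation, or the co-occurrence
structure of real laboratory panels. Passing tests therefore establish
algorithmic correctness (the right patterns, supports and extensions
are computed), not clinical validity of any discovered pattern.

`random_tree` grows structurally valid enumeration trees (prefix
property, anti-monotone synthetic VS) without requiring the relation
matrices to be realisable by intervals — the index and lookups treat
matrices symbolically, so realisability is irrelevant to what these
trees test. `fig1_fixture` is one fixed concrete resolution of the
partially specified 18-node toy tree used in the worked walkthrough;
filler nodes exist only to give every named pattern its prefix chain,
plus one pattern (`P15`) that contains the walkthrough's symbols
non-consecutively, so tests can tell consecutive-sequence lookups apart
from positional queries.

## Temporal abstraction

State abstraction bins each sample by expert cutoffs or equal-width
discretisation; bins are left-closed/right-open with the top bin
closed (a value equal to a cutoff goes up — no boundary rule is
standard, so one is fixed and documented). Gradient abstraction labels
inter-sample *segments* by slope against a stability threshold θ
(default 0: any nonzero slope is a trend); segment rather than sample
semantics is the package's reading of first-derivative abstraction.
Runs of identical labels merge into STIs; a run breaks when the
sampling gap exceeds `max_sample_gap` (default ∞ — regular data never
breaks, irregular event logs should set it). Point-sample STIs span the
first to last observed timestamp of the run (singleton runs are
zero-duration); an `extend_to_next` mode is available for pipelines
that prefer imputing duration to the next sample, which is a modelling
decision, not a default.

## Numerical and I/O choices

Times are plain numbers; calendar parsing belongs upstream. Tree and
index JSON writers are canonical (sorted keys, floats at 6 significant
digits, topological node order), so write∘read is byte-identical on
canonical documents and mining is reproducible to the byte. Readers
reject malformed rows with line numbers rather than coercing. Problem
sizes used by the acceptance checks — random trees up to 500 nodes
(10,000 for the entry-count conservation check), databases of at most 5
transactions × 12 STIs for exhaustive-oracle comparison, 20 seeded
planted runs at n = 200 — were chosen so each check exercises the
stated bounds while exhaustive enumeration stays exact.

## Known limitations

- The miner's exhaustive instance enumeration is exponential in
  transaction length in the worst case; it is intended for desk-scale
  databases and for generating trees, not for mining production EHR
  extracts.
- Horizontal support counts all lexicographic subsets matching the
  pattern; whether production miners count overlapping instances
  identically is not standardised, so HS values may differ from other
  tools on transactions with heavy symbol repetition.
- `epsilon` equality is not transitive; with `epsilon > 0` two
  near-equal timestamps may classify differently depending on pairing.
  Keep `epsilon` at least an order of magnitude below the data's
  granularity.
- Disjunctive ("broader") relation sets and the inverse relations are
  out of scope; so are closed/maximal pattern mining and population
  comparison.
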