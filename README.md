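# tirpscope

Mining, bidirectional indexing and associative exploration of
**time-interval-related patterns (TIRPs)** in symbolic-time-interval
databases.

## Who this is for

Clinical data scientists and medical informaticians who mine frequent
temporal patterns from longitudinal data — laboratory series, care-home
activity logs, admission records — and then face the real problem: an
enumeration tree with thousands of patterns and no good way to ask
*"what typically happens just before (or after) this event?"*.

## What it does

A **symbolic time interval** (STI) is a triple `(symbol, start, end)`,
e.g. `Fluids.Low` over `[2, 9]`, produced by temporal abstraction of
raw series. A **TIRP** is a lexicographically ordered symbol sequence
`s₁ … s_k` plus an upper-triangular matrix of Allen relations
`r(i,j) ∈ {b, m, o, s, c, f, e}` for every pair — `<Fluids.Low b
Fall.Event>` reads "low fluids before a fall". Mining an STI database
yields the enumeration tree of all patterns whose **vertical support**
(number of supporting transactions) clears a threshold, each annotated
with relative VS, **MHS** (mean per-transaction instance count) and
**MMD** (mean per-transaction mean instance span).

The package's centrepiece is a pair of nested hash maps built in one
pass over the tree: for every consecutive symbol pair of every pattern,
the forward index maps `earlier → later → (pattern, position,
relation)` and the backward index the transpose. Together they answer,
in time proportional to the result rather than the tree: *which
patterns contain this fixed STI sequence consecutively, plus at least
one STI afterwards / beforehand?* — the backward direction being
exactly what tree browsing and first/intermediate/last queries cannot
deliver. An exploration session wraps the two lookups with
selection, center shifting, undo, and plot-ready exports (mean
timelines, bubble-chart points, demographic breakdowns).

Modules: `core` (STIs, relations, TIRPs, trees) · `abstraction`
(state/gradient abstraction) · `mining` (correctness-first levelwise
miner) · `index` (the bidirectional pair indices) · `explore` (session
semantics + the positional-query baseline) · `presentation` (chart
payloads) · `io_formats` (CSV/JSON dialects) · `synthetic` (planted
databases, random trees, the toy walkthrough tree) · `cli`.

## Worked example

```python
import tirpscope as ts

# a database with a planted clinical pattern: low fluids overlapping
# low appetite, both before a fall event, in 60% of 200 transactions
db, truth = ts.generate_sti_db(ts.default_plant_spec(), seed=7)

tree = ts.mine_tree(db, ts.MiningConfig(min_vs=0.4, max_gap=20))
print(tree.n, "frequent patterns; planted pattern:", truth.tirp)

node = tree.find(truth.tirp)
print(f"VS={node.metrics.vs}  relative={node.metrics.relative_vs:.3f}  "
      f"MHS={node.metrics.mhs:.2f}  MMD={node.metrics.mmd:.2f}")

session = ts.ExplorationSession(tree, ts.build_indices(tree))
state = session.start("Fall.Event")
for row in state.left:          # what precedes a fall?
    print(row.symbol, f"R={row.relation.value}", row.size_label,
          f"VS={row.metrics.vs}")
```

prints

```
10 frequent patterns; planted pattern: <Fluids.Low o Appetite.Low b Fall.Event>
VS=118  relative=0.590  MHS=1.00  MMD=10.00
Appetite.Low R=b 2/3 VS=118
Appetite.Low R=b 1/2 VS=118
Fluids.Low R=b 1/2 VS=118
```

Reading the first row: in a size-3 pattern, `Appetite.Low` is the STI
at position 2 immediately before the fall (`R=b`, before), supported by
118 of 200 transactions — the planted pattern, whose empirical rate
0.590 fluctuates binomially around the planted 0.6. The MMD of 10.00
is the template's exact span (fall at t=10, fluids starting at t=0),
preserved because planting shifts time rigidly.

The same pipeline is available from the shell:

```sh
tirpscope simulate --n 200 --rate 0.6 --seed 7 --out db.csv --truth truth.json
tirpscope mine --sti-db db.csv --min-vs 0.4 --max-gap 20 --out tree.json
tirpscope index --tree tree.json --out index.json
tirpscope query --tree tree.json --seq "Fluids.Low:b:Fall.Event" --direction backward
tirpscope explore --tree tree.json --start Fall.Event
```

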