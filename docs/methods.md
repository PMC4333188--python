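# Methods

## Model and procedure

The predictor rests on one assumption: proteins belonging to the same
complex tend to interact, so a *dense* region of a detected complex whose
members are almost all pairwise connected is strong evidence that its few
missing pairs are false negatives of the interaction screen. Loosely
connected parts of a complex carry no such evidence and are discarded.

Given an undirected PPI network *G* and a complex (a node set, typically
5–50 proteins), decomposition proceeds:

1. **Seed.** Find a clique of *k* members. The method's own terminology
   calls this a *k*-core — a complete subnetwork on *k* nodes — which
   collides with the standard graph-theoretic k-core (maximal subgraph of
   minimum degree *k*); the implementation uses clique semantics throughout
   and names functions accordingly (`find_k_clique`).
2. **Greedy extension.** Among unconsumed complex members, append the node
   with the most edges into the current subnet. The extension stops when
   the best candidate has zero connections, or when accepting it would not
   keep the density 2*m*/*n*(*n*−1) strictly above the threshold λ. The
   comparison is strict (`density > λ`): a candidate landing exactly on λ
   is rejected. A rejected candidate ends the extension entirely rather
   than being skipped — the stopping rule is "the expansion stops", taken
   literally; the rejected node remains available for later seeds.
3. **Prune.** Remove the accepted subnet's members from the complex and
   repeat from step 1. When no *k*-clique remains, leftover members are
   abandoned. Subnets from one complex are therefore node-disjoint, each
   has ≥ *k* members and density > λ, and the loop terminates in at most
   ⌊*n*/*k*⌋ rounds.

Predictions are all non-adjacent member pairs of each retained subnet
(*n*(*n*−1)/2 − *m* pairs per subnet). Pairs are canonicalized (unordered,
stored lexicographically sorted) so (a,b) and (b,a) are one prediction.
The repetition count *h* of a pair is the number of (complex, subnet)
sources that emitted it; since subnets within one complex are disjoint,
*h* > 1 can only arise from overlapping or repeated complexes. The *h*
filter is exposed as a generic `min_h` threshold, with `min_h=2` the
standard high-confidence subset.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| *k* | seed clique size | required | 4 suits most detector outputs; use larger (e.g. 7) for detectors emitting big dense complexes. Must be ≥ 2. |
| λ | density threshold | 0.7 | densities above 0.5 already indicate a dense subnet; 0.7 trades prediction quality against quantity. Raising λ can only shrink the prediction set. |
| `seed_mode` | seed-clique choice | deterministic | "deterministic" picks the lexicographically smallest clique, making runs byte-reproducible; "random" draws uniformly over all enumerated k-cliques with a user RNG seed. |
| `min_h` | repetition filter | 1 | 2 keeps only pairs predicted by at least two subnets. |

Tie-breaking in the greedy extension (several candidates with equal
connection counts) takes the lexicographically smallest identifier, purely
for reproducibility; the method itself does not specify an order.

k-clique search runs as a backtracking enumeration over sorted node labels
restricted to the complex's induced subgraph, yielding cliques in
lexicographic order (so the deterministic mode is the first hit, and the
random mode draws from the full enumeration). Complexes are small, so the
exponential worst case is irrelevant in practice; a complex that is one
huge clique is handled by the candidate-count pruning in the enumerator.

## Evaluation estimators

- **Likelihood ratio** *L* = (*P*₊/*G*₊)/(*P*₋/*G*₋). The ratio of hit
  *rates* corrects the extreme imbalance between gold-standard positives
  and negatives. The published yeast constants *G*₊ = 8250 and
  *G*₋ = 2705844 are shipped as overridable defaults; with user-supplied
  gold standards the actual set sizes are used. *P*₋ = 0 with *P*₊ > 0
  yields `inf` (flagged as such in CLI output); *P*₊ = *P*₋ = 0 yields
  `nan` (undefined). *L* is invariant under common scaling of the hit
  counts.
- **Overlap statistics** report |A∩B|, |A∪B| (inclusion–exclusion,
  asserted against the direct set union) and 100·|A∩B|/|A∪B|, rounded
  half-up to an integer percent for display.
- **Annotation hit ratio**: a pair hits when its proteins share ≥ 1 term
  whose *name* contains a keyword ("complex" by default, case-insensitive
  substring). This is a deliberately flat reading of semantic screening —
  no ontology traversal or semantic similarity is attempted; the
  annotation input is a plain protein → (term id, term name) table.

## Synthetic benchmark

`coreppi.synthetic.generate` plants complexes of given sizes as dense
modules (each within-complex pair is an edge with probability `p_within`)
on an Erdős–Rényi background (`p_background` for every other pair),
optionally shares ⌈`overlap_fraction`·size⌉ nodes between consecutive
complexes, and removes ⌊`holdout_fraction`·(number of within-complex
edges)⌋ edges uniformly at random. The removed edges are the ground truth a
predictor should recover. Reference sets are derived from the same draw:
positives = held-out edges plus a 25% sample of kept within-complex edges
(real gold standards contain mostly known, present interactions);
negatives = a sample of cross-complex pairs that never carried an edge
(the different-compartment analogue), 10× the positive count; the
reference interactome = all network edges plus the held-out edges; and
each complex annotates its members with a "planted module *i* complex"
term.

The default study condition — complexes of 8, 9, 10, 11, 12 proteins,
`p_within` = 1.0, `holdout_fraction` = 0.1, `p_background` = 0.02, 120
background proteins, *k* = 4, λ = 0.7 — makes every planted complex a
near-clique, which is the regime the decomposition targets. Under it the
pipeline recovers essentially all held-out edges with near-perfect
precision, because the only missing pairs inside dense subnets *are* the
held-out edges. What passing these tests shows is that the machinery —
seeding, extension, pruning, aggregation, filtering, every estimator — is
correct and that recovery vastly exceeds a size-matched random predictor.
What it does not show: performance on real interactomes, whose complexes
are noisier, whose degree distribution is heavy-tailed (the generator makes
no attempt at scale-free structure), and whose detectors have biases the
generator does not emulate.

Two measured numbers deserve a note. The pipeline's likelihood ratio on the
clean benchmark is typically infinite (zero negative hits), so the
acceptance script reports the positive-hit percentage and negative-hit
count directly, plus the *L* of a 500-pair uniform random predictor as the
null reference; that null scores well below 1 (≈ 0.3 under the defaults)
because only the held-out share of the positive set is reachable by a
predictor that, by construction, proposes non-edges. And the *h*-filter
precision gain is 0 under `p_within` = 1.0, since unfiltered precision is
already 1; the filter's value on this benchmark is shown by its kept
fraction and by the h ≥ 2 counts arising from duplicated/overlapping
complexes.

## Numerical and design choices

- Densities are exact rationals computed in floating point from integer
  counts; the only comparisons are strict (`> λ`) and are not subject to
  rounding noise for the set sizes involved.
- Network cleaning on read: self-interactions dropped, duplicate and
  reversed-duplicate records collapsed, with dropped counts logged.
  Complex members absent from the network are ignored with no error —
  detectors and networks may come from different snapshots.
- Complexes may legitimately contain no *k*-clique; they produce zero
  subnets and zero predictions rather than an error.
- Prediction files round-trip losslessly: the sources column stores
  `complex_id/subnet_index` tokens.
- The overlap union is computed by inclusion–exclusion and asserted equal
  to the direct union on every call.

## Known limitations

- A node rejected by the density test ends the whole extension; an
  alternative (skip it and try the next-best candidate) would grow larger
  subnets. The stopping rule follows the method's specification.
- The generator's negative sampling assumes complexes are mostly
  non-overlapping; with heavy overlap, fewer cross-complex pairs exist.
- Identifier handling is purely lexical; no mapping between naming schemes
  is attempted.
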