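# Methods

This note states the measures and algorithms implemented by `ontoalign`
precisely, together with their conventions, degenerate cases, and known
caveats. All behaviour described here is covered by the test suite.

## Concept-graph model

A *concept graph* is a set of concepts, each with a unique namespaced id,
a primary name, optional synonyms and a definition, a list of property
names, a list of `is_a` parent ids, typed relationship targets
(`relation name → [target ids]`), and opaque instance labels. The `is_a`
edges must form a directed acyclic graph; cycles and unresolved
references are rejected at load time with errors naming the offending
concept. Relational schemas are mapped onto the same model: tables →
concepts, columns → properties, foreign keys → `references`
relationships, binding links → `hasBinding` relationships; schema graphs
have no `is_a` edges.

The *ancestor list* of a concept is computed breadth-first along `is_a`
edges with lexicographic tie-break among parents at equal depth, each
ancestor listed once, the concept itself excluded. This ordering is
deterministic so that repeated runs produce identical matrices.

## Lexical layer

Names are normalized before comparison: lowercase, hyphens/underscores
removed, each whitespace-separated token reduced from plural form
(`-ies → -y`; `-ses → -s` base; `-ss`/`-us` kept; otherwise a trailing
`-s` dropped), then tokens concatenated. Edit distance is the standard
Levenshtein distance (unit insert/delete/substitute), computed by the
`edlib` library and cross-checked in the tests against an independent
dynamic-programming oracle, exhaustively for all string pairs of length
≤ 6 over a three-letter alphabet.

Name similarity of concepts `a`, `b` with normalized names `n_a`, `n_b`:

- `1.0` if `n_a = n_b` or the pair is declared synonymous in the lexicon
  (synsets are compared in normalized form);
- otherwise `max(0, 1 − ed(n_a, n_b) / max(|n_a|, |n_b|))`.

Comparing two names that normalize to the empty string is an error
(`DegenerateNameError`), not a silent 0 or 1.

## Four similarity aspects

For a concept pair `(a, b)` the similarity vector is
`x = (s1, s2, s3, s4)`:

- **s1 — name**: as above.
- **s2 — properties**: property-name lists are matched greedily
  (repeatedly pair the currently most similar unused names, ties broken
  lexicographically), counting pairs with name similarity ≥
  `theta_match` (default 0.9). With `m` matches,
  `s2 = 2m / (|P_a| + |P_b|)`. Both lists empty → 0.
- **s3 — `is_a` ancestry**: ancestor *name* lists are greedily matched
  with the same floor; `s3 = (Σ matched similarities) / max(|A_a|, |A_b|)`.
  Two roots (both ancestor sets empty) → 1.0; one empty → 0.0.
- **s4 — binding targets**: the Dice form of s2 applied to the names of
  `hasBinding` relationship targets. Both target sets empty → 0.0.

The overall similarity is `v = w · x` with the weight vector `w` on the
probability simplex (`w_k ≥ 0`, `Σ w_k = 1`); the all-pairs similarity
matrix stores the 4-component vectors so it can be re-weighted without
recomputation.

## Weight learning

Given training pairs `T` (expert-declared correspondences, indices `d`),
with `v_d` the overall similarity of training cell `d` and `rmax_d`,
`cmax_d` the maxima of its row and column (both include the cell
itself), the training error is

```
E(w) = ½ Σ_d [ (rmax_d − v_d)² + (cmax_d − v_d)² ].
```

`E = 0` exactly when every training pair dominates its row and column.
Starting from uniform weights `(¼, ¼, ¼, ¼)`, the delta rule updates

```
w ← Π( w + η Σ_d [ (rmax_d − v_d) + (cmax_d − v_d) ] · x_d ),
```

where `x_d` is the component vector of training cell `d` and `Π` clamps
negative coordinates to zero and renormalizes to sum 1 (falling back to
uniform if all mass is clamped). Row/column maxima are recomputed each
iteration from the re-weighted matrix. Iteration stops when the maximum
coordinate change falls below the tolerance (default `1e-4`; default
`η = 0.1`, cap 5000 iterations). A trace of `(iteration, w, E)` is
recorded. A matrix whose training cells are identically zero has no
gradient signal and is rejected (`NoSignalError`).

Properties of this scheme, verified in the tests:

- weights remain on the simplex after every iteration;
- an aspect that is zero everywhere receives no gradient, so
  renormalization drives its weight monotonically toward 0 — on resource
  pairs without properties or binding links the learned `w2`, `w4` come
  out ≈ 0;
- larger learning rates converge in at most as many iterations on the
  studied instances (η = 0.3 roughly halves the count vs η = 0.1);
- on instances where each training cell is challenged by competitors
  that win on *different* aspects (trade-off instances), `E` is
  non-increasing for small η, and the learned weights agree with a
  brute-force simplex grid search (step 0.01) to within 0.05 per
  coordinate on a fixed instance with a unique zero-error point.

**Caveats.** The delta rule is not a gradient descent of `E` in the
strict sense (the dependence of `rmax`/`cmax` on `w` is ignored within an
update), and it only ever *adds* nonnegative multiples of training-cell
component vectors before projection. Two consequences: (i) when a
competitor cell componentwise dominates a training cell, the row maximum
grows at least as fast as the cell value and `E` can increase regardless
of step size — monotone descent is therefore a property of trade-off
instances, not of arbitrary ones; (ii) on arbitrary component grids the
fixed point need not be the global minimizer of `E` over the simplex, so
grid-search agreement is asserted on instances whose unique zero-error
point the rule can reach.

Weight learning only moves when the training error is nonzero at the
uniform start, i.e. when some training pair is out-ranked in its row or
column. That requires confusable non-equivalent concepts (homonyms,
near-duplicates) — precisely the situation of real resource pairs. The
synthetic generator produces this regime via `confuser_rate`.

## Equivalent-pair extraction

All concepts start as singleton clusters; the most similar admissible
cluster pair (one concept from each resource, neither merged before) is
merged repeatedly while similarity ≥ threshold (default 0.7; ties broken
lexicographically on the id pair). With clusters capped at one concept
per side this is greedy maximum-first bipartite matching; the tests
verify agreement with an exhaustive enumeration of all maximal-first
merge orders on small instances.

Threshold choice interacts with perturbation: a single corrupted name
zeroes the binding similarity of every concept that binds to it (its
match falls below `theta_match`) and dilutes ancestry similarity of its
whole subtree, so under uniform weights a perfectly reasonable candidate
can score ≈ 0.75. Very high thresholds (0.95) are appropriate only for
near-identical resources; the default 0.7 tolerates mild perturbation.

## Evaluation

With `n1` output pairs, `n2` of them correct and `n3` gold pairs missed
(pair identity is unordered):

```
p = n2/n1    r = n2/(n2+n3)    f = 2pr/(p+r)    o = r(2 − 1/p)
```

The Overall measure `o` estimates the fraction of manual alignment
effort saved after post-processing (deleting the `n1 − n2` false pairs,
adding the `n3` missed ones); it is negative when `p < ½` and is not
clamped. Degenerate counts use 0-conventions. The training fraction is
`100 · |T| / (n2 + n3)`, reported exactly (no truncation).

## Backbone augmentation

Alignment pairs are `(backbone id, source id)`. Processing order is
topological (parents before children):

1. Candidate imports are all `is_a` descendants of aligned source
   concepts that are not themselves aligned. A candidate whose id
   already exists in the backbone, or none of whose parents survive
   import, is recorded as a conflict and skipped.
2. Surviving candidates are imported with ids and names unchanged,
   parents rewritten through the aligned-equivalence map (direct
   children of an aligned concept are re-rooted under its backbone
   equivalent), and relation targets rewritten the same way; targets
   outside the import scope are dropped with a conflict record.
3. Aligned backbone concepts absorb the union of their counterpart's
   properties and relationship entries.

The report counts imported concepts and *catalogue-level* additions: the
number of property and relationship names newly introduced into the
backbone's catalogues. The result graph is re-validated (resolution +
acyclicity). The backbone passed in is never modified; re-running the
same augmentation adds nothing new.

## Synthetic generator

One seeded pseudo-random stream drives everything, so a configuration is
byte-reproducible. Ontology A is a rooted DAG of `n` concepts with fresh
pronounceable names (pairwise name similarity < 0.5), 1–3 properties
drawn from a shared pool, and backward-pointing `hasBinding` links. The
first `k = max(2, round(overlap · n))` concepts — an upward-closed set,
so ancestry and bindings survive — are copied into ontology B under a
fresh namespace and perturbed at configured rates: one-character name
edits, synonym swaps (recorded in the emitted lexicon), property drops,
parent rewires. B is padded back to `n` concepts with distractors that
are either fresh disjoint-vocabulary concepts or, with probability
`confuser_rate`, homonyms of shared concepts (same name, parents and
properties, different identity). The gold standard maps each copied
concept to its origin.
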