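# Methods

## The model

`biocnet` analyses *biocultural values networks*: directed, weighted
graphs with two node classes — cultural values (e.g. stewardship, people
to place) and biophysical elements (species, places, ecosystem features)
— built from qualitatively coded interview data. The raw material is a
set of *coded segments*: sections of interview narrative to which coders
assigned directed dependency mentions between codes. The pipeline makes
three modelling commitments:

1. **Co-occurrence weighting.** The weight of a directed edge `a -> b` is
   the number of segments whose mention set contains that dependency.
   Mentions within a segment have set semantics: repeating a dependency
   inside one segment does not strengthen it, because the narrative
   section, not the utterance, is the unit of association.
2. **Direction is coder-assigned.** An edge `a -> b` means "b depends on
   a". The pipeline never infers direction from data. Dependencies
   between two biophysical elements are excluded by the coding framework
   and rejected on input. Value→biophysical mentions are accepted (with a
   warning counter) but the support-direction analyses only use
   biophysical→value and value→value edges.
3. **Vulnerability is k-step reachability.** No spreading or percolation
   dynamics: a value is "at direct risk" from losing an element if it is
   an out-neighbour of that element in the core network (path length 1),
   and "at cascading risk" if it is reachable within two directed steps.

## Standardization

Raw integer weights are mapped to [0, 1] before thresholding. The default
is `divide_by_max` (`std = raw / max(raw)`): every observed link keeps
positive weight and the weakest observed link maps to `1/max`, not 0. A
`min_max` mode (`(raw − min)/(max − min)`, all-equal case mapping to 1)
is provided for sensitivity checks. Both are rank-preserving, so core
extraction is invariant to the choice; only the printed weights differ.
The mode used is recorded in the network's provenance.

## Core extraction

The core keeps the strongest `fraction` (default 0.05) of links: target
count `k = ceil(fraction × E)` over `E` edges, sorted by standardized
weight. Boundary ties are included by default (`include_ties`), so the
result never depends on an arbitrary edge ordering; the realized fraction
is recorded in the threshold metadata. A `strict_count` policy retains
exactly `k` edges with a deterministic lexicographic tie-break. Either
way the minimum retained weight is ≥ the maximum dropped weight, and
every node without a retained link is removed, so the core has no
isolated nodes.

## Ego networks, support and path length

Ego networks are induced subgraphs of all nodes within `k ∈ {1, 2}`
directed steps of a biophysical ego. Edges with standardized weight above
0.5 carry a boolean `strong` flag (a display convention for the strongest
core links). The ego summary table reports node counts with the ego
included by default, *and* values-reached counts separately, because the
two conventions (count the ego or not) both occur in practice and the
difference is exactly 1 per row; exposing both avoids resolving that
ambiguity silently.

The per-value *support* count is the number of distinct biophysical
in-neighbours in the core — a redundancy measure: a value supported by
several elements can survive losing one.

Average path length is the mean unweighted shortest-path length over
ordered node pairs with a finite directed path; unreachable pairs are
counted and reported, never imputed. An undirected mode exists for
sensitivity analysis. The directed-over-finite-pairs convention is the
least-assumption choice for a sparse digraph in which many ordered pairs
are unreachable.

Full-network connectivity summaries ("how many elements is each value
associated with") deliberately ignore direction, since they describe
association, not dependency.

## The synthetic generator

Real corpora of this kind are typically owned by the interviewed
community and not distributable, so the generator emulates the *regime*
such data occupy rather than any particular dataset:

- 24 interviews over a vocabulary of 22 values and 41 biophysical
  elements (the shipped vocabulary file is synthetic: real value codes
  and a handful of real element names, padded with invented coastal
  elements);
- Poisson segment counts (mean 10/interview) and mention counts (mean
  12/segment), ≈ 2 500–3 000 mentions per corpus; negative binomial
  dispersion available;
- heavy-tailed background: each admissible pair (value→value with
  probability `p_value_value` = 0.35, else biophysical→value) is drawn
  from a rank-based power law with exponent `background_concentration`
  = 0.9 over a seeded rank permutation;
- a planted core: a planted pair's sampling weight is
  `multiplier × (mean background weight of its pool)`. Anchoring the
  multiplier to the pool mean (rather than to the pair's own random rank
  weight) makes multiplier 1 an exactly-average pair — a clean null —
  and makes core recovery monotone in the multiplier instead of hostage
  to the rank lottery.

The shipped default configuration plants 27 pairs (18 biophysical→value,
9 value→value) spanning 13 values and 7 elements with multipliers 50–150.
Under it the built network's maximum raw weight falls around 90–125
(within the 1–142 range such studies report) and the 5% core recovers
roughly those 13 values and 7 elements plus a few background edges. These
sizes were fixed once, when the defaults were chosen, and are treated as
the study conditions; exact core composition is stochastic and is not
asserted in tests.

**What passing tests do and do not show.** The generator reproduces count
skew, class structure and a planted backbone. It does not emulate
narrative correlation between segments of one interview, coder
disagreement, interview-level heterogeneity beyond Poisson noise, or the
semantic clustering of real values. Recovery results therefore validate
the *pipeline* (thresholding finds planted count leaders), not any claim
about real interview data.

The recovery benchmark (`recovery_benchmark_config`) plants 10
biophysical→value pairs at a uniform multiplier over ≈ 2 000 mentions;
at 20× the 5% core recovers them essentially perfectly (mean recall ≥
0.9 over 20 seeded replicates), at 1× essentially never, and recall is
monotone across multipliers 1, 5, 20, 100.

## Numerical and determinism choices

- `ceil(fraction × E)` is computed with a 1e-9 guard so exact multiples
  are not bumped up by float noise.
- All tables sort by the reported statistic descending with alphabetical
  tie-breaks; edge and node iteration orders are sorted at construction.
  Re-running the pipeline on identical inputs yields byte-identical
  outputs (asserted in tests).
- Degenerate inputs fail loudly: empty corpora cannot build a network,
  edgeless networks cannot be standardized or thresholded, path length
  requires ≥ 2 nodes, egos must exist and be biophysical.
- The generator is fully determined by its config (including seed); all
  randomness flows through one `numpy` `Generator`.

## Reproducing published-study quantities

`biocnet.study.reproduce_study(adjacency_csv, vocabulary)` recomputes the
headline quantities of a published analysis (core composition at 5%,
per-value biophysical support, ego node counts at path lengths 1 and 2,
core average path length) from a raw-count adjacency matrix. The matrix
behind the published Ngātiwai analysis is held by the tribe and shared
only on request, so the corresponding acceptance test can only run where
that file has been obtained and placed at `data/study_adjacency.csv`;
the mechanics of the routine are tested against a synthetic stand-in
matrix.

## Known limitations

- Reachability treats all core edges as equally traversable; edge
  weights do not attenuate cascades.
- Multi-participant interviews are not weighted differently from
  single-participant ones; every segment counts equally.
- The frequency table's denominator convention (per-segment vs
  per-mention) changes relative frequencies; both are exposed because
  published percentages of this kind rarely state the denominator.
- No statistical null model for co-occurrence: the backbone is a raw
  count threshold, not a significance filter.
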