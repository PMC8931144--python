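# biocnet

Biocultural values networks from coded interview data: build a directed,
weighted co-occurrence network linking cultural values and biophysical
elements, extract the *core network* of strongest dependencies, and
quantify how environmental change could cascade through a community's
value system.

## Who this is for

Researchers in conservation social science and social-ecological systems
who work with qualitatively coded interviews — segments of narrative
annotated with value codes (e.g. `STE` stewardship, `PTP` people to
people) and biophysical element codes (e.g. `SEA`, `PETRELS`) and
directed dependency relations between them. Because such data are often
owned by the interviewed community and cannot be shared, the package also
ships a seeded synthetic-corpus generator that reproduces the statistical
regime of this kind of study, so every stage of the pipeline is testable
without access to restricted data.

## The method

From coded segments the pipeline computes, for each directed pair of
codes `(a, b)`, the weight

&nbsp;&nbsp;&nbsp;&nbsp;`w(a→b) = #{segments whose mention set contains a→b}`,

i.e. co-occurrence frequency with the narrative segment as the counting
unit; the edge direction `a→b` means *b depends on a*, as assigned by the
coders. Biophysical→biophysical links are excluded. Weights are
standardized to [0, 1] (default: divide by the maximum). The **core
network** keeps the strongest 5% of links, `k = ⌈0.05·E⌉` with boundary
ties included, and drops all nodes left without a retained link. On the
core, for each biophysical element *e*:

- **direct risk** (path length 1): the values that are out-neighbours of
  *e* — directly dependent on it;
- **cascading risk** (path length 2): all values reachable from *e*
  within two directed steps;
- **support/redundancy**: per value, the number of distinct biophysical
  in-neighbours;
- **average path length**: the mean directed shortest-path length over
  reachable node pairs, a measure of how easily perturbations traverse
  the core.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```sh
python examples/02_core_vulnerability.py
```

generates a synthetic study-regime corpus (24 interviews, 22 values,
41 elements, planted strong links) and prints, among other things:

```
corpus: 249 segments, 2653 mentions
full network: 63 nodes, 491 edges, max raw weight 109

core (top 5% of links, ties included): 25 edges, 15 values + 8 biophysical elements

ego-network sizes per core element (node counts include the ego):
   element  k1_nodes  k2_nodes  k1_values  k2_values
       SEA         5         6          4          5
      FISH         3         3          2          2
...
core average path length (directed, finite pairs): 1.23 over 31 pairs (475 unreachable)
```

Reading this: the thresholded core couples 15 values to 8 biophysical
elements; losing access to `SEA` would directly degrade 4 core values
(`k1_values`) and reach a 5th within two steps (`k2_values`); the short
average path length says perturbations cross the core in barely more
than one step. `examples/01_build_network.py` shows the counting
conventions on a three-segment toy corpus, and
`examples/03_simulate_and_recover.py` sweeps the planted-signal strength
and shows the 5% core recovering planted links with recall rising from
0.0 (multiplier 1) to 1.0 (multiplier 20 and above).

## Command line

```sh
biocnet simulate --seed 7 --out corpus.csv --vocab-out vocab.csv --truth truth.json
biocnet validate corpus.csv vocab.csv
biocnet run corpus.csv vocab.csv --out results/
biocnet ego corpus.csv vocab.csv PETRELS --k 2
biocnet summarize corpus.csv vocab.csv
```

`run` writes GraphML networks (full, core, per-element ego networks),
CSV tables (frequencies, connectivity, support, ego summary),
`metrics.json` and a manifest with input checksums; identical inputs
produce byte-identical outputs. Exit codes: 0 success, 1 invalid
corpus/analysis failure, 2 usage or I/O error.

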