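# Methods

## Model

`communet` treats community metabolism as a directed metabolite graph and
asks two questions per treatment: *what does this community need from its
environment?* and *what can it make there?*

**Graph construction.** Every EC number in the input table is mapped to the
reactions it catalyzes; for each reaction, an edge is drawn from every
substrate to every product (Cartesian product, self-pairs skipped). Edges
carry the set of (reaction, EC) witnesses that justify them, so parallel
chemistry collapses onto one edge without information loss. Reversible
reactions are split into two directed reactions (`_f`/`_r`) at load time:
seed detection and expansion both require explicit direction, and the split
is exactly equivalent to the declared bidirectional relation. Stoichiometry
is ignored throughout — the expansion semantics are presence/absence, so
coefficients would carry no information. Compounds that occur in the
database but in no selected reaction are omitted from the graph; they
reflect database scope, not community chemistry.

**Seed detection.** The strongly connected components of the graph are
contracted to a DAG (the condensation); components with no incoming edge
from another component ("source components") cannot be produced from
anywhere else in the network, so their members are predicted to be consumed
from the environment. All members of a multi-node source SCC are reported
— the component id and size are kept in the proxy's provenance so users can
post-filter, but no confidence weighting is applied. Any SCC algorithm
gives the same partition; the implementation delegates to networkx. Two
consequences are used as internal checks: the condensation is acyclic, and
every node of the graph is reachable from the seed set by directed
traversal.

**Meta filtering.** A sub-network built only from differentially abundant
enzymes is fragmented, and fragmentation manufactures artificial sources
(deleting an edge u→v can promote v to a source). Treatment seed lists are
therefore intersected with the seed list of the full meta-network; only
compounds in both survive into the environmental proxy. By construction
the filter can only shrink a treatment's seed list.

**Expansion.** Network expansion is a least fixed point: starting from the
proxy compounds, each round fires every reaction whose full substrate set
is currently available, adds all products, and repeats until no reaction
fires. The result is order-invariant, monotone in the seed set, and
idempotent; rounds are recorded so the provenance of each compound
(which round, which reactions) is inspectable. Both treatments are
expanded over the identical meta reaction bank, so closure differences are
caused only by the predicted environments. No cofactor amnesty is granted:
only proxy compounds seed the expansion (an explicit auxiliary compound
set, default empty, exists for sensitivity studies). Compounds producible
in exactly one treatment's closure are that treatment's unique compounds.

**Enrichment.** Three entity classes are tested per treatment: enzymes
(treatment-associated ECs), environmental resources (the filtered proxy),
and treatment-unique expansion compounds. The test is the one-sided Fisher
exact / hypergeometric upper tail P(X ≥ k) with k = |query ∩ pathway|,
K = |pathway ∩ universe|, n = |query|, N = |universe|, computed via
`scipy.stats.hypergeom.sf`; q-values are Benjamini–Hochberg over exactly
the tested pathways (`statsmodels.stats.multitest`), and a pathway is
called enriched at q ≤ alpha (default 0.05). A pathway is tested only when
min_size ≤ K ≤ max_size (user-set, defaults 1 and 10000), it is not
explicitly excluded, and k ≥ 1. Pathway size K is measured within the
universe, not the whole database, so the size filter and the 2×2 table
share one frame.

Universe choices (the pool a treatment-specific set was drawn from) are
deliberate defaults, each overridable and recorded in the run manifest:
enzymes → all ECs in the input table; resources → all meta-network seeds;
expansion compounds → the meta-bank closure under the union of both
proxies. Each universe contains its query by construction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_pathway_size` / `max_pathway_size` | 1 / 10000 | bounds on K for a pathway to be tested |
| `excluded_pathways` | empty | pathways dropped before testing (e.g. catch-all maps); removing one never changes other pathways' p-values, only their q-values |
| `alpha` | 0.05 | FDR threshold on q for the enriched flag |
| `hub_max_neighbors` | 25 | strict threshold: nodes with >25 distinct neighbors (direction ignored) are removed before layout, targeting currency metabolites such as water; removal is single-pass on input-graph degrees, no cascade |
| `layout_iterations` | 50 | Fruchterman–Reingold iterations; 0 returns the seeded initial placement |
| `rng_seed` | 0 | seeds the layout; all text outputs are deterministic regardless |
| `auxiliary_seed_compounds` | empty | extra compounds granted to both environments |

## Synthetic data

The fixture generator (`generate_fixture_database`) plants known structure
so its ground truth is exact rather than estimated: the first `n_seeds`
compounds are sources that only ever appear as substrates; every other
compound enters the network as the product of a reaction whose substrates
are already producible; cycle reactions and reversible flags are only
placed where they neither add an incoming edge to a source nor extend the
closure. Consequently the planted sources are provably the unique seed set
and the set of compounds used is provably the expansion closure, which the
test-suite verifies across randomized specifications. The companion table
generator assigns each EC to treatment 1 / treatment 2 / background with
configurable probabilities (default 0.3/0.3/0.4) and draws fold changes
and p-values with the qualitative shape of a real contrast (|logFC| in
[1.5, 6] with p ≤ 0.01 for associated ECs, |logFC| < 1 with p ≥ 0.05
otherwise).

What the synthetic data does **not** emulate: the scale-free degree
distribution and currency-metabolite hubs of real metabolic networks, EC
promiscuity (most fixture reactions carry one EC), partial EC numbers,
and annotation noise. Passing tests therefore demonstrate algorithmic
correctness of seed detection, expansion, filtering and enrichment — not
biological validity of predictions on any real community.

## Numerical and design choices

* Fisher sidedness: over-representation only (upper tail); depletion is
  not tested.
* BH q-values are computed over exactly the set of pathways tested under
  the current size/exclusion filters, so changing filters changes m.
* Tie-breaks: enrichment rows sort by (q, p, pathway name); all list
  outputs are sorted; graph nodes are laid out in sorted order, making
  every text output independent of dict/set iteration order.
* Degenerate inputs: empty networks give empty seed proxies (not errors);
  an EC set matching no reaction gives an empty network plus a warning in
  the manifest; empty enrichment universes skip the test with a warning;
  empty graphs render a placeholder image.
* Exact EC matching: a partial EC in the input ("1.1.1.-") is accepted at
  parse time but matches a reaction only if the database annotates that
  exact string; unmatched ECs are reported, not expanded to all
  completions.
* Hub filtering applies only at visualization; seed detection and
  expansion always see the full graph. A sensitivity pre-filter exists but
  is off by default.
* Problem sizes in the test-suite (digraphs up to 200 nodes, reaction
  banks up to 300, 50–200 replicates per property) were chosen as the
  scale at which the brute-force oracles — transitive-closure
  reachability, sequential loop-until-stable expansion, exact rational
  hypergeometric sums — remain exact and fast.

## Limitations

* Set-based expansion has no notion of flux, yield, thermodynamics or
  compartments; a compound once produced is permanently available.
* Seed prediction is purely topological; reversibility annotations in the
  database strongly affect which compounds look producible.
* The intersection filter assumes the meta-network is itself
  well-connected; on very sparse inputs it can empty a treatment's proxy
  (reported as a warning).
* Enrichment universes are pragmatic defaults; with a biased database the
  background choice can dominate results, which is why the manifest
  records the definitions used.
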