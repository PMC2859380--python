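# Methods

## Interolog transfer

An interaction (A, B) known in species *s* is transferred to species *t* when
both A and B have orthologues in *t*: every pair (A′, B′) from the Cartesian
product of A's and B's orthologues in *t* (excluding pairs whose members are
the same gene) is a candidate. Candidates already present in *t*'s known
interactome are excluded — the package predicts only what is unobserved; a
candidate is never removed just because its score is low (a score cutoff is a
presentation choice, applied only in the CLI, default 1.5). One-to-many and
many-to-many orthologies are enumerated in full rather than restricted to the
best reciprocal pair: co-orthologues with weaker homology still carry
evidence, and the scoring stage (not the enumeration stage) discounts them.
A prediction supported by several source species is a single prediction with
one support list per species; the same machinery run in "detection" mode
(both sides known) yields the conserved-interolog lists, reported
directionally (s→t and t→s are separate counts, since the number of known
interactions in each species differs).

Orthology is an input, not something the package computes: records are read
from a six-column TSV (source gene, source species, target gene, target
species, homology type, percent identity), one directed record per gene pair
and direction, each carrying the percent of *source* residues identical to
the target. Scoring uses the records oriented from the perspective of the
species being scored; when a reciprocal record is missing the forward
record's identity is reused.

## The score family

* **OrthoScore.** For the contributing orthologues of one protein toward one
  supporting species, relative identities r_i = I_i / max(I) are squared and
  summed. "Contributing" means participating in at least one supporting known
  interaction in that species; the maximum is taken among contributors only.
  A single one-to-one orthologue gives exactly 1.
* **Relative-identity rounding.** The reference arithmetic for the
  three-orthologue example (92/87/72 → 1.0, 0.945, 0.78 → 2.501) is
  reproduced by flooring r_i to half-percent granularity (multiples of
  0.005) before squaring; that is the default mode (`half_percent`). Neither
  plain truncation nor half-up rounding at three decimals reproduces both
  printed scaled identities (72/92 = 0.78260 truncates to 0.782, yielding
  2.505, and rounds to 0.783, yielding 2.508). Because the underlying
  convention is ambiguous, the mode is a switch: `half_percent` (default),
  `truncate3`, `round3`, `none`. All modes leave the score scale-invariant
  and bounded by the number of contributing orthologues.
* **SingleSpeciesScore** is the product of the two partners' OrthoScores for
  one supporting species; **SpeciesScore** sums these over supporting
  species. An experimentally observed interaction adds 1.00 for its home
  species. This home-species term is forced by consistency: known
  interactions without any conserved interolog must still score ≥ 1 (the
  observed 1.xx pattern of known-interaction scores), while the stated
  maximum of 4 for a one-to-one prediction in a five-species analysis counts
  only the four *other* species.
* **ExperimentScore** counts distinct (experiment type, evidence id) records
  pooled over the interaction's own evidence and all supporting interologues'
  evidence. Deduplication ignores the database of origin, so the same
  experiment reported by two databases counts once, while two independent
  studies using the same method count twice. A `count_types=True` switch
  collapses to distinct experiment types, for users who read "each type
  counted once" strictly. Interactions known only from a source without
  experiment annotations (the BIND-style dialect) carry the sentinel type
  `protein_protein` and score 1.
* **ExperimentQualityScore** sums, over the distinct experiment types in the
  pooled evidence, the fraction q_e of type-e-annotated interactions found in
  a reference edge set (a STRING-like list over the same identifier space).
  The ratio table is an artifact: computable with `quality_ratios` from any
  reference edge list, or loadable from TSV, so no external download is ever
  required. Unknown types contribute 0; types annotating nothing are omitted.
* **InteroScore** = SpeciesScore × ExperimentScore + ExperimentQualityScore.
  It is monotone non-decreasing in every component; it is *not* a calibrated
  probability — a low score mostly reflects sparse coverage, not evidence
  against the interaction.
* **SpeciesNotation**: one genus initial per registry species in registry
  order (default H, M, D, C, S; the source convention fixes no order), kept
  only where both partners have orthologues (the home species always
  appears); uppercase if an interaction between orthologues is observed
  there, lowercase otherwise. The home letter of a prediction is lowercase by
  definition.

## Interactome assembly

Per-database PPI TSVs are taxon-filtered (both interactors must carry the
species' taxid), optionally filtered to protein–protein rows via
molecule-type columns, identifier-normalised through a synonym table (retired
ids mapped forward to their replacement, rows resolving to the wrong species
or to nothing dropped and counted — never fatal), and merged into one
interactome per species: one interaction per canonically ordered unordered
pair, evidence united with each (type, id) kept once. Merging is
order-invariant. Genes with status `novel` are retained by default; a
`known_only` flag restricts to curated genes. Self-interactions are kept in
the interactome but excluded from topology metrics (simple-graph convention).
Multiple evidence ids under one publication are treated as distinct records,
the only reading the inputs support. Paralogy records are excluded from
prediction: only orthology (speciation-derived) relations transfer
interactions.

## Topology validation

All metrics treat the network as a simple undirected graph (networkx
container).

* **Degree distribution / power-law fit.** p(k) over observed degrees;
  p(k) = c·k^−r fitted by ordinary least squares on (log k, log p) over
  unbinned degrees. Maximum-likelihood (Clauset-style) fitting is out of
  scope; the fit record carries a method tag so it can be added without
  breaking the type. An optional `min_probability` floor restricts the fit to
  well-populated degrees: the near-horizontal band of degrees observed once
  (p = 1/n) otherwise drags the slope toward zero; with a floor of 10/n a
  planted exponent of 2.5 is recovered within ±0.3 on 5 000-node
  configuration-model graphs.
* **Diameter** is computed on the largest connected component (how
  disconnected networks should be handled is otherwise undefined).
* **Clustering coefficient** is the global transitivity
  c = 3·triangles / connected triples, not the mean local coefficient; 0 with
  a log message when no connected triple exists.
* **Global efficiency** is the mean of 1/d(u, v) over unordered node pairs,
  disconnected pairs contributing 0. When scoring a node subset, distances
  are still computed in the full network: subnetworks of interest are almost
  never internally connected, and their connectivity through the rest of the
  interactome is precisely what the measure should capture.
* **Null models.** `rewire_full` randomises the whole network by double edge
  swaps (seeded, default budget 10×|E|, swaps creating self-loops or
  duplicates rejected; if the budget cannot be met the achieved count is
  logged) — degrees are preserved exactly. `rewire_partial` swaps only the
  predicted edges, with known edges frozen and treated as forbidden targets;
  the union is returned. `randomize_same_nodes` draws the same number of
  edges uniformly on the same node set. The expected signature when predicted
  edges densify real modules: the combined network has a smaller diameter and
  higher clustering than the known one, while the partially rewired control
  keeps a similar diameter at much lower clustering.
* **Node-set efficiency Z-scores.** The observed subset efficiency is
  compared against `n_samples` (default 1000) uniformly drawn node sets of
  equal size; z = (obs − mean)/sd with a one-sided normal tail p and an
  empirical p = (1 + #null ≥ obs)/(n + 1). When the queried set is the whole
  network the null is a point mass and z = 0 exactly; a degenerate null with
  a different observation is flagged rather than scored. Random node *sets*
  are the implemented null (matching the subnetwork question "are these
  genes better connected than arbitrary genes?"); an edge-rewired alternative
  can be had by passing a rewired graph.
* **Proportion test.** One-sample two-sided z-test for a proportion against a
  genome-wide value, (p̂ − p₀)/√(p₀(1−p₀)/n) with a normal-approximation p —
  used to ask whether orthologue-bearing proteins are over- or
  under-represented in an interactome.

## Synthetic data

`FixtureSpec`/`generate` emit every input dialect the pipeline consumes, as a
pure function of the spec (same seed, byte-identical files). Genes are
organised into orthologous families (one or more genes per member species;
family structure determines one2one/one2many/many2many labels), with a
conserved core present in all species, partially conserved families, and a
species-unique remainder. Defaults: five species, 100 genes each, 25 % fully
and 25 % partially conserved, identities uniform on 40–99 % (real identity
distributions are not modelled — scores only need valid inputs), 25
background known edges per species, three databases with 20 % two-way and
10 % three-way overlap, a three-type experiment alphabet with planted quality
ratios, 20 % of PPI rows written through synonym or retired identifiers, and
10 % of genes flagged `novel`.

Two deliberate idealisations make planted truth exactly recoverable:
background edges are drawn only among species-unique genes, so planted
interologs are the only source of cross-species support; and the reference
edge set is constructed greedily per experiment type (preferring
singly-annotated interactions) with the *achieved* ratio recorded in the
ground truth, so ratio recovery is exact at 1/n granularity. Consequently,
passing recovery tests demonstrates correctness of the bookkeeping and
enumeration, not robustness to noisy orthology, promiscuous hubs, or the
correlated evidence structure of real databases — none of which the
generator emulates. `generate_scale_free` (configuration model on a power-law
degree sequence, simplified) and `generate_modular_known_predicted`
(planted-partition known network plus within-module predicted edges) provide
the topology fixtures. The five-species Venn counts, coverage percentages and
species-level metric values reported for real 2008-era database snapshots
are not reproducible from synthetic data and are deliberately not targeted;
the directional and structural properties are tested instead.

## Numerical and design choices

* Scores are reported to 3 decimals in tables and attribute files; pair order
  is canonical (lexicographic) everywhere, making all outputs byte-
  deterministic.
* Candidate enumeration removes only same-gene pairs; predicted
  self-interactions between distinct paralogues are allowed.
* Problem sizes in the test suite (500-node/25-module null-model fixture, 20
  trials; 5 000-node configuration model; 1000-sample Z-scores) were chosen
  as the smallest sizes at which the directional effects are stable across
  seeds.
* Known limitations: no MITAB/PSI-XML parsing (dialect TSVs stand in);
  no paralogy-based transfer; OLS power-law fitting is biased for heavy
  tails compared to maximum likelihood; the home-species SpeciesScore term
  and the record-level ExperimentScore are conventions chosen among
  defensible readings (both switchable where ambiguity matters).
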