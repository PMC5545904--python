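# Methods

## The model substrate

A cause-and-effect model is a directed multigraph per species. Nodes are
entities with a function class (protein, gene, chemical, bioprocess,
cell_population, complex), a namespace (HGNC, MGI, CHEBI, GOBP, MESH,
OTHER) and an identifier; protein/gene nodes may carry a modification tag
(e.g. `pmod(Ph, Thr, 1462)`) and/or an activity wrapper (`act(...)`).
Edges carry one of six relations with a total polarity map:
`increases`/`directlyIncreases` → +1, `decreases`/`directlyDecreases` → −1,
`association`/`causesNoChange` → 0. `association` is symmetric (an edge
equals its reverse; it is canonically oriented lexicographically); all
other relations are directed. Edge identity is the canonical
(subject, relation, object) triple; evidence (citation, sentence, statement
order) is metadata, so duplicated statements raise the statement count but
not the distinct-edge count.

The parser accepts a deliberately small BEL-like dialect — term functions
`p, g, a, bp, complex, act, pmod` plus a `cell()` function for
cell-population nodes, the six relations (with `->`, `=>`, `-|`, `=|`, `--`
arrow aliases), `SET Citation`/`SET Evidence` annotations — because curated
neuroinflammation models use the language as a substrate, not its full
grammar. Unknown annotations are skipped with a warning; malformed
statements fail with a line number. Species comes from an explicit
declaration (header comment, `SET Species`, or API/CLI flag) or is inferred
when exactly one of HGNC/MGI appears; mixing both without a declaration is
an error. HGNC implies human and MGI implies mouse; CHEBI/GOBP/MESH
entities are species-neutral and inherit the model's species. `Aβ` is
normalized to the ASCII identifier `amyloid-beta`.

Decorations (`pmod`, `act`) are entity-level, not separate nodes: the
comparison questions here treat "phosphorylated Akt1" and "Akt1" as one
node family. Strict matching (below) can re-separate them.

## Orthology

Cross-species identity is symbol-level: a curated (human_symbol,
mouse_symbol) table, by default backed by the nomenclature case convention
(human all-caps ↔ mouse capitalized), under which NFKB1 ↔ Nfkb1 without
any table row. `table_only` disables the fallback; an unmappable endpoint
is then a value (the edge becomes unique-to-human with a `no_orthology`
flag), never an exception. One-to-many orthology is allowed and every
counterpart is a candidate during matching — a match to *any* counterpart
counts, which is conservative toward "found in mouse". Mapping never
changes function class or decorations, and is an involution on table pairs
and on already-uppercase human symbols.

## Edge concordance

For each human edge, candidate mouse edges are those whose endpoints match
any orthology image of the human endpoints **in the same orientation**
(association candidates match either orientation). Orientation mismatch is
"not found": "opposite direction" in this analysis means opposite effect
sign, not a reversed arrow. Decision rule, given the human polarity
p ≠ 0:

1. any candidate with polarity p → **consistent** (flagged
   `mixed_evidence` if an opposite-polarity candidate also exists — the
   conservative tie-break, surfaced for review rather than silently
   contradictory);
2. else any candidate with polarity −p → **contradictory**;
3. else only zero-polarity candidates → **consistent** with
   `nonpolar_match=True` (a correlative mouse edge supports but cannot
   confirm the sign); a switch demotes this case to unique-to-human;
4. else → **unique_to_human**.

A correlative human edge (p = 0) is consistent when any candidate exists.
Mouse edges with no human edge over their mapped endpoint pair (any
polarity) are reported separately as **unique_to_mouse**; with one-to-one
orthology, swapping the two models' roles exchanges the unique sets and
preserves the consistent/contradictory counts.

Edges are stratified into **molecular** (both endpoints protein, gene,
chemical or complex) versus **cellular** (either endpoint a bioprocess or
cell population). Summaries report per-level counts and integer
percentages with round-half-away-from-zero; within a level, counts always
sum to the level denominator. Note one rounding consequence: a 40-edge
cellular scope generated at proportions 0.62/0.10/0.28 yields exact counts
25/4/11, whose percentages print as 63/10/28 (25/40 = 62.5 rounds up) — no
integer triple over 40 prints as 62/10/28 under a single rounding rule.

## Expression concordance

Inputs are per-gene differential-expression tables in the GEO2R export
layout (`Gene.symbol`, `logFC`, `P.Value`, optional `adj.P.Val`), consumed
as published — raw-matrix reanalysis is out of scope. Multiple probes per
gene collapse to the smallest p-value per dataset (the tables themselves do
not say how probes were resolved upstream; this default is recorded in the
output). A call's direction is `ns` when its p-value exceeds α (default
0.05, unadjusted; `--use-adjusted` switches to the adjusted column), else
the sign of logFC; a significant zero logFC is `ns` with a warning.

Per gene, with mouse symbols mapped into human space, the six categories
are evaluated in precedence order: (1) inconsistent_within_species when a
single species shows both significant directions; (2) non_significant when
every call everywhere is ns; (3) human_only / mouse_only when exactly one
species has a significant call; (4) same_pattern when both species'
collapsed directions agree; (5) contradictory_between_species otherwise.
Agreeing significant calls within a species collapse to one direction —
"inconsistent" requires a strict up-and-down conflict. Genes with no calls
in either species sit outside the summary denominator in an "uncovered"
list. Tissue labels are metadata only: the underlying datasets do not
share tissues across species, so no tissue weighting is attempted.

## Enrichment

Over-representation of a query gene list in a GMT collection uses the
hypergeometric upper tail P(X ≥ k) for overlap k, set size K, query size n,
universe size N, with Benjamini–Hochberg adjustment across the collection's
sets. The universe defaults to the collection's declared background, else
the union of set members; query genes outside it are dropped with a
warning. The EASE-style modified Fisher score used by web annotation tools
is deliberately not reproduced — those results depend on the tool's
database version — so pathway counts from such tools are report-only
inputs, never recomputed. Significant sets from two species over the same
collection are partitioned into shared / unique-to-human / unique-to-mouse
by q ≤ threshold.

## Perturbation propagation

A drug action is a set of (target entity, sign) pairs with sign ±1
(inhibition −1). From each target present in the model (matched by
undecorated node key; targets written for the other species are translated
through the orthology map; missing targets warn and are skipped, all
missing is an error) the engine enumerates **simple** directed paths — no
repeated node, which terminates cycles such as the Nfkb1→Ptgs2→…→Nfkb1
self-regulatory loop — of length ≤ `max_len` through polar edges only;
association edges have no sign to compose and are excluded. A path's sign
is the action sign times the product of its edge polarities; a node's net
sign is +1 or −1 when all arriving paths agree, `conflict` otherwise.
Conflicts are reported, never resolved numerically — the reasoning is
qualitative, with no path weighting, dose or kinetics. The default
`max_len` of 6 covers the longest chain in the worked example
(PDPK1→AKT1→TSC2→RHEB→MTOR→autophagy→amyloid-beta). The target node itself
carries its action sign as the length-0 path. Increasing `max_len` never
un-reaches a node, and can only change a pure sign by way of `conflict`.

Cross-species comparison pairs downstream nodes via orthology and buckets
them: agree (same pure sign), disagree (both reached, different outcome,
including conflict vs pure), agree_on_conflict, and one-species-only.

### The celecoxib fixture

`causenet.fixtures` hand-encodes the two networks around celecoxib's
targets PTGS2 and PDPK1. The mouse network carries the normal-physiology
edges (Pdpk1 → Il4/Ins/Akt1/Gsk3b, Pdpk1 ⊣ Ccr2/M1-macrophage/insulin
resistance, Ptgs2 → amyloid-beta → Tnf/Nfkb1 → Ptgs2, plus the
clearance/phagocytosis and Mapt arms); the human network carries the
perturbed-pathway axis (PDPK1 → AKT1 ⊣ TSC2 → RHEB → MTOR ⊣ autophagy ⊣
amyloid-beta, MTOR → BACE1, the AMPK brake PRKAA1 ⊣ MTOR, and the IL4 /
INS arms). PTGS2 is declared as a human target but the encoded human
normal-physiology network states no downstream PTGS2 edge, so propagation
runs from PDPK1 alone there (with a logged skip). The fixture reproduces
the qualitative contrast: amyloid-beta −1 in mouse versus +1 in human,
with disagreements also on amyloid clearance and inflammatory response.

## Synthetic generators

The generators are constructive, not statistical: category assignment uses
largest-remainder apportionment of the requested proportions, so the
intended counts are exact and closure tests are sharp rather than
within-sampling-error. Randomness (seeded, reproducible byte-for-byte)
affects only symbol choice, topology and magnitudes.

* `generate_model_pair` draws polar human edges over synthetic HGNC-style
  symbols (`SYG1…`) and bioprocess/cell nodes in the requested
  molecular/cellular mix, with no self-edges and no two edges over the
  same ordered endpoint pair (so label recovery is exact); the mouse model
  keeps the sign (consistent), flips it (contradictory) or omits the edge
  (unique-to-human), plus extra edges over mouse-only symbols (`Mog1…`).
  Defaults encode the motivating cytokine-pathway scope: 73 edges, ~45%
  molecular, 27/15/58 proportions, 10 mouse-only edges.
* `generate_expression_tables` builds full per-dataset tables (default
  three datasets per species, matching the number of expression accessions
  per species in the motivating comparison) in which each gene's calls
  force its category at the spec's α: significant p-values are drawn below
  0.8·α, non-significant ones above α + 0.1·(1−α), |logFC| of significant
  calls is `effect` (default 1.5) plus exponential jitter. Default counts
  are the six-way 31/14/19/17/7/12 split over 100 genes.

What the generators do **not** emulate: realistic degree distributions,
citation structure, probe-level noise, inter-dataset correlation, or
tissue effects. Passing closure tests therefore demonstrates that the
classifiers implement their definitions exactly — not that real curated
models or real expression tables are this clean.

## Numerical and interface choices

* Percentages: round half away from zero to integers; counts, not
  percentages, are the stored quantities.
* Hypergeometric p via `scipy.stats.hypergeom.sf(k−1, N, K, n)`; BH via
  `statsmodels` (`fdr_bh`); both are verified in tests against exhaustive
  enumeration and a manual step-up oracle on small cases.
* Determinism: model serialization sorts statements by canonical triple;
  propagation iterates sorted adjacency; generators use
  `numpy.random.default_rng(seed)`.
* The pipeline report is canonical JSON (timestamp isolated in one field so
  the rest is byte-comparable); HTML is a render of that JSON. Every
  reported number is recomputable from the emitted per-record tables.
* Degenerate inputs: empty documents/models/scopes yield empty results with
  zero denominators and no division; empty ORA universe is an error;
  missing drug targets warn (all-missing errors).

## Known limitations

* The two published curated neuroinflammation models (671/1,224 and
  1,016/1,939 nodes/edges) are not redistributed here; their counts are
  reproducible by `model_stats` only when a user supplies the model files.
  The same applies to literature-corpus sizes and annotation-tool pathway
  counts — the pipeline reports them only from supplied inputs.
* Orthology is symbol-level; no sequence-based inference or paralog
  resolution.
* Matching is identifier-level; no ontology reasoning over GO hierarchy.
* Expression concordance ignores effect sizes beyond sign, and performs no
  meta-analytic pooling.
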