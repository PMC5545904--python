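# causenet

Cross-species comparison of cause-and-effect disease models.

Mouse models of neurodegeneration often fail to predict what a drug will do
in patients. One way to ask *why* is to build, per species, a causal
knowledge graph — entities (proteins, genes, chemicals, bioprocesses, cell
populations) connected by signed relations (`increases` → +1, `decreases` →
−1, `association` → 0) — and then compare the two graphs mechanism by
mechanism. `causenet` implements that comparison for curated human/mouse
model pairs, such as neuroinflammation models in the Alzheimer's disease
context:

* **Model I/O** — parse a BEL-subset dialect or flat TSV edge tables into a
  species-scoped multigraph; write back deterministically; export SIF /
  GraphML; summarize node/edge/statement counts.
* **Edge concordance** — classify every human edge against the mouse model
  through symbol orthology (curated table plus HGNC/MGI case-convention
  fallback) as **consistent** (same sign), **contradictory** (opposite
  sign), or **unique to human** (absent in mouse), stratified into
  *molecular* (both endpoints protein/gene/chemical/complex) and *cellular*
  (a bioprocess or cell-population endpoint) levels, with integer
  percentage summaries; unmatched mouse edges are reported as unique to
  mouse.
* **Expression concordance** — consume per-gene differential-expression
  call tables (GEO2R export layout) from each species and classify every
  gene into six categories: same pattern, human-only, mouse-only,
  inconsistent within a species, contradictory between species,
  non-significant (significance at p ≤ α, default α = 0.05, unadjusted).
* **Enrichment** — hypergeometric over-representation of a model's gene
  list in user-supplied GMT gene sets with Benjamini–Hochberg adjustment,
  and shared/unique partitioning of significant sets across species.
* **Perturbation** — a signed-path mode-of-action engine: given a drug's
  signed target actions, enumerate simple directed paths (length ≤ L,
  default 6) through polar edges; a node's net predicted sign is the action
  sign times the product of edge polarities, with +/− conflicts surfaced,
  never resolved; compare the two species' predictions node by node.
* **Synthetic data** — constructive generators for paired models with
  exact per-category edge counts (largest-remainder apportionment) and for
  expression tables with exact six-way category counts, so every classifier
  is testable against known ground truth.

## Worked example: celecoxib across species

Celecoxib inhibits PTGS2 (COX-2) and PDPK1 (PDK1). The package ships a
hand-encoded pair of networks around those targets — the mouse
normal-physiology interactions and the human perturbed-pathway reasoning:

```python
from causenet import celecoxib_case, propagate, compare_perturbation

human, mouse, drug = celecoxib_case()
rh, rm = propagate(human, drug), propagate(mouse, drug)
print("mouse Abeta:", rm.net_sign("a:CHEBI:amyloid-beta"))
print("human Abeta:", rh.net_sign("a:CHEBI:amyloid-beta"))
print("human MTOR:", rh.net_sign("p:HGNC:MTOR"))
print("human insulin resistance:", rh.net_sign("bp:GOBP:insulin resistance"))
print("disagreements:", [d["node"] for d in compare_perturbation(rh, rm)["disagree"]])
```

prints

```
mouse Abeta: -1
human Abeta: 1
human MTOR: 1
human insulin resistance: 1
disagreements: ['a:CHEBI:amyloid-beta', 'bp:GOBP:amyloid-beta clearance', 'bp:GOBP:inflammatory response']
```

i.e. in the mouse network the drug suppresses amyloid-beta (via the
Ptgs2 arm — the intended benefit), while in the human network the same
inhibition disinhibits the AKT1 ⊣ TSC2 → RHEB → MTOR axis, suppressing
autophagy and *raising* predicted amyloid burden, amyloid-clearance loss
and net inflammation — three node-level sign disagreements between the
species for one drug.

The same analyses are available from the shell:

```sh
causenet parse --in model.bel --out model.json
causenet compare --human human.tsv --mouse mouse.tsv --out report.json
causenet expression --human-tables h1.tsv --mouse-tables m1.tsv --out conc.tsv
causenet perturb --model human.bel --drug celecoxib.yaml --out moa.json
causenet simulate models --seed 17 --n-edges 73 --out fixtures/
causenet run --config run.yaml
```

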