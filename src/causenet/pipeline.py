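"""Pipeline orchestration: parse -> compare -> expression -> enrich -> perturb.

A :class:`RunConfig` (usually loaded from YAML) names the inputs; stages
whose inputs are absent are marked skipped, not errors. The canonical
report is JSON; an HTML page is rendered from that JSON. The run timestamp
is isolated in a single field so the rest of the report is byte-comparable
across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import yaml

from . import io as model_io
from .concordance import compare_models, records_to_table
from .enrichment import load_gmt, ora, shared_unique_sets
from .expression import classify_all, concordance_to_table, load_de_table, summarize_concordance
from .orthology import TABLE_THEN_CASEFOLD, OrthologyMap, load_orthology_table
from .perturbation import compare_perturbation, load_drug_action, propagate

logger = logging.getLogger(__name__)

Pathish = Union[str, Path]


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Expression tables are given as {accession: path} per species. ``alpha``
    is the significance threshold on unadjusted p-values; ``max_path_len``
    bounds drug sign propagation; ``q_threshold`` gates enrichment
    significance.
    """

    human_model: Optional[str] = None
    mouse_model: Optional[str] = None
    orthology_table: Optional[str] = None
    ortho_policy: str = TABLE_THEN_CASEFOLD
    human_expression: dict = field(default_factory=dict)
    mouse_expression: dict = field(default_factory=dict)
    gene_sets: Optional[str] = None
    drug: Optional[str] = None
    alpha: float = 0.05
    use_adjusted: bool = False
    q_threshold: float = 0.05
    max_path_len: int = 6
    strict_matching: bool = False
    output_dir: str = "causenet_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Pathish) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate_paths(self) -> None:
        paths = [self.human_model, self.mouse_model, self.orthology_table, self.gene_sets, self.drug]
        paths += list(self.human_expression.values()) + list(self.mouse_expression.values())
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages whose inputs are configured; write the report.

    Returns the report dict; also writes ``report.json``, ``report.html``
    and per-record TSVs into ``config.output_dir``.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(config),
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "skipped": [],
    }

    omap = (
        load_orthology_table(config.orthology_table, policy=config.ortho_policy)
        if config.orthology_table
        else OrthologyMap(policy=config.ortho_policy)
    )

    human = model_io.load_model(config.human_model, species="human") if config.human_model else None
    mouse = model_io.load_model(config.mouse_model, species="mouse") if config.mouse_model else None

    if human or mouse:
        report["model_stats"] = {
            m.species: model_io.model_stats(m) for m in (human, mouse) if m is not None
        }
    else:
        report["skipped"].append("model_stats")

    if human and mouse:
        comparison = compare_models(human, mouse, omap, strict=config.strict_matching)
        records_to_table(comparison).to_csv(outdir / "concordance_records.tsv", sep="\t", index=False)
        report["concordance"] = {
            "counts": comparison.summary.counts,
            "denominators": comparison.summary.denominators,
            "percentages": comparison.summary.percentages,
            "unique_to_mouse_counts": comparison.mouse_only_counts,
        }
    else:
        report["skipped"].append("concordance")

    if config.human_expression and config.mouse_expression:
        h_calls = [
            c
            for acc, path in sorted(config.human_expression.items())
            for c in load_de_table(path, "human", acc)
        ]
        m_calls = [
            c
            for acc, path in sorted(config.mouse_expression.items())
            for c in load_de_table(path, "mouse", acc)
        ]
        conc = classify_all(
            h_calls, m_calls, omap, alpha=config.alpha, use_adjusted=config.use_adjusted
        )
        concordance_to_table(conc).to_csv(outdir / "expression_concordance.tsv", sep="\t", index=False)
        report["expression"] = summarize_concordance(conc.classifications) | {
            "uncovered": conc.uncovered
        }
    else:
        report["skipped"].append("expression")

    if config.gene_sets and human and mouse:
        collection = load_gmt(config.gene_sets)
        genes_h = sorted(
            {e.identifier for e in human.entities if e.namespace.value == "HGNC"}
        )
        genes_m = sorted(
            {e.identifier.upper() for e in mouse.entities if e.namespace.value == "MGI"}
        )
        res_h, res_m = ora(genes_h, collection), ora(genes_m, collection)
        res_h.to_csv(outdir / "enrichment_human.tsv", sep="\t", index=False)
        res_m.to_csv(outdir / "enrichment_mouse.tsv", sep="\t", index=False)
        report["enrichment"] = shared_unique_sets(res_h, res_m, config.q_threshold)
    else:
        report["skipped"].append("enrichment")

    if config.drug and human and mouse:
        action = load_drug_action(config.drug)
        res_h = propagate(human, action, config.max_path_len, omap)
        res_m = propagate(mouse, action, config.max_path_len, omap)
        agreement = compare_perturbation(res_h, res_m, omap)
        report["perturbation"] = {
            "drug": action.drug,
            "human_signs": {k: v.net_sign for k, v in res_h.outcomes.items()},
            "mouse_signs": {k: v.net_sign for k, v in res_m.outcomes.items()},
            "agreement": agreement,
        }
    else:
        report["skipped"].append("perturbation")

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "report.html").write_text(render_html(report))
    return report


def render_html(report: dict) -> str:
    """Minimal HTML render of the canonical JSON report."""
    body = json.dumps({k: v for k, v in report.items() if k != "generated_at"}, indent=2, default=str)
    return (
        "<!doctype html><html><head><meta charset='utf-8'>"
        "<title>causenet report</title></head><body>"
        f"<h1>causenet report</h1><p>generated: {report.get('generated_at', '')}</p>"
        f"<pre>{body}</pre></body></html>\n"
    )
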