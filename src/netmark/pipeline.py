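"""End-to-end orchestration: DE -> condition network -> screen -> enrichment.

Stages compose through plain-text files (TSV tables, GMT, JSON manifest), so
each can also be run on its own.  A run is fully determined by its inputs and
configuration; rerunning reproduces every table byte for byte (the manifest
carries a timestamp, which is the one field that differs).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .datasets import read_expression, read_id_list
from .diffexpr import run_differential, write_results
from .enrichment import (
    enrich_gene_sets,
    read_gmt,
    top_k_report,
    write_records,
)
from .network import (
    build_condition_network,
    load_reference_network,
    score_all,
    write_edge_list,
    write_scores,
)
from .screen import (
    BiomarkerCall,
    ScreenConfig,
    annotate_known,
    screen_biomarkers,
    write_calls,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and an exit-code hint."""

    def __init__(self, stage: str, message: str, exit_code: int = 2):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    mirna_expr: str = ""
    mirna_design: str = ""
    mrna_expr: str = ""
    mrna_design: str = ""
    reference_edges: str = ""
    tf_list: str = ""
    gene_sets: str = ""
    known_biomarkers: str | None = None
    out_dir: str = "netmark_out"
    alpha_de: float = 0.05
    alpha_screen: float = 0.05
    alpha_enrich: float = 0.05
    restrict_genes: bool = True
    paired: bool = False
    normalization: str = "quantile"
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_enrich"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.alpha_screen <= 0:
            raise ValueError("alpha_screen must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a key-value YAML config; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    n_de_mirnas: int
    n_de_genes: int
    n_network_edges: int
    n_scored_mirnas: int
    n_candidates: int
    n_novel_candidates: int
    n_significant_sets: int
    version: str = __version__
    timestamp: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _require(path: str | None, stage: str) -> str:
    if not path or not Path(path).exists():
        raise PipelineError(stage, f"input file missing: {path!r}", exit_code=2)
    return path


def _downstream(
    config: PipelineConfig,
    de_mirnas: set[str],
    de_genes: set[str],
    out: Path,
) -> tuple[list[BiomarkerCall], int, int]:
    """Network scoring, screen, annotation and enrichment shared by both entry points."""
    reference = load_reference_network(
        _require(config.reference_edges, "network"),
        _require(config.tf_list, "network"),
    )
    condition = build_condition_network(
        reference, de_mirnas, de_genes, restrict_genes=config.restrict_genes
    )
    if not condition.mirna_ids:
        raise PipelineError(
            "network", "no DE miRNA maps onto the reference network", exit_code=3
        )
    write_edge_list(condition, out / "condition_network.tsv")
    scores = score_all(condition)
    if len(scores) < 6:
        raise PipelineError(
            "screen",
            f"only {len(scores)} scored miRNAs; need >= 6 for a background",
            exit_code=3,
        )
    calls = screen_biomarkers(scores, ScreenConfig(alpha=config.alpha_screen))
    calls = annotate_known(calls, config.known_biomarkers)
    write_scores(scores, out / "scores.tsv")
    write_calls(calls, out / "candidates.tsv")

    candidates = [c for c in calls if c.is_candidate]
    query = set().union(*(c.targets for c in candidates)) if candidates else set()
    n_sig = 0
    if config.gene_sets and Path(config.gene_sets).exists() and query:
        collection = read_gmt(config.gene_sets, universe=reference.gene_ids)
        records = enrich_gene_sets(query, collection, alpha=config.alpha_enrich)
        write_records(records, out / "enrichment.tsv")
        write_records(top_k_report(records, config.top_k), out / "enrichment_top.tsv")
        n_sig = sum(1 for r in records if r.p_adj < config.alpha_enrich)
    return calls, condition.n_edges, n_sig


def _finish(
    config: PipelineConfig,
    de_mirnas: set[str],
    de_genes: set[str],
    calls: list[BiomarkerCall],
    n_edges: int,
    n_sig: int,
    out: Path,
) -> RunManifest:
    candidates = [c for c in calls if c.is_candidate]
    manifest = RunManifest(
        config=asdict(config),
        n_de_mirnas=len(de_mirnas),
        n_de_genes=len(de_genes),
        n_network_edges=n_edges,
        n_scored_mirnas=len(calls),
        n_candidates=len(candidates),
        n_novel_candidates=sum(1 for c in candidates if not c.is_known),
        n_significant_sets=n_sig,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write every intermediate table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    mirna_ds = read_expression(
        _require(config.mirna_expr, "diffexpr"), _require(config.mirna_design, "diffexpr")
    )
    mrna_ds = read_expression(
        _require(config.mrna_expr, "diffexpr"), _require(config.mrna_design, "diffexpr")
    )
    mirna_res, de_mirnas = run_differential(
        mirna_ds, config.alpha_de, config.normalization, paired=config.paired
    )
    mrna_res, de_genes = run_differential(
        mrna_ds, config.alpha_de, config.normalization, paired=config.paired
    )
    write_results(mirna_res, out / "de_mirnas.tsv")
    write_results(mrna_res, out / "de_genes.tsv")
    logger.info(
        "diffexpr: %d DE miRNAs, %d DE genes (%.1fs)",
        len(de_mirnas),
        len(de_genes),
        time.time() - t0,
    )
    if not de_mirnas:
        raise PipelineError("diffexpr", "no differentially expressed miRNA", exit_code=3)
    if not de_genes and config.restrict_genes:
        raise PipelineError("diffexpr", "no differentially expressed gene", exit_code=3)

    calls, n_edges, n_sig = _downstream(config, de_mirnas, de_genes, out)
    return _finish(config, de_mirnas, de_genes, calls, n_edges, n_sig, out)


def scoring_only(
    config: PipelineConfig,
    de_mirna_file: str | Path,
    de_gene_file: str | Path | None = None,
) -> tuple[list[BiomarkerCall], RunManifest]:
    """Skip the expression stages: score precomputed DE lists.

    ``de_gene_file`` may be omitted when ``restrict_genes`` is off.  When the
    supplied network already contains only pre-screened miRNAs, set
    ``alpha_screen >= 1`` to carry every scored miRNA forward as a candidate.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    de_mirnas = set(read_id_list(_require(str(de_mirna_file), "scoring")))
    if not de_mirnas:
        raise PipelineError("scoring", "DE miRNA list is empty", exit_code=3)
    de_genes: set[str] = set()
    if config.restrict_genes:
        de_genes = set(read_id_list(_require(str(de_gene_file), "scoring")))
    calls, n_edges, n_sig = _downstream(config, de_mirnas, de_genes, out)
    manifest = _finish(config, de_mirnas, de_genes, calls, n_edges, n_sig, out)
    return calls, manifest
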