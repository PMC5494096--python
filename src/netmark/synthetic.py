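"""Synthetic study generator: expression, network, TF annotation, gene sets.

Emulates the shapes of the real study inputs — a miRNA assay with 47 tumor /
47 control samples, an mRNA assay with 33 / 32, a reference miRNA->gene
interactome with heterogeneous out-degree, a TF catalogue and a GMT gene-set
collection — with planted, exactly recoverable ground truth:

* differential miRNAs/genes shifted by +-effect_size log2 units in cases;
* "planted biomarker" miRNAs endowed with a fixed number of targets nobody
  else regulates (high NOG by construction) and a TF-rich target set
  (high TFP by construction);
* one gene set deliberately loaded with planted-biomarker targets so that
  enrichment recovery is testable.

Everything is driven by a single master seed; each artifact (network, miRNA
matrix, mRNA matrix, gene sets) consumes its own child RNG stream, so
regenerating one artifact never perturbs the others and identical configs
yield byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, write_expression
from .enrichment import GeneSetCollection, write_gmt
from .network import RegulatoryNetwork, write_edge_list


class InfeasibleConfigError(ValueError):
    """The requested planting cannot be realised with the given universe."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Sample counts default to the real study's assay shapes (miRNA 47/47,
    mRNA 33/32).  Expression is generated directly on log2 scale around
    ``baseline`` with residual SD ``noise_sd``; differential features are
    shifted by +-``effect_size`` in cases with a random recorded sign.
    """

    n_mirnas: int = 100
    n_genes: int = 400
    n_tfs: int = 40
    n_case_mirna: int = 47
    n_control_mirna: int = 47
    n_case_mrna: int = 33
    n_control_mrna: int = 32
    frac_de_mirna: float = 0.25
    frac_de_gene: float = 0.25
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline: float = 8.0
    mean_out_degree: float = 8.0
    n_planted_biomarkers: int = 3
    planted_unique_targets: int = 5
    planted_tf_frac: float = 0.6
    n_gene_sets: int = 50
    gene_set_size: int = 20
    loaded_overlap_frac: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de_mirna", "frac_de_gene", "planted_tf_frac", "loaded_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_tfs > self.n_genes:
            raise InfeasibleConfigError("n_tfs exceeds the gene universe")
        if self.n_planted_biomarkers * self.planted_unique_targets > self.n_genes:
            raise InfeasibleConfigError(
                "not enough genes to give every planted biomarker its unique targets"
            )
        if self.n_planted_biomarkers > self.n_mirnas:
            raise InfeasibleConfigError("more planted biomarkers than miRNAs")
        for name in ("n_case_mirna", "n_control_mirna", "n_case_mrna", "n_control_mrna"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")


@dataclass
class GroundTruth:
    """Planted truth labels; signs map each DE feature to its case-shift sign."""

    de_mirnas: frozenset[str]
    de_genes: frozenset[str]
    planted_biomarkers: frozenset[str]
    tf_genes: frozenset[str]
    de_mirna_signs: dict[str, int] = field(default_factory=dict)
    de_gene_signs: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_mirnas": sorted(self.de_mirnas),
            "de_genes": sorted(self.de_genes),
            "planted_biomarkers": sorted(self.planted_biomarkers),
            "tf_genes": sorted(self.tf_genes),
            "de_mirna_signs": dict(sorted(self.de_mirna_signs.items())),
            "de_gene_signs": dict(sorted(self.de_gene_signs.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _mirna_name(i: int) -> str:
    return f"miR-syn-{i:04d}"


def _gene_name(i: int) -> str:
    return f"SYNG{i:04d}"


def _streams(config: SyntheticConfig) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(config.seed).spawn(4)


@lru_cache(maxsize=16)
def _blueprint(config: SyntheticConfig) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Network, TF flags and DE membership, all from the network stream.

    DE gene selection deliberately includes every target of a planted
    biomarker, so that the condition network (restricted to DE genes) retains
    the planted structure the downstream screen is supposed to recover.
    """
    rng = np.random.default_rng(_streams(config)[0])
    mirnas = [_mirna_name(i) for i in range(config.n_mirnas)]
    genes = [_gene_name(i) for i in range(config.n_genes)]

    planted = sorted(
        rng.choice(mirnas, size=config.n_planted_biomarkers, replace=False).tolist()
    )
    n_unique_total = config.n_planted_biomarkers * config.planted_unique_targets
    unique_pool = rng.choice(genes, size=n_unique_total, replace=False).tolist()
    shared_pool = sorted(set(genes) - set(unique_pool))
    unique_slices = {
        m: unique_pool[i * config.planted_unique_targets : (i + 1) * config.planted_unique_targets]
        for i, m in enumerate(planted)
    }

    edges: set[tuple[str, str]] = set()
    targets: dict[str, set[str]] = {}
    for m in mirnas:
        k = int(rng.poisson(config.mean_out_degree))
        k = min(k, len(shared_pool))
        tgt = set(rng.choice(shared_pool, size=k, replace=False).tolist()) if k else set()
        if m in unique_slices:
            tgt |= set(unique_slices[m])
        targets[m] = tgt
        edges |= {(m, g) for g in tgt}

    # TF flags: enough of each planted miRNA's targets (unique slice first) to
    # reach the requested TF fraction, then random fill up to exactly n_tfs.
    forced_tfs: set[str] = set()
    for m in planted:
        tgt = targets[m]
        need = math.ceil(config.planted_tf_frac * len(tgt))
        have = len(tgt & forced_tfs)
        deficit = need - have
        if deficit > 0:
            preferred = [g for g in unique_slices[m] if g not in forced_tfs]
            extra = sorted(tgt - forced_tfs - set(preferred))
            pool = preferred + extra
            forced_tfs |= set(pool[:deficit])
    if len(forced_tfs) > config.n_tfs:
        raise InfeasibleConfigError(
            f"planting requires {len(forced_tfs)} TFs but n_tfs={config.n_tfs}"
        )
    fill_pool = sorted(set(genes) - forced_tfs)
    fill = rng.choice(fill_pool, size=config.n_tfs - len(forced_tfs), replace=False)
    tf_genes = frozenset(forced_tfs) | frozenset(fill.tolist())

    # DE membership: planted biomarkers are always differential; their targets
    # are always differential genes.
    n_de_mirna = round(config.frac_de_mirna * config.n_mirnas)
    n_de_mirna = max(n_de_mirna, config.n_planted_biomarkers)
    other_mirnas = sorted(set(mirnas) - set(planted))
    de_mirnas = set(planted) | set(
        rng.choice(other_mirnas, size=n_de_mirna - len(planted), replace=False).tolist()
    )
    planted_targets = set().union(*(targets[m] for m in planted)) if planted else set()
    n_de_gene = round(config.frac_de_gene * config.n_genes)
    n_de_gene = max(n_de_gene, len(planted_targets))
    other_genes = sorted(set(genes) - planted_targets)
    de_genes = planted_targets | set(
        rng.choice(other_genes, size=n_de_gene - len(planted_targets), replace=False).tolist()
    )
    if config.frac_de_mirna == 0 and not planted:
        de_mirnas = set()
    if config.frac_de_gene == 0 and not planted_targets:
        de_genes = set()

    network = RegulatoryNetwork(
        mirna_ids=frozenset(mirnas),
        gene_ids=frozenset(genes),
        edges=frozenset(edges),
        tf_genes=tf_genes,
    )
    truth = GroundTruth(
        de_mirnas=frozenset(de_mirnas),
        de_genes=frozenset(de_genes),
        planted_biomarkers=frozenset(planted),
        tf_genes=tf_genes,
    )
    return network, truth


def generate_reference_network(config: SyntheticConfig) -> RegulatoryNetwork:
    """Bipartite reference interactome with Poisson out-degrees and planting.

    Every planted biomarker receives ``planted_unique_targets`` genes of
    in-degree 1 (no other miRNA may target them) and a target set whose TF
    fraction is at least ``planted_tf_frac``.
    """
    return _blueprint(config)[0]


def generate_ground_truth(config: SyntheticConfig) -> GroundTruth:
    return _blueprint(config)[1]


def generate_expression_dataset(
    config: SyntheticConfig, truth_role: str
) -> tuple[ExpressionDataset, GroundTruth]:
    """Two-group log2 expression matrix for one assay ("mirna" or "mrna").

    Null features are i.i.d. Normal(baseline, noise_sd); differential
    features get a +-effect_size shift in cases, sign drawn per feature and
    recorded in the returned GroundTruth.
    """
    if truth_role not in ("mirna", "mrna"):
        raise ValueError("truth_role must be 'mirna' or 'mrna'")
    network, truth = _blueprint(config)
    if truth_role == "mirna":
        features = sorted(network.mirna_ids)
        de_set = truth.de_mirnas
        n_case, n_control = config.n_case_mirna, config.n_control_mirna
        stream = _streams(config)[1]
    else:
        features = sorted(network.gene_ids)
        de_set = truth.de_genes
        n_case, n_control = config.n_case_mrna, config.n_control_mrna
        stream = _streams(config)[2]
    rng = np.random.default_rng(stream)
    n_samples = n_case + n_control
    values = config.baseline + config.noise_sd * rng.standard_normal(
        (len(features), n_samples)
    )
    signs = {f: int(rng.choice([-1, 1])) for f in features if f in de_set}
    fidx = {f: i for i, f in enumerate(features)}
    for f, sign in signs.items():
        values[fidx[f], :n_case] += sign * config.effect_size
    sample_ids = [f"{truth_role}_case_{i:02d}" for i in range(n_case)] + [
        f"{truth_role}_ctrl_{i:02d}" for i in range(n_control)
    ]
    design = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=sample_ids, name="group"
    )
    ds = ExpressionDataset(
        values=pd.DataFrame(values, index=features, columns=sample_ids),
        design=design,
    )
    out_truth = replace(
        truth,
        de_mirna_signs=signs if truth_role == "mirna" else dict(truth.de_mirna_signs),
        de_gene_signs=signs if truth_role == "mrna" else dict(truth.de_gene_signs),
    )
    return ds, out_truth


LOADED_SET_NAME = "SET_LOADED"


def generate_gene_sets(
    config: SyntheticConfig,
    network: RegulatoryNetwork,
    truth: GroundTruth,
) -> GeneSetCollection:
    """GMT-writable collection over the network's gene universe.

    The first set (``SET_LOADED``) is loaded with planted-biomarker targets at
    fraction ``loaded_overlap_frac`` of its size (recorded in the set's
    description); the remaining sets are uniform draws.
    """
    universe = sorted(network.gene_ids)
    if config.gene_set_size > len(universe):
        raise ValueError("gene_set_size exceeds the gene universe")
    rng = np.random.default_rng(_streams(config)[3])
    planted_targets = sorted(
        set().union(
            *(network.targets_of(m) for m in truth.planted_biomarkers)
        )
        if truth.planted_biomarkers
        else set()
    )
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_loaded = min(
        round(config.loaded_overlap_frac * config.gene_set_size), len(planted_targets)
    )
    if config.n_gene_sets > 0:
        loaded = rng.choice(planted_targets, size=n_loaded, replace=False).tolist() if n_loaded else []
        rest_pool = sorted(set(universe) - set(loaded))
        filler = rng.choice(
            rest_pool, size=config.gene_set_size - n_loaded, replace=False
        ).tolist()
        sets[LOADED_SET_NAME] = frozenset(loaded) | frozenset(filler)
        descriptions[LOADED_SET_NAME] = (
            f"planted-target overlap fraction {n_loaded / config.gene_set_size:.3f}"
        )
    for i in range(1, config.n_gene_sets):
        members = rng.choice(universe, size=config.gene_set_size, replace=False)
        sets[f"SET_{i:04d}"] = frozenset(members.tolist())
        descriptions[f"SET_{i:04d}"] = "uniform draw"
    return GeneSetCollection(
        sets=sets, universe=frozenset(universe), descriptions=descriptions
    )


def write_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input file for this config; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network = generate_reference_network(config)
    mirna_ds, truth_m = generate_expression_dataset(config, "mirna")
    mrna_ds, truth_g = generate_expression_dataset(config, "mrna")
    truth = replace(
        truth_m, de_gene_signs=dict(truth_g.de_gene_signs)
    )
    collection = generate_gene_sets(config, network, truth)
    paths = {
        "mirna_expr": out / "mirna_expression.tsv",
        "mirna_design": out / "mirna_design.tsv",
        "mrna_expr": out / "mrna_expression.tsv",
        "mrna_design": out / "mrna_design.tsv",
        "reference_edges": out / "reference_edges.tsv",
        "tf_list": out / "tf_genes.txt",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    write_expression(mirna_ds, paths["mirna_expr"], paths["mirna_design"])
    write_expression(mrna_ds, paths["mrna_expr"], paths["mrna_design"])
    write_edge_list(network, paths["reference_edges"])
    paths["tf_list"].write_text("".join(f"{g}\n" for g in sorted(network.tf_genes)))
    write_gmt(collection, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
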