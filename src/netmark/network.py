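"""Bipartite miRNA->mRNA regulatory networks and structural biomarker indices.

The two per-miRNA indices computed here quantify how irreplaceable a miRNA is
inside a condition-specific (disease) regulatory network:

* **NOG** — the number of genes uniquely targeted by the miRNA, i.e. targets
  whose in-degree in the network is exactly 1.  A regulation that no other
  miRNA can compensate for is a candidate point of failure, hence a candidate
  biomarker signal.
* **TFP** — the transcription-factor percentage: the fraction of the miRNA's
  targets annotated as transcription factors.  A TF-rich target set amplifies
  the downstream impact of the miRNA's dysregulation.

Both indices are defined *within* the network they are computed on: NOG
uniqueness refers to the miRNAs present in that network, not to any larger
reference interactome.  A miRNA retained with an empty target set scores
NOG = 0 and TFP = 0.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping


def normalize_mirna_id(raw: str) -> str:
    """Normalize a miRNA identifier to lower-case ``miR-`` style.

    Species prefixes (``hsa-``) are stripped, the body is lower-cased and the
    canonical ``miR`` capitalization restored.  Arm suffixes (``-3p``/``-5p``)
    are preserved verbatim — the two arms are distinct molecules.
    """
    s = raw.strip()
    if s.lower().startswith("hsa-"):
        s = s[4:]
    s = s.lower()
    if s.startswith("mir-"):
        s = "miR-" + s[4:]
    return s


def strip_arm(mirna_id: str) -> str:
    """Drop a trailing -3p/-5p arm suffix, for arm-insensitive matching."""
    low = mirna_id.lower()
    for suffix in ("-3p", "-5p"):
        if low.endswith(suffix):
            return mirna_id[: -len(suffix)]
    return mirna_id


def normalize_gene_id(raw: str) -> str:
    return raw.strip().upper()


def round_tfp(value: float) -> float:
    """Round a TF fraction to 2 decimals, half away from zero (0.125 -> 0.13)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A bipartite miRNA->gene edge set with TF annotation on the gene side.

    ``tf_genes`` may contain symbols that do not appear in any edge (a TF
    catalogue is usually broader than one network); only the intersection with
    a miRNA's target set ever enters a score.
    """

    mirna_ids: frozenset[str]
    gene_ids: frozenset[str]
    edges: frozenset[tuple[str, str]]
    tf_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if m not in self.mirna_ids or g not in self.gene_ids:
                raise ValueError(f"edge ({m}, {g}) references an undeclared node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, mirna_id: str) -> frozenset[str]:
        if mirna_id not in self.mirna_ids:
            raise KeyError(f"unknown miRNA: {mirna_id!r}")
        return frozenset(g for m, g in self.edges if m == mirna_id)

    def gene_in_degree(self) -> Counter:
        """In-degree of every gene (genes with no surviving edge count 0)."""
        deg = Counter(g for _, g in self.edges)
        for g in self.gene_ids:
            deg.setdefault(g, 0)
        return deg


@dataclass
class MiRNAStructuralScore:
    """Per-miRNA structural indices on a condition network.

    ``p_nog`` / ``p_tfp`` are filled by the biomarker screen; they stay None
    until then.
    """

    mirna_id: str
    targets: frozenset[str]
    nog: int
    tfp: float
    p_nog: float | None = None
    p_tfp: float | None = None


def load_reference_network(
    edge_file: str | Path, tf_file: str | Path | None = None
) -> RegulatoryNetwork:
    """Read a two-column miRNA->gene edge list TSV plus an optional TF list.

    An optional header row ``mirna_id<TAB>gene_id`` is recognised and skipped.
    Duplicate edges collapse; identifiers are normalized (genes upper-case,
    miRNAs ``miR-`` style).  TF symbols absent from every edge are retained —
    harmless, they never intersect a target set.
    """
    edges: set[tuple[str, str]] = set()
    with open(edge_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{edge_file}: malformed edge on line {lineno}: {line!r}"
                )
            if lineno == 1 and parts[0].strip().lower() == "mirna_id":
                continue
            edges.add((normalize_mirna_id(parts[0]), normalize_gene_id(parts[1])))
    tf_genes: frozenset[str] = frozenset()
    if tf_file is not None:
        with open(tf_file) as fh:
            tf_genes = frozenset(
                normalize_gene_id(line) for line in fh if line.strip()
            )
    return RegulatoryNetwork(
        mirna_ids=frozenset(m for m, _ in edges),
        gene_ids=frozenset(g for _, g in edges),
        edges=frozenset(edges),
        tf_genes=tf_genes,
    )


def build_condition_network(
    reference: RegulatoryNetwork,
    de_mirnas: Iterable[str],
    de_genes: Iterable[str] | None = None,
    restrict_genes: bool = True,
) -> RegulatoryNetwork:
    """Map differentially expressed features onto the reference interactome.

    Edges are kept when the miRNA is differentially expressed; with
    ``restrict_genes`` (the default) the gene must be differentially expressed
    too, matching the dysregulated-network framing where both endpoints are
    condition-specific.  DE miRNAs present in the reference are retained even
    when all their edges drop (they score NOG = 0, TFP = 0); genes survive
    only through an edge.
    """
    de_m = {normalize_mirna_id(m) for m in de_mirnas}
    kept_mirnas = de_m & reference.mirna_ids
    if not kept_mirnas:
        warnings.warn("no differentially expressed miRNA maps onto the reference")
    if restrict_genes:
        if de_genes is None:
            raise ValueError("restrict_genes=True requires a DE gene set")
        de_g = {normalize_gene_id(g) for g in de_genes}
        edges = {
            (m, g) for m, g in reference.edges if m in kept_mirnas and g in de_g
        }
    else:
        edges = {(m, g) for m, g in reference.edges if m in kept_mirnas}
    return RegulatoryNetwork(
        mirna_ids=frozenset(kept_mirnas),
        gene_ids=frozenset(g for _, g in edges),
        edges=frozenset(edges),
        tf_genes=reference.tf_genes,
    )


def compute_nog(network: RegulatoryNetwork, mirna_id: str) -> int:
    """Number of the miRNA's targets that no other miRNA in the network targets."""
    targets = network.targets_of(mirna_id)
    indeg = Counter(g for _, g in network.edges)
    return sum(1 for g in targets if indeg[g] == 1)


def compute_tfp(network: RegulatoryNetwork, mirna_id: str) -> float:
    """TF fraction of the miRNA's target set (0.0 for an empty target set).

    Returns the exact fraction; :func:`round_tfp` gives the 2-decimal reported
    form.
    """
    targets = network.targets_of(mirna_id)
    if not targets:
        return 0.0
    return len(targets & network.tf_genes) / len(targets)


def score_all(network: RegulatoryNetwork) -> list[MiRNAStructuralScore]:
    """Score every miRNA in the network.

    Output order is deterministic: descending NOG, then descending TFP, then
    lexicographic miRNA id.
    """
    indeg = Counter(g for _, g in network.edges)
    scores = []
    for m in network.mirna_ids:
        targets = frozenset(g for mm, g in network.edges if mm == m)
        nog = sum(1 for g in targets if indeg[g] == 1)
        tfp = len(targets & network.tf_genes) / len(targets) if targets else 0.0
        scores.append(MiRNAStructuralScore(m, targets, nog, tfp))
    scores.sort(key=lambda s: (-s.nog, -s.tfp, s.mirna_id))
    return scores


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in sorted(network.edges):
            fh.write(f"{m}\t{g}\n")


def write_scores(scores: Iterable[MiRNAStructuralScore], path: str | Path) -> None:
    """Write a score table TSV (TFP to 2 decimals, p-values to 6 significant digits)."""

    def fmt_p(p: float | None) -> str:
        return "" if p is None else f"{p:.6g}"

    with open(path, "w") as fh:
        fh.write("mirna_id\tnog\tp_nog\ttfp\tp_tfp\ttargets\n")
        for s in scores:
            fh.write(
                f"{s.mirna_id}\t{s.nog}\t{fmt_p(s.p_nog)}\t{round_tfp(s.tfp):.2f}"
                f"\t{fmt_p(s.p_tfp)}\t{';'.join(sorted(s.targets))}\n"
            )
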