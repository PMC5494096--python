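"""Bundled worked-example fixtures.

The package ships a small candidate subnetwork — the nine screened miRNAs of
the NSCLC adenocarcinoma study with their published target lists — plus a
pinned TF annotation covering the TF members that are inferable from the
published TF percentages (FOS, FOSB, KLF4, KLF9, ZFP36, SPDEF, HOXA5, ETS2),
and a curated list of literature-reported adenocarcinoma biomarker miRNAs.
Two rows (miR-567, miR-590-3p) have TF members that cannot be inferred from
the published numbers; their TFP on this fixture is accordingly lower than
the published value.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .network import RegulatoryNetwork, load_reference_network


def _data_path(name: str) -> Path:
    return Path(resources.files("netmark.data") / name)


def candidate_edges_path() -> Path:
    """Edge-list TSV of the nine screened miRNAs and their published targets."""
    return _data_path("candidate_targets_edges.tsv")


def tf_annotation_path() -> Path:
    """Pinned TF gene list reproducing the published TF percentages."""
    return _data_path("tf_annotation.txt")


def known_biomarkers_path() -> Path:
    """Curated literature-reported adenocarcinoma biomarker miRNAs (official ids)."""
    return _data_path("known_biomarkers.txt")


def candidate_network() -> RegulatoryNetwork:
    """The nine-miRNA candidate subnetwork with TF flags."""
    return load_reference_network(candidate_edges_path(), tf_annotation_path())
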