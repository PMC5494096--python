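"""Two-group expression containers and plain-text I/O.

Expression values are log2 scale throughout: a features x samples matrix plus
a per-sample group label (``case`` / ``control``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("case", "control")


@dataclass
class ExpressionDataset:
    """log2 expression matrix (features x samples) with a two-group design.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    ``design`` maps each sample id to ``case`` or ``control``.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("sample ids of matrix and design do not match")
        bad = set(self.design.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        for g in GROUPS:
            if (self.design == g).sum() < 2:
                raise ValueError(f"need >=2 samples in group {g!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(values=values, design=self.design.copy())


def read_expression(expr_path: str | Path, design_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV (first column ``feature_id``) and design TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col="feature_id")
    design_df = pd.read_csv(design_path, sep="\t")
    design = design_df.set_index("sample_id")["group"]
    values = values[list(design.index)]
    return ExpressionDataset(values=values, design=design)


def write_expression(ds: ExpressionDataset, expr_path: str | Path, design_path: str | Path) -> None:
    out = ds.values.copy()
    out.index.name = "feature_id"
    out.to_csv(expr_path, sep="\t", float_format="%.6g")
    design = ds.design.rename("group").rename_axis("sample_id").reset_index()
    design.to_csv(design_path, sep="\t", index=False)


def read_geo_series_matrix(path: str | Path, case_samples: list[str], control_samples: list[str]) -> ExpressionDataset:
    """Loader hook for GEO series-matrix text files.

    Metadata lines prefixed ``!`` are skipped; the remaining block must be the
    tab-separated expression table with sample accessions as columns.  The
    caller supplies the case/control split (series-matrix metadata encodes it
    too inconsistently to parse generically).
    """
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("!") and ln.strip()]
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    table.index.name = "feature_id"
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [c.strip('"') for c in table.columns]
    wanted = list(case_samples) + list(control_samples)
    missing = [s for s in wanted if s not in table.columns]
    if missing:
        raise ValueError(f"samples absent from series matrix: {missing}")
    design = pd.Series(
        ["case"] * len(case_samples) + ["control"] * len(control_samples),
        index=wanted,
        name="group",
    )
    return ExpressionDataset(values=table[wanted], design=design)


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line, blanks ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
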