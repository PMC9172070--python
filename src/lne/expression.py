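"""Expression matrices and sample annotations.

An :class:`ExpressionStudy` bundles a genes x samples expression matrix
with the sample annotation table that splits samples into the reference
cohort and the staged case samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionStudy", "read_expression", "read_annotations", "write_expression", "write_annotations"]

REFERENCE_LABEL = "reference"
CASE_LABEL = "case"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix (tab- or comma-delimited, header row
    of sample IDs, first column of gene symbols)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene symbols in {path}: {dupes}")
    return df.astype(float)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table with columns sample_id, group, stage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {sorted(missing)}")
    if "stage" not in df.columns:
        df["stage"] = ""
    return df[["sample_id", "group", "stage"]]


@dataclass
class ExpressionStudy:
    """Expression matrix plus its reference/case sample split.

    ``expression`` is genes x samples. ``groups`` maps every sample ID to
    ``"reference"`` or ``"case"``; ``stages`` maps case sample IDs to their
    stage label.
    """

    expression: pd.DataFrame
    groups: dict[str, str]
    stages: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = set(self.expression.columns)
        unknown = set(self.groups) - samples
        if unknown:
            raise ValueError(f"annotated samples missing from expression matrix: {sorted(unknown)[:5]}")
        bad = {g for g in self.groups.values()} - {REFERENCE_LABEL, CASE_LABEL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)} (expected reference/case)")

    @classmethod
    def from_frames(cls, expression: pd.DataFrame, annotations: pd.DataFrame) -> "ExpressionStudy":
        groups = dict(zip(annotations["sample_id"], annotations["group"]))
        stages = {
            s: st
            for s, g, st in zip(annotations["sample_id"], annotations["group"], annotations["stage"])
            if g == CASE_LABEL
        }
        keep = [c for c in expression.columns if c in groups]
        dropped = len(expression.columns) - len(keep)
        if dropped:
            logger.warning("dropping %d unannotated expression columns", dropped)
        return cls(expression=expression[keep], groups=groups, stages=stages)

    @property
    def reference_samples(self) -> list[str]:
        return [s for s in self.expression.columns if self.groups.get(s) == REFERENCE_LABEL]

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.expression.columns if self.groups.get(s) == CASE_LABEL]

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    def drop_incomplete_genes(self) -> list[str]:
        """Remove genes with missing values; returns the dropped symbols."""
        mask = self.expression.isna().any(axis=1)
        dropped = list(self.expression.index[mask])
        if dropped:
            logger.warning("dropping %d genes with missing values: %s%s",
                           len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
            self.expression = self.expression.loc[~mask]
        return dropped

    def stage_of(self, sample: str) -> str:
        return self.stages.get(sample, "")


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def write_annotations(study: ExpressionStudy, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "group": study.groups[s], "stage": study.stages.get(s, "")}
        for s in study.expression.columns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
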