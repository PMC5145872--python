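"""Core data container for a two-group expression study.

The whole pipeline operates on a single object: a log2-scale expression
matrix (genes x samples) together with a two-level sample grouping
(case vs. control, e.g. disease vs. healthy blood donors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy"]


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus a two-group sample annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (unique index), samples in columns, log2 scale,
        no missing values.
    groups : pandas.Series
        Maps every sample id to one of exactly two group labels.
    case_label : str, optional
        Which group label is the "case" (disease) group.  If omitted the
        labels must literally be ``{"case", "control"}``.
    """

    values: pd.DataFrame
    groups: pd.Series
    case_label: str | None = None
    control_label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.groups = self.groups.reindex(self.values.columns)
        missing = self.groups.index[self.groups.isna()].tolist()
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        labels = sorted(self.groups.unique().tolist())
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        if self.case_label is None:
            if set(labels) != {"case", "control"}:
                raise ValueError(
                    f"group labels {labels} are not case/control; pass case_label"
                )
            self.case_label = "case"
        elif self.case_label not in labels:
            raise ValueError(f"case_label {self.case_label!r} not among groups {labels}")
        self.control_label = next(l for l in labels if l != self.case_label)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, label: str) -> list[str]:
        return self.groups.index[self.groups == label].tolist()

    @property
    def trait(self) -> pd.Series:
        """0/1 indicator per sample: 1 for case samples."""
        return (self.groups == self.case_label).astype(int)

    def matrix(self, label: str | None = None) -> pd.DataFrame:
        """Expression sub-matrix for one group (or all samples)."""
        if label is None:
            return self.values
        return self.values[self.samples_of(label)]

    def subset_genes(self, genes: list[str]) -> "ExpressionStudy":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in study: {missing[:5]}")
        return ExpressionStudy(self.values.loc[genes], self.groups.copy(), self.case_label)
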