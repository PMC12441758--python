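"""Significance filtering of log2 fold-change tables.

An entry survives when |log2FC| exceeds the fold-change cut-off strictly
AND its p-value falls below the p cut-off strictly; every other entry is
set to zero.  Genes whose entire row becomes zero are dropped, so each
retained gene was significant in at least one condition.  The zero-filled
matrix of survivors is what gets embedded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GeneTable

__all__ = ["FilteredMatrix", "SignificanceFilter", "filter_significant"]


@dataclass
class FilteredMatrix:
    """Gene × condition log2FC matrix with non-significant entries zeroed.

    Invariant: every row has at least one non-zero entry, and every
    non-zero entry passed both cut-offs.
    """

    values: pd.DataFrame  # index: gene_id, columns: conditions

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_gene_table(self, pval: float = 0.0) -> GeneTable:
        """View the filtered matrix as a GeneTable (all entries maximally significant).

        Used for idempotence: re-filtering keeps exactly the non-zero
        entries, so ``filter(filter(t)) == filter(t)``.
        """
        p = pd.DataFrame(
            np.where(self.values.to_numpy() != 0.0, pval, 1.0),
            index=self.values.index,
            columns=self.values.columns,
        )
        return GeneTable(lfc=self.values.copy(), pval=p)


class SignificanceFilter(BaseEstimator, TransformerMixin):
    """Transformer zeroing non-significant log2FC entries and dropping empty rows.

    Parameters
    ----------
    lfc_cut : float, default 1.0
        Absolute log2 fold-change must exceed this strictly.
    p_cut : float, default 0.05
        p-value must fall below this strictly.

    Attributes
    ----------
    mask_ : pandas.DataFrame of bool
        Per-entry significance decisions for the fitted table.
    retained_ids_ : list of str
        Gene ids with at least one significant entry, input order kept.
    n_retained_ : int
    """

    def __init__(self, lfc_cut: float = 1.0, p_cut: float = 0.05):
        self.lfc_cut = lfc_cut
        self.p_cut = p_cut

    def _validate(self) -> None:
        if not (self.lfc_cut > 0 and self.p_cut > 0):
            raise ValueError("cut-offs must be positive")

    def fit(self, X: GeneTable, y=None):
        self._validate()
        lfc, pval = X.lfc, X.pval
        # a measured fold-change with no accompanying p-value is not decidable
        orphan = lfc.notna() & pval.isna()
        if orphan.any().any():
            genes = lfc.index[orphan.any(axis=1)].tolist()
            raise ValueError(f"missing p-value for a non-missing log2FC in genes: {genes}")
        with np.errstate(invalid="ignore"):
            mask = (lfc.abs() > self.lfc_cut) & (pval < self.p_cut)
        self.mask_ = mask.fillna(False)
        keep = self.mask_.any(axis=1)
        self.retained_ids_ = list(lfc.index[keep])
        self.n_retained_ = int(keep.sum())
        return self

    def transform(self, X: GeneTable) -> FilteredMatrix:
        if not hasattr(self, "mask_"):
            self.fit(X)
        values = X.lfc.where(self.mask_, other=0.0).fillna(0.0)
        return FilteredMatrix(values=values.loc[self.retained_ids_])


def filter_significant(table: GeneTable, lfc_cut: float = 1.0, p_cut: float = 0.05) -> FilteredMatrix:
    """Zero non-significant entries and drop genes significant nowhere.

    Both inequalities are strict: |log2FC| > ``lfc_cut`` and p < ``p_cut``.
    Boundary values (e.g. log2FC exactly 1.0) are excluded.
    """
    return SignificanceFilter(lfc_cut=lfc_cut, p_cut=p_cut).fit_transform(table)
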