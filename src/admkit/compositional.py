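"""Compositional preprocessing of abundance tables.

Metagenomic abundance tables are compositional: each sample carries only
relative information, so standard covariance-based statistics are invalid on
the raw values. The canonical preparation is (i) drop rare taxa, (ii) replace
zeros with a small pseudo-value via multiplicative replacement, and (iii) map
each sample onto centred log-ratio (CLR) coordinates, where proportionality
analysis is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "ClrMatrix",
    "filter_by_occurrence",
    "impute_zeros",
    "clr_transform",
]


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every taxon."""


@dataclass
class AbundanceTable:
    """Sample-by-taxon table of non-negative relative abundances.

    Parameters
    ----------
    values
        ``(n_samples, n_taxa)`` array of non-negative reals.
    sample_ids, taxon_ids
        Unique identifiers for rows and columns.
    sample_meta
        Optional per-sample metadata frame indexed by sample id. Expected
        columns (when used downstream): ``latitude``, ``longitude``,
        ``depth``, ``month``, ``size_fraction``.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample x taxon matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != m:
            raise ValueError(
                f"dimension mismatch: values is {n}x{m} but got "
                f"{len(self.sample_ids)} sample ids, {len(self.taxon_ids)} taxon ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.taxon_ids)) != m:
            raise ValueError("duplicate taxon_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.sample_meta is not None:
            self.sample_meta = self.sample_meta.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def presence(self) -> np.ndarray:
        """Boolean presence matrix: raw abundance strictly positive.

        Presence is defined on the raw (pre-imputation) table; zero
        replacement deliberately destroys this information.
        """
        return self.values > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class ClrMatrix:
    """CLR-transformed abundances; rows sum to zero (closure)."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CLR matrix contains non-finite entries")
        row_sums = np.abs(self.values.sum(axis=1))
        if row_sums.size and row_sums.max() > 1e-9:
            raise ValueError(
                f"CLR closure violated: max |row sum| = {row_sums.max():.3e} > 1e-9"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def column(self, taxon_id: str) -> np.ndarray:
        return self.values[:, self.taxon_ids.index(taxon_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


def filter_by_occurrence(table: AbundanceTable, min_occurrence: int) -> AbundanceTable:
    """Keep taxa observed (abundance > 0) in at least ``min_occurrence`` samples.

    Sample set and the relative order of retained taxa are unchanged.
    """
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be a positive integer")
    if min_occurrence > table.n_samples:
        raise ValueError(
            f"min_occurrence={min_occurrence} exceeds the number of samples "
            f"({table.n_samples})"
        )
    occ = (table.values > 0).sum(axis=0)
    keep = occ >= min_occurrence
    if not keep.any():
        raise EmptyResultError(
            f"no taxon occurs in at least {min_occurrence} samples"
        )
    return AbundanceTable(
        values=table.values[:, keep],
        sample_ids=list(table.sample_ids),
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        sample_meta=table.sample_meta,
    )


def impute_zeros(table: AbundanceTable, factor: float = 0.65) -> AbundanceTable:
    """Multiplicative zero replacement.

    Every zero is replaced by ``factor`` times the global minimum non-zero
    value of the table, forcing the imputed value below any observed one.
    Non-zero entries are untouched; the result is strictly positive and the
    operation is idempotent.
    """
    if not (0.0 < factor < 1.0):
        raise ValueError("factor must lie in (0, 1)")
    nonzero = table.values[table.values > 0]
    if nonzero.size == 0:
        raise ValueError("cannot impute an all-zero table")
    pseudo = nonzero.min() * factor
    values = np.where(table.values == 0, pseudo, table.values)
    out = AbundanceTable(
        values=values,
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
        sample_meta=table.sample_meta,
    )
    return out


def clr_transform(table: AbundanceTable, impute_factor: float | None = None) -> ClrMatrix:
    """Centred log-ratio transform (natural log).

    ``clr(x)_ij = log x_ij - mean_j log x_ij``; each sample row of the result
    sums to zero. Requires strictly positive input — impute zeros first.
    When ``impute_factor`` is given, zero replacement is applied on the fly
    and recorded in provenance.
    """
    if impute_factor is not None:
        table = impute_zeros(table, impute_factor)
    if np.any(table.values <= 0):
        raise ValueError(
            "CLR requires strictly positive abundances; impute zeros first "
            "(impute_zeros or impute_factor=...)"
        )
    logs = np.log(table.values)
    centred = logs - logs.mean(axis=1, keepdims=True)
    # exact closure: remove accumulated floating-point residue per row
    centred -= centred.mean(axis=1, keepdims=True)
    return ClrMatrix(
        values=centred,
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
        provenance={"impute_factor": impute_factor, "log_base": "e"},
    )
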