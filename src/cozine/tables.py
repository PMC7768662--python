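"""Validated sample-by-taxon abundance tables.

The package's entry point is an ``n x p`` table of non-negative abundances
(raw counts or relative abundances), with one row per sample and one column
per taxon.  Because every downstream quantity is a ratio, raw counts and
proportions are interchangeable; zeros, however, are meaningful (absence)
and are preserved exactly through the whole pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CountTable"]


@dataclass(frozen=True)
class CountTable:
    """An ``n x p`` non-negative abundance matrix with axis labels.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_taxa)`` with non-negative entries.
        Counts and proportions are both accepted.
    sample_ids
        ``n`` unique sample identifiers.
    taxon_ids
        ``p`` unique taxon identifiers.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())
    taxon_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D table, got ndim={values.ndim}")
        n, p = values.shape
        sample_ids = tuple(self.sample_ids) or tuple(f"S{i}" for i in range(n))
        taxon_ids = tuple(self.taxon_ids) or tuple(f"T{j}" for j in range(p))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)

        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} rows")
        if len(taxon_ids) != p:
            raise ValueError(f"{len(taxon_ids)} taxon ids for {p} columns")
        for name, ids in (("sample", sample_ids), ("taxon", taxon_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(x for x in ids if x in seen or seen.add(x))
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("table contains non-finite entries")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {sample_ids[i]!r}, taxon {taxon_ids[j]!r}"
            )
        row_tot = values.sum(axis=1)
        if np.any(row_tot == 0):
            i = int(np.argmin(row_tot))
            raise ValueError(f"zero row total for sample {sample_ids[int(np.argmax(row_tot == 0))]!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        """Build a table from a samples-by-taxa DataFrame."""
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=tuple(str(s) for s in df.index),
            taxon_ids=tuple(str(t) for t in df.columns),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    def select_taxa(self, indices: np.ndarray) -> "CountTable":
        """Return a sub-table restricted to the given taxon column indices."""
        indices = np.asarray(indices, dtype=int)
        return CountTable(
            values=self.values[:, indices],
            sample_ids=self.sample_ids,
            taxon_ids=tuple(self.taxon_ids[j] for j in indices),
        )

    def select_samples(self, indices: np.ndarray, allow_repeats: bool = False) -> "CountTable":
        """Return a sub-table of the given sample rows.

        With ``allow_repeats`` (bootstrap resampling) the repeated sample ids
        are suffixed to keep identifiers unique.
        """
        indices = np.asarray(indices, dtype=int)
        if allow_repeats:
            ids = tuple(f"{self.sample_ids[i]}.b{k}" for k, i in enumerate(indices))
        else:
            ids = tuple(self.sample_ids[i] for i in indices)
        return CountTable(values=self.values[indices], sample_ids=ids, taxon_ids=self.taxon_ids)
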