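"""Compositional representations of zero-inflated abundance data.

Raw abundances ``W`` are carried into three paired representations:

* the composition ``X`` (row-wise proportions, zeros kept),
* the incidence matrix ``V`` (``1`` where the taxon is present),
* the zero-preserving centred log-ratio matrix ``Y``.

The clr transform here differs from Aitchison's classical one in that the
geometric-mean centring for each sample uses only the taxa *present* in
that sample; absent taxa stay exactly zero.  No pseudo-count is ever
added: zeros are data, and they are modelled, not imputed.
"""

from __future__ import annotations

import logging

import numpy as np

from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "counts_to_composition",
    "incidence",
    "modified_clr",
    "prevalence_filter",
    "prepare_yv",
]


def counts_to_composition(counts: CountTable) -> CountTable:
    """Normalise each sample's abundances to proportions summing to one.

    Scale-free: multiplying a row by any positive constant leaves the
    result unchanged, so counts and relative abundances are equivalent
    inputs.  Zeros are preserved exactly.
    """
    totals = counts.values.sum(axis=1, keepdims=True)
    # CountTable validation already rejects zero-total rows.
    x = counts.values / totals
    return CountTable(values=x, sample_ids=counts.sample_ids, taxon_ids=counts.taxon_ids)


def incidence(table: CountTable | np.ndarray) -> np.ndarray:
    """Binary presence/absence indicator: 1 exactly where the entry is nonzero.

    "Nonzero" is exact (no epsilon): abundance data record absence as a
    literal zero.
    """
    values = table.values if isinstance(table, CountTable) else np.asarray(table, dtype=float)
    return (values != 0).astype(np.int8)


def modified_clr(x: np.ndarray) -> np.ndarray:
    """Zero-preserving centred log-ratio transform, row-wise.

    For each row, present entries (nonzero) are mapped to
    ``ln x_j - mean(ln x_k over present k)``; absent entries stay exactly 0.
    The present entries of each output row therefore sum to zero.  A row
    with a single present taxon maps to all zeros (its information lives
    entirely in the incidence vector).

    Parameters
    ----------
    x
        1-D composition row or 2-D matrix of composition rows.  Any
        positive row scaling is removed by the centring, so proportions
        and counts behave identically.
    """
    x = np.asarray(x, dtype=float)
    single_row = x.ndim == 1
    x2 = np.atleast_2d(x)
    if np.any(x2 < 0):
        raise ValueError("negative entries are not a valid composition")
    present = x2 != 0
    q = present.sum(axis=1)
    if np.any(q == 0):
        raise ValueError(f"row {int(np.argmin(q))} has no nonzero entries")
    with np.errstate(divide="ignore"):
        logs = np.where(present, np.log(np.where(present, x2, 1.0)), 0.0)
    means = logs.sum(axis=1) / q
    y = np.where(present, logs - means[:, None], 0.0)
    return y[0] if single_row else y


def prevalence_filter(
    counts: CountTable, threshold: float
) -> tuple[CountTable, np.ndarray]:
    """Keep taxa whose prevalence (fraction of samples with nonzero
    abundance) is at least ``threshold``.

    The comparison is inclusive (``>=``) and column order is preserved.
    Returns the filtered table together with the kept column indices of
    the input table.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"prevalence threshold must be in [0, 1], got {threshold}")
    prevalence = (counts.values != 0).mean(axis=0)
    kept = np.flatnonzero(prevalence >= threshold)
    if kept.size < counts.n_taxa:
        logger.info(
            "prevalence filter (threshold %.3g) kept %d of %d taxa",
            threshold,
            kept.size,
            counts.n_taxa,
        )
    return counts.select_taxa(kept), kept


def prepare_yv(counts: CountTable) -> tuple[np.ndarray, np.ndarray]:
    """Full transform pipeline: counts -> (clr matrix Y, incidence matrix V)."""
    comp = counts_to_composition(counts)
    v = incidence(comp)
    y = modified_clr(comp.values)
    return y, v
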