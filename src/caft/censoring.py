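"""Censoring transform and quality-control filters for count tables.

Zero counts are interpreted through a detection-limit lens: taxon j in
sample i is observed as a relative abundance ``C_ij / N_i`` only when
``C_ij > 0``; a zero cell tells us the relative abundance is below the
sample-specific detection limit ``1 / N_i``.  The negative log relative
abundance ``tau_ij = -log(C_ij / N_i)`` is therefore *right-censored* at
``log N_i`` whenever the cell is zero, which turns the log-linear model
for relative abundance into an accelerated failure time (AFT) problem.

The library size ``N_i`` is the sequencing depth of the sample and plays
the role of the censoring time.  By default it is computed from the raw
table *before* any taxon filtering and carried along unchanged, because
the detection limit depends on the depth at which the sample was
sequenced, not on the subtotal over whichever taxa survive a prevalence
filter.  ``filter_taxa(recompute_library_sizes=True)`` opts into the
subtotal behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CaftError, EmptyTableError

__all__ = [
    "CountTable",
    "CensoredTaxon",
    "filter_samples",
    "filter_taxa",
    "to_censored",
    "zero_fraction",
]


@dataclass
class CountTable:
    """A samples x taxa integer count matrix with per-sample library sizes.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, one row per sample, one column per
        taxon.
    sample_ids, taxon_ids
        Unique string identifiers for rows and columns.
    library_sizes
        Sequencing depth of each sample.  If omitted it is computed as
        the row sums of ``counts``.  After taxon filtering the stored
        depths intentionally exceed the row sums (see module docstring).
    """

    counts: np.ndarray
    sample_ids: np.ndarray
    taxon_ids: np.ndarray
    library_sizes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CaftError("counts must be a 2-D samples x taxa matrix")
        if np.any(self.counts < 0):
            raise CaftError("counts must be nonnegative")
        if self.counts.dtype.kind not in "iu":
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise CaftError("counts must be integers")
            self.counts = as_int
        self.sample_ids = np.asarray(self.sample_ids)
        self.taxon_ids = np.asarray(self.taxon_ids)
        for name, ids, n in (
            ("sample_ids", self.sample_ids, self.counts.shape[0]),
            ("taxon_ids", self.taxon_ids, self.counts.shape[1]),
        ):
            if len(ids) != n:
                raise CaftError(f"{name} has length {len(ids)}, expected {n}")
            if len(np.unique(ids)) != len(ids):
                raise CaftError(f"{name} contains duplicates")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=1).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if len(self.library_sizes) != self.counts.shape[0]:
                raise CaftError("library_sizes length mismatch")
        if np.any(self.library_sizes <= 0):
            raise CaftError("every sample must have a positive library size")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def taxon_index(self, taxon_id) -> int:
        hits = np.flatnonzero(self.taxon_ids == taxon_id)
        if hits.size == 0:
            raise KeyError(f"unknown taxon id: {taxon_id!r}")
        return int(hits[0])

    def presence_fractions(self) -> np.ndarray:
        """Fraction of samples in which each taxon has a nonzero count."""
        return (self.counts > 0).mean(axis=0)

    def to_dataframe(self, taxa_as_rows: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)
        return df.T if taxa_as_rows else df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, taxa_as_rows: bool = True) -> "CountTable":
        if taxa_as_rows:
            df = df.T
        return cls(
            counts=df.to_numpy(),
            sample_ids=df.index.to_numpy(),
            taxon_ids=df.columns.to_numpy(),
        )


@dataclass
class CensoredTaxon:
    """Censored negative log relative abundance for one taxon.

    ``tau[i] = -log(C_ij / N_i)`` when the count is positive, otherwise
    ``log N_i``; ``delta[i] = 1`` iff the count is positive (the
    observation is uncensored).
    """

    tau: np.ndarray
    delta: np.ndarray
    taxon_id: object = None


def filter_samples(
    table: CountTable,
    min_library: int,
    exclude_at_threshold: bool = False,
) -> CountTable:
    """Remove shallowly sequenced samples.

    With the default ``exclude_at_threshold=False`` a sample is removed
    when its library size is strictly below ``min_library``; with
    ``True`` samples exactly at the threshold are removed as well.
    Sample order is preserved.  Raises :class:`EmptyTableError` when no
    sample survives.
    """
    if min_library < 1:
        raise CaftError("min_library must be >= 1")
    if exclude_at_threshold:
        keep = table.library_sizes > min_library
    else:
        keep = table.library_sizes >= min_library
    if not keep.any():
        raise EmptyTableError(
            f"library-size filter at {min_library} removed all {table.n_samples} samples"
        )
    return CountTable(
        counts=table.counts[keep],
        sample_ids=table.sample_ids[keep],
        taxon_ids=table.taxon_ids,
        library_sizes=table.library_sizes[keep],
    )


def filter_taxa(
    table: CountTable,
    min_presence_frac: float,
    recompute_library_sizes: bool = False,
) -> CountTable:
    """Remove rare taxa by prevalence.

    Taxon j is retained iff it is present (nonzero) in at least
    ``min_presence_frac`` of the samples; taxa absent everywhere are
    always removed (so ``min_presence_frac=0`` removes exactly the
    all-zero taxa).  Library sizes are *not* recomputed by default; see
    the module docstring.
    """
    if not 0.0 <= min_presence_frac <= 1.0:
        raise CaftError("min_presence_frac must be in [0, 1]")
    presence = (table.counts > 0).sum(axis=0)
    keep = (presence / table.n_samples >= min_presence_frac) & (presence > 0)
    counts = table.counts[:, keep]
    library = counts.sum(axis=1) if recompute_library_sizes else table.library_sizes
    return CountTable(
        counts=counts,
        sample_ids=table.sample_ids,
        taxon_ids=table.taxon_ids[keep],
        library_sizes=library,
    )


def to_censored(table: CountTable, taxon) -> CensoredTaxon:
    """Censoring transform for one taxon (natural log scale).

    Returns ``tau = -log(C/N)`` where the count is positive and
    ``tau = log N`` (the censoring bound) where it is zero, together
    with the event indicator ``delta = 1{C > 0}``.
    """
    j = table.taxon_index(taxon)
    c = table.counts[:, j].astype(float)
    n = table.library_sizes.astype(float)
    delta = (c > 0).astype(np.int8)
    logn = np.log(n)
    tau = np.where(delta == 1, logn - np.log(np.maximum(c, 1.0)), logn)
    return CensoredTaxon(tau=tau, delta=delta, taxon_id=table.taxon_ids[j])


def zero_fraction(table: CountTable) -> float:
    """Proportion of zero cells in the table."""
    if table.counts.size == 0:
        raise EmptyTableError("empty table")
    return float((table.counts == 0).mean())
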