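"""Shared data containers for count matrices and group designs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts.
    gene_ids : array-like of str
        One identifier per row.
    sample_ids : array-like of str
        One identifier per column.
    groups : array-like of int
        Zero-based group index per sample. Every group in
        ``0..n_groups-1`` must have at least one sample.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        g, n = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {g} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} columns")
        if len(self.groups) != n:
            raise ValueError("one group label required per sample")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                bad = np.argwhere(rounded != self.counts)[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        uniq = np.unique(self.groups)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("groups must be consecutive integers starting at 0")
        if len(set(map(str, self.gene_ids))) != g:
            raise ValueError("duplicate gene identifiers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1

    @property
    def library_sizes(self) -> np.ndarray:
        """Total counts per sample."""
        return self.counts.sum(axis=0).astype(float)

    def group_indices(self) -> list[np.ndarray]:
        """Column indices per group, in group order."""
        return [np.flatnonzero(self.groups == i) for i in range(self.n_groups)]

    def drop_all_zero_genes(self) -> tuple["CountMatrix", int]:
        """Remove genes whose counts are zero in every sample.

        Returns the filtered matrix and the number of genes removed.
        """
        keep = self.counts.sum(axis=1) > 0
        removed = int((~keep).sum())
        if removed == 0:
            return self, 0
        return (
            CountMatrix(
                self.counts[keep], self.gene_ids[keep], self.sample_ids, self.groups
            ),
            removed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )
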