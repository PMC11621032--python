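"""Shared data containers for paired spliced/unspliced count matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CountDataset"]


@dataclass
class CountDataset:
    """Paired cell x gene matrices of spliced and unspliced UMI counts.

    ``S`` and ``U`` share shape, cell ordering, and gene ordering.  ``batch``
    optionally assigns each cell to a condition/batch label used for batch
    offsets during manifold learning and for per-condition angular speeds
    during velocity learning.
    """

    S: np.ndarray
    U: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S)
        self.U = np.asarray(self.U)
        if self.S.shape != self.U.shape:
            raise ValueError(
                f"spliced {self.S.shape} and unspliced {self.U.shape} shapes differ"
            )
        if np.any(self.S < 0) or np.any(self.U < 0):
            raise ValueError("counts must be nonnegative")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.S.shape[0])]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.S.shape[1])]
        if len(self.cell_ids) != self.S.shape[0]:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.gene_ids) != self.S.shape[1]:
            raise ValueError("gene_ids length does not match matrix columns")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.shape[0] != self.S.shape[0]:
                raise ValueError("batch length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]

    @property
    def n_genes(self) -> int:
        return self.S.shape[1]

    def batch_codes(self) -> tuple[np.ndarray, list]:
        """Integer batch codes per cell plus the ordered label list.

        Cells with no batch annotation all map to a single code 0 with label
        ``"all"``.  Label order is first-appearance order, so the first batch
        (whose offset is pinned to zero) is well defined.
        """
        if self.batch is None:
            return np.zeros(self.n_cells, dtype=int), ["all"]
        labels: list = []
        codes = np.empty(self.n_cells, dtype=int)
        index: dict = {}
        for i, b in enumerate(self.batch):
            key = b.item() if isinstance(b, np.generic) else b
            if key not in index:
                index[key] = len(labels)
                labels.append(key)
            codes[i] = index[key]
        return codes, labels

    def subset_genes(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountDataset(
            S=self.S[:, idx],
            U=self.U[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[j] for j in idx],
            batch=None if self.batch is None else self.batch.copy(),
        )

    def subset_cells(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountDataset(
            S=self.S[idx],
            U=self.U[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            batch=None if self.batch is None else self.batch[idx],
        )
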