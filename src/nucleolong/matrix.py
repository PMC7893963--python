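"""Sparse nuclei-by-feature count container shared by all pipeline layers.

A :class:`LayerMatrix` is the common currency of the pipeline: the Illumina
abundance matrix, the per-gene spliced/unspliced splicing matrix and the
polyA-site-cluster APA matrix are all instances tagged with a ``layer`` name.
Rows are nuclei (cell barcodes), columns are namespaced feature identifiers
(``gene``, ``gene|spliced``, ``gene|unspliced``, ``gene|PA1`` ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

LAYER_KINDS = ("abundance", "splicing", "apa")


@dataclass
class LayerMatrix:
    """Sparse nonnegative integer matrix of nuclei x features.

    Parameters
    ----------
    layer
        One of ``abundance``, ``splicing`` or ``apa``.
    nuclei
        Ordered cell-barcode list (row labels).
    features
        Ordered namespaced feature-id list (column labels).
    counts
        ``scipy.sparse`` matrix of shape ``(len(nuclei), len(features))``.
    """

    layer: str
    nuclei: list[str]
    features: list[str]
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        if self.layer not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.layer!r}; expected one of {LAYER_KINDS}")
        self.nuclei = list(self.nuclei)
        self.features = list(self.features)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.nuclei), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.nuclei)} nuclei x {len(self.features)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len(set(self.nuclei)) != len(self.nuclei):
            raise ValueError("duplicate nucleus barcodes")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def nucleus_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.nuclei)}

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.features)}

    def subset_nuclei(self, barcodes: list[str]) -> "LayerMatrix":
        """Row-subset (and reorder) to the given barcodes."""
        idx = self.nucleus_index()
        rows = [idx[b] for b in barcodes]
        return LayerMatrix(self.layer, list(barcodes), list(self.features), self.counts[rows])

    def to_anndata(self):
        """View as an :class:`anndata.AnnData` (features as var)."""
        import anndata as ad
        import pandas as pd

        return ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=pd.DataFrame(index=pd.Index(self.nuclei, name="barcode")),
            var=pd.DataFrame({"layer": self.layer}, index=pd.Index(self.features, name="feature")),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayerMatrix):
            return NotImplemented
        return (
            self.layer == other.layer
            and self.nuclei == other.nuclei
            and self.features == other.features
            and self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
        )
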