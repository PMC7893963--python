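"""Short-read side of the pipeline: abundance matrix, QC and the bin index.

Single-nucleus libraries are dominated by intron-containing transcripts, so
gene assignment must count reads that fall inside introns.  Rather than
stripping introns from reads and re-aligning, a read is assigned to a gene
when all of its aligned blocks fall within the gene's full genomic span
(exons plus introns) on the matching strand; reads overlapping several gene
spans are ambiguous and dropped.

The bin index buckets guide records into non-overlapping 500-bp genomic
bins; barcode rescue for a long read then only searches records from bins
overlapping or adjacent to the read's mapped span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .formats import GeneModel, GuideRecord
from .matrix import LayerMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene quality-control cut-offs.

    Defaults are the root preset (350-2300 genes per nucleus, genes in >= 3
    nuclei); the endosperm preset uses 400-3000.
    """

    min_genes_per_cell: int = 350
    max_genes_per_cell: int = 2300
    min_cells_per_gene: int = 3

    ENDOSPERM = None  # filled in below

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")


QCThresholds.ENDOSPERM = QCThresholds(400, 3000, 3)


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------


def assign_gene_intron_tolerant(
    read_blocks: Sequence[tuple[int, int]],
    models: Iterable[GeneModel],
    strand: str | None = None,
    allow_antisense: bool = False,
) -> str | None:
    """Assign a read to a gene if all blocks fall in exactly one gene span.

    The span is exons plus introns, so purely intronic reads — the bulk of a
    nuclear library — still count.  ``strand``, when given, is the read's
    transcript strand and must match the gene unless ``allow_antisense``.
    Overlap with more than one gene span returns ``None`` (ambiguous), as
    does intergenic placement.
    """
    if not read_blocks:
        return None
    lo = min(s for s, _ in read_blocks)
    hi = max(e for _, e in read_blocks)
    hits = []
    for m in models:
        gs, ge = m.span
        if lo < ge and hi > gs:  # any overlap with the span
            if strand is not None and not allow_antisense and strand != m.strand:
                continue
            hits.append(m)
    if len(hits) != 1:
        return None
    m = hits[0]
    gs, ge = m.span
    if lo >= gs and hi <= ge:
        return m.gene_id
    return None


# ---------------------------------------------------------------------------
# abundance matrix
# ---------------------------------------------------------------------------


def build_abundance_matrix(
    guide_records: Iterable[GuideRecord],
    models: dict[str, GeneModel] | None = None,
) -> LayerMatrix:
    """Count distinct UMIs per (nucleus, gene) from guide records.

    Duplicate (barcode, umi, gene) rows collapse to a single molecule.
    Records naming a gene absent from ``models`` (when given) are skipped
    with a log message.
    """
    triples = set()
    for r in guide_records:
        if models is not None and r.gene_id not in models:
            logger.warning("guide record with unknown gene_id %s skipped", r.gene_id)
            continue
        triples.add((r.barcode, r.umi, r.gene_id))
    if not triples:
        return LayerMatrix("abundance", [], [], sp.csr_matrix((0, 0), dtype=np.int64))
    barcodes = sorted({t[0] for t in triples})
    genes = sorted({t[2] for t in triples})
    bidx = {b: i for i, b in enumerate(barcodes)}
    gidx = {g: i for i, g in enumerate(genes)}
    rows = [bidx[b] for b, _, g in triples]
    cols = [gidx[g] for _, _, g in triples]
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(barcodes), len(genes)),
    ).tocsr()
    return LayerMatrix("abundance", barcodes, genes, counts)


def qc_filter(matrix: LayerMatrix, thresholds: QCThresholds) -> LayerMatrix:
    """Drop sparse genes, then out-of-range nuclei.

    Genes detected in fewer than ``min_cells_per_gene`` nuclei are discarded
    first; nuclei with detected-gene counts strictly below the minimum or
    strictly above the maximum are then removed.  Idempotent.
    """
    counts = matrix.counts
    detected = (counts > 0).astype(np.int64)
    gene_keep = np.asarray(detected.sum(axis=0)).ravel() >= thresholds.min_cells_per_gene
    counts = counts[:, gene_keep]
    features = [f for f, k in zip(matrix.features, gene_keep) if k]
    genes_per_cell = np.asarray((counts > 0).sum(axis=1)).ravel()
    cell_keep = (genes_per_cell >= thresholds.min_genes_per_cell) & (
        genes_per_cell <= thresholds.max_genes_per_cell
    )
    if matrix.shape[0] and not cell_keep.any():
        raise ValueError("QC thresholds removed every nucleus")
    nuclei = [b for b, k in zip(matrix.nuclei, cell_keep) if k]
    return LayerMatrix(matrix.layer, nuclei, features, counts[cell_keep])


# ---------------------------------------------------------------------------
# bin index
# ---------------------------------------------------------------------------


@dataclass
class BinIndex:
    """Guide records bucketed into non-overlapping genomic bins.

    A record at position ``p`` lives in bin ``floor(p / bin_size)``.  A
    lookup over an interval returns records from all bins the interval
    overlaps plus ``adjacent_bins`` extra bins on each side.
    """

    bin_size: int = 500
    adjacent_bins: int = 1
    _bins: dict[tuple[str, int], list[GuideRecord]] = field(default_factory=dict, repr=False)
    n_records: int = 0

    def add(self, record: GuideRecord) -> None:
        if record.position < 0:
            raise ValueError(f"negative position {record.position}")
        key = (record.chrom, record.position // self.bin_size)
        self._bins.setdefault(key, []).append(record)
        self.n_records += 1

    def lookup(self, chrom: str, start: int, end: int) -> list[GuideRecord]:
        """Records in bins overlapping [start, end) plus the adjacent bins."""
        if end <= start:
            raise ValueError(f"empty query interval [{start}, {end})")
        first = max(start // self.bin_size - self.adjacent_bins, 0)
        last = (end - 1) // self.bin_size + self.adjacent_bins
        out: list[GuideRecord] = []
        for b in range(first, last + 1):
            out.extend(self._bins.get((chrom, b), []))
        return out

    def all_records(self) -> list[GuideRecord]:
        out: list[GuideRecord] = []
        for recs in self._bins.values():
            out.extend(recs)
        return out


def build_bin_index(
    guide_records: Iterable[GuideRecord], bin_size: int = 500, adjacent_bins: int = 1
) -> BinIndex:
    """Bucket guide records into ``bin_size``-bp bins (default 500)."""
    index = BinIndex(bin_size=bin_size, adjacent_bins=adjacent_bins)
    for r in guide_records:
        index.add(r)
    return index
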