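"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention is uniformly 0-based half-open; GTF (1-based closed)
is converted at the boundary, so a GTF exon ``1..100`` becomes ``[0, 100)``.

Long-read alignments come in as SAM/BAM (pysam); read sequences may be
supplied separately as FASTQ/FASTA, in which case they take precedence over
the SAM SEQ field — the cell barcode can live in a hard-clipped region that
is only recoverable from the original read.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import LayerMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GUIDE_COLUMNS = ["barcode", "umi", "gene_id", "chrom", "position"]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed record in an input file; carries the offending record id."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of non-overlapping exons; introns are the gaps.

    All intervals are 0-based half-open genomic coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(f"{self.gene_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, derived, never stored."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint: exons plus introns, half-open."""
        return (self.start, self.end)


@dataclass
class AlignedLongRead:
    """One mapped long read: aligned blocks plus its unmapped clip flanks.

    ``blocks`` are half-open genomic intervals covering CIGAR M/D runs;
    N (splice) gaps separate blocks.  ``clip5``/``clip3`` are the unmapped
    prefix/suffix lengths *in read orientation* — for a reverse-strand
    alignment the reference-forward left clip is the read's 3' end.
    ``seq`` is in read orientation.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    clip5: int
    clip3: int
    seq: str
    is_secondary: bool = False
    is_supplementary: bool = False
    mapq: int = 0

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def flank5(self) -> str:
        """Unmapped prefix in read orientation (adapter/barcode end or noise)."""
        return self.seq[: self.clip5]

    @property
    def flank3(self) -> str:
        """Unmapped suffix in read orientation."""
        return self.seq[len(self.seq) - self.clip3 :] if self.clip3 else ""


@dataclass(frozen=True)
class GuideRecord:
    """A short-read-derived (barcode, UMI, gene, position) record.

    These records, produced from the accurate Illumina library made from the
    same cDNA pool, define the search space when rescuing barcodes on
    error-prone long reads.
    """

    barcode: str
    umi: str
    gene_id: str
    chrom: str
    position: int

    BARCODE_LEN = 16
    UMI_LEN = 10

    def __post_init__(self) -> None:
        if len(self.barcode) != self.BARCODE_LEN or set(self.barcode) - set("ACGT"):
            raise ValueError(f"barcode must be {self.BARCODE_LEN} nt over ACGT: {self.barcode!r}")
        if len(self.umi) != self.UMI_LEN or set(self.umi) - set("ACGT"):
            raise ValueError(f"umi must be {self.UMI_LEN} nt over ACGT: {self.umi!r}")
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")


# ---------------------------------------------------------------------------
# long-read alignments
# ---------------------------------------------------------------------------

_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_BLOCK_SPLIT = 3  # N
_CLIP_OPS = {4, 5}  # S, H


def _blocks_from_cigar(pos: int, cigartuples, read_id: str) -> tuple[tuple[int, int], ...]:
    blocks: list[tuple[int, int]] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if length < 0:
            raise FormatError(f"{read_id}: negative CIGAR length")
        if op in _REF_CONSUMING:
            cur += length
        elif op == _BLOCK_SPLIT:
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
    if cur > cur_start:
        blocks.append((cur_start, cur))
    if not blocks:
        raise FormatError(f"{read_id}: CIGAR consumes no reference bases")
    return tuple(blocks)


def _load_sequences(fastq_source) -> dict[str, str]:
    from Bio import SeqIO

    path = Path(fastq_source)
    fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta"} else "fastq"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)}


def read_long_alignments(sam_source, fastq_source=None) -> Iterator[AlignedLongRead]:
    """Stream :class:`AlignedLongRead` records from a SAM/BAM file.

    One record is produced per mapped alignment line (secondary and
    supplementary lines included, flagged — filtering is policy and happens
    downstream).  If ``fastq_source`` is given, sequences are taken from it
    (read orientation) in preference to the SAM SEQ field; records with no
    sequence from either source are skipped with a warning.
    """
    import pysam

    seqs = _load_sequences(fastq_source) if fastq_source is not None else {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(os.fspath(sam_source), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                strand = "-" if rec.is_reverse else "+"
                try:
                    blocks = _blocks_from_cigar(rec.reference_start, rec.cigartuples or [], rec.query_name)
                except FormatError:
                    raise
                cig = rec.cigartuples or []
                left = 0
                i = 0
                while i < len(cig) and cig[i][0] in _CLIP_OPS:
                    left += cig[i][1]
                    i += 1
                right = 0
                i = len(cig) - 1
                while i >= 0 and cig[i][0] in _CLIP_OPS:
                    right += cig[i][1]
                    i -= 1
                seq = seqs.get(rec.query_name)
                if seq is None:
                    raw = rec.query_sequence
                    if raw is None:
                        logger.warning("read %s has no sequence in SAM or FASTQ; skipped", rec.query_name)
                        continue
                    seq = revcomp(raw.upper()) if rec.is_reverse else raw.upper()
                    has_hard = any(op == 5 for op, _ in cig)
                    if has_hard:
                        logger.warning(
                            "read %s is hard-clipped and no FASTQ was supplied; "
                            "clip flanks are incomplete",
                            rec.query_name,
                        )
                clip5, clip3 = (right, left) if rec.is_reverse else (left, right)
                yield AlignedLongRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    strand=strand,
                    blocks=blocks,
                    clip5=clip5,
                    clip3=clip3,
                    seq=seq,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                    mapq=rec.mapping_quality,
                )
    finally:
        pysam.set_verbosity(save)


# ---------------------------------------------------------------------------
# gene models (GTF)
# ---------------------------------------------------------------------------


def read_gene_models(gtf_source) -> dict[str, GeneModel]:
    """Parse gene models from GTF/GFF3, returning ``{gene_id: GeneModel}``.

    Overlapping exons (e.g. from multiple transcripts) are unioned per gene,
    so introns are the regions covered by no annotated exon of the gene.
    An exon outside its gene feature's bounds raises :class:`FormatError`.
    """
    import gffutils

    source = os.fspath(gtf_source) if isinstance(gtf_source, (str, Path)) else gtf_source
    db = gffutils.create_db(
        source,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    gene_bounds: dict[str, tuple[str, str, int, int]] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        gene_bounds[gid] = (g.seqid, g.strand, g.start - 1, g.end)

    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for e in db.features_of_type("exon"):
        gid = e.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise FormatError(f"exon at {e.seqid}:{e.start} lacks gene_id")
        start, end = e.start - 1, e.end  # GTF 1-based closed -> half-open
        if gid in gene_bounds:
            chrom, strand, gs, ge = gene_bounds[gid]
            if start < gs or end > ge:
                raise FormatError(f"exon [{start}, {end}) outside bounds of gene {gid}")
        else:
            chrom, strand = e.seqid, e.strand
        exons_by_gene.setdefault(gid, []).append((start, end))
        meta[gid] = (chrom, strand)

    models: dict[str, GeneModel] = {}
    for gid, exons in exons_by_gene.items():
        exons.sort()
        merged: list[list[int]] = []
        for start, end in exons:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        chrom, strand = meta[gid]
        models[gid] = GeneModel(gid, chrom, strand, tuple((s, e) for s, e in merged))
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GTF (gene + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                f"{m.chrom}\tnucleolong\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tnucleolong\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# guide records (TSV)
# ---------------------------------------------------------------------------


def read_guide_records(tsv_source) -> list[GuideRecord]:
    """Read guide records from TSV with columns barcode, umi, gene_id, chrom, position."""
    df = pd.read_csv(tsv_source, sep="\t", dtype={"barcode": str, "umi": str})
    missing = set(GUIDE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"guide TSV missing columns: {sorted(missing)}")
    return [
        GuideRecord(r.barcode, r.umi, r.gene_id, str(r.chrom), int(r.position))
        for r in df.itertuples(index=False)
    ]


def write_guide_records(records: Iterable[GuideRecord], path) -> None:
    pd.DataFrame(
        [(r.barcode, r.umi, r.gene_id, r.chrom, r.position) for r in records],
        columns=GUIDE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# layer matrices (MatrixMarket + TSV sidecars, 10x-style layout)
# ---------------------------------------------------------------------------


def write_layer_matrix(matrix: LayerMatrix, out_dir) -> None:
    """Write a LayerMatrix as ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``.

    The .mtx holds features x barcodes (10x layout).  Round-trips losslessly
    through :func:`read_layer_matrix`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(matrix.counts.T)
    if mat.shape != (len(matrix.features), len(matrix.nuclei)):
        raise ValueError("feature/barcode count mismatch with matrix dims")
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.nuclei))
    with open(out / "features.tsv", "w") as fh:
        for f in matrix.features:
            fh.write(f"{f}\t{matrix.layer}\n")


def read_layer_matrix(in_dir) -> LayerMatrix:
    """Inverse of :func:`write_layer_matrix`."""
    in_dir = Path(in_dir)
    mat = sp.csr_matrix(scipy.io.mmread(str(in_dir / "matrix.mtx"))).T.astype(np.int64)
    barcodes = (in_dir / "barcodes.tsv").read_text().splitlines()
    features: list[str] = []
    layer = "abundance"
    for line in (in_dir / "features.tsv").read_text().splitlines():
        parts = line.split("\t")
        features.append(parts[0])
        if len(parts) > 1:
            layer = parts[1]
    return LayerMatrix(layer, barcodes, features, sp.csr_matrix(mat))
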