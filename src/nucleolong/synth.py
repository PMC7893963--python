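"""Synthetic full-length single-nucleus datasets with ground truth.

Emulates the inputs the pipeline sees in practice: a small genome with
multi-exon gene models, a nucleus barcode set, error-free short-read guide
records (barcode, UMI, gene, position), and error-injected long reads whose
structure follows 10x 3' chemistry —

    adapter (30 nt) + barcode (16 nt) + UMI (10 nt) + polyT (20 nt)
    + reverse-complemented cDNA of the transcript fragment

The sequencing channel applies i.i.d. per-base errors at a configurable
rate (default 5%, the accuracy regime of Nanopore long reads) split between
substitutions, insertions and deletions.  Guide records are emitted
error-free: the accurate short-read library is treated as truth.

Every read and molecule carries a truth row (barcode, UMI, gene, per-intron
retention flags, polyA site; per nucleus, its planted cell type), so
parameter recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    AlignedLongRead,
    GeneModel,
    GuideRecord,
    revcomp,
    write_gene_models,
    write_guide_records,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
ADAPTER_LEN = 30
POLYT_LEN = 20
BARCODE_LEN = 16
UMI_LEN = 10


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``intron_retention_prob`` is the per-intron probability that a molecule
    retains the intron; it may be a scalar (all cell types alike) or a map
    ``{celltype_index: prob}`` to plant cell types that differ in splicing.
    ``pa_site_offsets`` are candidate polyA-site offsets in bp upstream of
    each gene's annotated 3' end; offsets that would leave no transcript are
    dropped per gene, so genes carry 1..len(offsets) sites.
    """

    n_genes: int = 60
    n_nuclei: int = 120
    n_celltypes: int = 3
    reads_per_nucleus: int = 20
    per_base_error_rate: float = 0.05
    error_split: tuple[float, float, float] = (0.5, 0.25, 0.25)  # sub : ins : del
    barcode_len: int = BARCODE_LEN
    umi_len: int = UMI_LEN
    intron_retention_prob: float | Mapping[int, float] = 0.25
    pa_site_offsets: tuple[int, ...] = (0, 250)
    introns_range: tuple[int, int] = (1, 5)  # inclusive bounds on introns per gene
    reads_per_molecule: int = 1
    marker_genes_per_type: int = 5
    marker_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "n_nuclei", "n_celltypes", "reads_per_nucleus", "reads_per_molecule"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1]")
        if abs(sum(self.error_split) - 1.0) > 1e-9 or min(self.error_split) < 0:
            raise ValueError("error_split must be nonnegative and sum to 1")
        if self.barcode_len != BARCODE_LEN or self.umi_len != UMI_LEN:
            raise ValueError("10x chemistry fixes barcode_len=16 and umi_len=10")
        if not 0 <= self.introns_range[0] <= self.introns_range[1]:
            raise ValueError("introns_range must be ordered and nonnegative")
        probs = (
            self.intron_retention_prob.values()
            if isinstance(self.intron_retention_prob, Mapping)
            else [self.intron_retention_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("intron_retention_prob values must be in [0, 1]")

    def retention_prob(self, celltype: int) -> float:
        if isinstance(self.intron_retention_prob, Mapping):
            return float(self.intron_retention_prob[celltype])
        return float(self.intron_retention_prob)


@dataclass
class SimMolecule:
    """One cDNA molecule with its full truth labels."""

    molecule_id: str
    barcode: str
    umi: str
    gene_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]  # genomic blocks of the fragment
    retention_flags: tuple[bool, ...]  # aligned to GeneModel.introns
    pa_site: int  # genomic coordinate of the 3' terminus
    celltype: int


@dataclass
class SimRead:
    """One simulated long read (read orientation) plus its SAM projection."""

    read_id: str
    molecule_id: str
    seq: str
    sam_pos: int  # 0-based leftmost reference position
    sam_cigar: str  # reference-forward
    sam_flag: int
    chrom: str
    n_errors: tuple[int, int, int] = (0, 0, 0)  # channel (sub, ins, del) events
    n_template_bases: int = 0  # error-free template length the channel saw


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    models: dict[str, GeneModel]
    barcodes: list[str]
    celltypes: dict[str, int]  # barcode -> planted cell type
    molecules: list[SimMolecule]
    reads: list[SimRead]
    guide_records: list[GuideRecord]

    @property
    def truth_reads(self) -> pd.DataFrame:
        mol = {m.molecule_id: m for m in self.molecules}
        rows = []
        for r in self.reads:
            m = mol[r.molecule_id]
            rows.append(
                {
                    "read_id": r.read_id,
                    "barcode": m.barcode,
                    "umi": m.umi,
                    "gene_id": m.gene_id,
                    "pa_site": m.pa_site,
                    "retention_flags": "".join("1" if f else "0" for f in m.retention_flags),
                }
            )
        return pd.DataFrame(rows)

    @property
    def truth_nuclei(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"barcode": list(self.celltypes), "celltype": list(self.celltypes.values())}
        )

    def aligned_reads(self) -> list[AlignedLongRead]:
        """Truth alignments as reader output, bypassing SAM serialization."""
        from .formats import _blocks_from_cigar  # same CIGAR arithmetic as the reader

        out = []
        for r in self.reads:
            cig = _parse_cigar(r.sam_cigar)
            blocks = _blocks_from_cigar(r.sam_pos, cig, r.read_id)
            left = cig[0][1] if cig[0][0] == 4 else 0
            right = cig[-1][1] if cig[-1][0] == 4 else 0
            reverse = bool(r.sam_flag & 16)
            clip5, clip3 = (right, left) if reverse else (left, right)
            out.append(
                AlignedLongRead(
                    read_id=r.read_id,
                    chrom=r.chrom,
                    strand="-" if reverse else "+",
                    blocks=blocks,
                    clip5=clip5,
                    clip3=clip3,
                    seq=r.seq,
                    mapq=60,
                )
            )
        return out

    def write(self, out_dir) -> None:
        """Write FASTA/GTF/FASTQ/SAM/guide TSV/truth TSVs to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_gene_models(self.models.values(), out / "annotation.gtf")
        with open(out / "reads.fq", "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
        with open(out / "alignments.sam", "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom, seq in self.genome.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
            for r in self.reads:
                seq_rf = revcomp(r.seq) if r.sam_flag & 16 else r.seq
                fh.write(
                    f"{r.read_id}\t{r.sam_flag}\t{r.chrom}\t{r.sam_pos + 1}\t60\t"
                    f"{r.sam_cigar}\t*\t0\t0\t{seq_rf}\t*\n"
                )
        write_guide_records(self.guide_records, out / "guide.tsv")
        self.truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        self.truth_nuclei.to_csv(out / "truth_nuclei.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_reference(config: SimulationConfig) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Simulate a one-chromosome genome and its gene models.

    Genes carry 1-5 introns and are spaced >= 2 kb apart so that 500-bp bin
    lookups never mix neighbouring genes.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    models: dict[str, GeneModel] = {}
    cursor = 1000
    chrom = "chrS"
    lo, hi = config.introns_range
    for i in range(config.n_genes):
        n_introns = int(rng.integers(lo, hi + 1))
        exons = []
        pos = cursor
        for j in range(n_introns + 1):
            exon_len = int(rng.integers(80, 251))
            exons.append((pos, pos + exon_len))
            pos += exon_len
            if j < n_introns:
                pos += int(rng.integers(60, 151))
        gid = f"g{i:04d}"
        models[gid] = GeneModel(gid, chrom, "+", tuple(exons))
        cursor = pos + 2000  # >= 2 kb intergenic spacing
    genome_len = cursor + 1000
    if genome_len > 50_000_000:
        raise ValueError("genome too small for requested gene count at this spacing")
    genome = {chrom: _random_seq(rng, genome_len)}
    return genome, models


def _pa_sites(model: GeneModel, offsets: Sequence[int]) -> list[int]:
    """Candidate 3'-terminus coordinates; offsets leaving < 150 nt of transcript drop."""
    sites = []
    for off in offsets:
        site = model.end - int(off)
        if site - model.start >= 150 and site > model.exons[0][1]:
            sites.append(site)
    return sites or [model.end]


# ---------------------------------------------------------------------------
# error channel
# ---------------------------------------------------------------------------


def _mutate_with_ops(
    seq: str, rng: np.random.Generator, p_sub: float, p_ins: float, p_del: float
) -> tuple[str, list[tuple[int, int]], tuple[int, int, int]]:
    """Apply the error channel to a reference-aligned segment.

    Returns the mutated sequence, CIGAR ops (op, length) over the reference
    segment (0=M, 1=I, 2=D; substitutions stay inside M runs), and the
    (substitution, insertion, deletion) event counts.
    """
    out = []
    ops: list[tuple[int, int]] = []
    n_sub = n_ins = n_del = 0

    def push(op: int, length: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    u = rng.random(len(seq))
    v = rng.random(len(seq))
    for i, base in enumerate(seq):
        if u[i] < p_del:
            push(2)
            n_del += 1
        else:
            if u[i] < p_del + p_sub:
                alt = "ACGT".replace(base, "")
                base = alt[int(rng.integers(0, 3))]
                n_sub += 1
            out.append(base)
            push(0)
        if v[i] < p_ins:
            out.append("ACGT"[int(rng.integers(0, 4))])
            push(1)
            n_ins += 1
    return "".join(out), ops, (n_sub, n_ins, n_del)


def _mutate_free(
    seq: str, rng: np.random.Generator, p_sub: float, p_ins: float, p_del: float
) -> tuple[str, tuple[int, int, int]]:
    mutated, _, counts = _mutate_with_ops(seq, rng, p_sub, p_ins, p_del)
    return mutated, counts


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_str(ops: Sequence[tuple[int, int]]) -> str:
    return "".join(f"{length}{_CIGAR_OPS[op]}" for op, length in ops)


def _parse_cigar(cigar: str) -> list[tuple[int, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((_CIGAR_OPS.index(ch), int(num)))
            num = ""
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _molecule_blocks(
    model: GeneModel, retention: Sequence[bool], pa_site: int
) -> tuple[tuple[int, int], ...]:
    """Genomic blocks of a transcript fragment: exons plus retained introns,
    truncated at the polyA site."""
    parts = list(model.exons)
    for flag, intron in zip(retention, model.introns):
        if flag:
            parts.append(intron)
    parts.sort()
    merged: list[list[int]] = []
    for s, e in parts:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    blocks = []
    for s, e in merged:
        if s >= pa_site:
            break
        blocks.append((s, min(e, pa_site)))
    return tuple(blocks)


def simulate_reads(
    config: SimulationConfig,
    genome: dict[str, str],
    models: dict[str, GeneModel],
) -> SimulatedDataset:
    """Simulate molecules, long reads and guide records with full truth.

    One guide record is emitted per molecule (error-free); each molecule
    produces ``reads_per_molecule`` long reads through the error channel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    e = config.per_base_error_rate
    fs, fi, fd = config.error_split
    p_sub, p_ins, p_del = e * fs, e * fi, e * fd

    gene_ids = sorted(models)
    chrom = models[gene_ids[0]].chrom
    pa_by_gene = {g: _pa_sites(models[g], config.pa_site_offsets) for g in gene_ids}

    # nucleus barcodes and planted cell types
    barcodes: list[str] = []
    seen = set()
    while len(barcodes) < config.n_nuclei:
        bc = _random_seq(rng, config.barcode_len)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    celltypes = {bc: i % config.n_celltypes for i, bc in enumerate(barcodes)}

    # expression programs: disjoint marker blocks per cell type, uplifted
    weights = np.ones((config.n_celltypes, len(gene_ids)))
    m = min(config.marker_genes_per_type, len(gene_ids) // max(config.n_celltypes, 1))
    for t in range(config.n_celltypes):
        weights[t, t * m : (t + 1) * m] *= config.marker_fold
    weights /= weights.sum(axis=1, keepdims=True)

    molecules: list[SimMolecule] = []
    reads: list[SimRead] = []
    guide: list[GuideRecord] = []
    umi_seen: set[tuple[str, str]] = set()

    for bc in barcodes:
        ct = celltypes[bc]
        r_prob = config.retention_prob(ct)
        gene_draws = rng.choice(len(gene_ids), size=config.reads_per_nucleus, p=weights[ct])
        for k, gi in enumerate(gene_draws):
            gid = gene_ids[int(gi)]
            model = models[gid]
            while True:
                umi = _random_seq(rng, config.umi_len)
                if (bc, umi) not in umi_seen:
                    umi_seen.add((bc, umi))
                    break
            retention = tuple(bool(b) for b in rng.random(len(model.introns)) < r_prob)
            pa_site = int(pa_by_gene[gid][int(rng.integers(0, len(pa_by_gene[gid])))])
            blocks = _molecule_blocks(model, retention, pa_site)
            mid = f"{bc}_{umi}"
            mol = SimMolecule(mid, bc, umi, gid, chrom, blocks, retention, pa_site, ct)
            molecules.append(mol)
            guide.append(GuideRecord(bc, umi, gid, chrom, pa_site - 1))

            prefix = (
                _random_seq(rng, ADAPTER_LEN) + bc + umi + "T" * POLYT_LEN
            )
            cdna_fwd = "".join(genome[chrom][s:t] for s, t in blocks)
            for j in range(config.reads_per_molecule):
                prefix_mut, pref_counts = _mutate_free(prefix, rng, p_sub, p_ins, p_del)
                totals = list(pref_counts)
                ops_all: list[tuple[int, int]] = []
                cdna_parts = []
                prev_end = None
                for s, t in blocks:
                    if prev_end is not None:
                        ops_all.append((3, s - prev_end))  # N gap
                    seg_mut, seg_ops, seg_counts = _mutate_with_ops(
                        genome[chrom][s:t], rng, p_sub, p_ins, p_del
                    )
                    for ci in range(3):
                        totals[ci] += seg_counts[ci]
                    cdna_parts.append(seg_mut)
                    # merge adjacent runs across segment boundary
                    for op, length in seg_ops:
                        if ops_all and ops_all[-1][0] == op and op != 3:
                            ops_all[-1] = (op, ops_all[-1][1] + length)
                        else:
                            ops_all.append((op, length))
                    prev_end = t
                cdna_mut = "".join(cdna_parts)
                read_seq = prefix_mut + revcomp(cdna_mut)
                cigar = _cigar_str(list(ops_all) + [(4, len(prefix_mut))])
                reads.append(
                    SimRead(
                        read_id=f"{mid}_r{j}",
                        molecule_id=mid,
                        seq=read_seq,
                        sam_pos=blocks[0][0],
                        sam_cigar=cigar,
                        sam_flag=16,
                        chrom=chrom,
                        n_errors=(totals[0], totals[1], totals[2]),
                        n_template_bases=len(prefix) + len(cdna_fwd),
                    )
                )

    return SimulatedDataset(
        config=config,
        genome=genome,
        models=models,
        barcodes=barcodes,
        celltypes=celltypes,
        molecules=molecules,
        reads=reads,
        guide_records=guide,
    )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Convenience: reference plus reads in one call."""
    genome, models = simulate_reference(config)
    return simulate_reads(config, genome, models)
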