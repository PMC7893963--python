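"""Per-molecule splicing calls, polyA-site clusters and the isoform matrices.

A molecule is *unspliced* when at least one annotated intron has a mapping
ratio above 0.5 — more than half of the intron's bases covered by the
molecule's aligned blocks.  Introns lying entirely outside the molecule's
aligned span (5' truncation) are unobserved and contribute no evidence.

Alternative polyadenylation is quantified per gene by single-linkage
clustering of the molecules' 3' termini with a 24-nt gap threshold: sorted
sites are cut wherever consecutive sites are more than 24 nt apart, and
each maximal group becomes one APA feature.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .formats import GeneModel
from .matrix import LayerMatrix
from .nanopore_assign import MoleculeConsensus

PA_CLUSTER_THRESHOLD = 24
IR_RATIO_THRESHOLD = 0.5

SPLICED = "spliced"
UNSPLICED = "unspliced"


@dataclass
class SpliceCall:
    """Per-intron retention flags and the molecule-level splicing status.

    ``retention_flags[i]`` is True when intron i is retained, False when it
    is observed spliced and None when the molecule gives no evidence (the
    intron lies outside the aligned span).
    """

    barcode: str
    umi: str
    gene_id: str
    retention_flags: tuple[bool | None, ...]
    status: str  # SPLICED | UNSPLICED

    def __post_init__(self) -> None:
        any_retained = any(f is True for f in self.retention_flags)
        if (self.status == UNSPLICED) != any_retained:
            raise ValueError("status must be unspliced iff any intron is retained")


@dataclass
class PolyACluster:
    """Maximal single-linkage group of polyA sites within the gap threshold."""

    cluster_id: str
    chrom: str
    strand: str
    gene_id: str
    member_sites: tuple[int, ...]
    representative: int

    def __post_init__(self) -> None:
        sites = sorted(self.member_sites)
        for a, b in zip(sites, sites[1:]):
            if b - a > PA_CLUSTER_THRESHOLD:
                raise ValueError("cluster members exceed the gap threshold")


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------


def intron_mapping_ratio(
    read_blocks: Sequence[tuple[int, int]], intron: tuple[int, int]
) -> float:
    """Fraction of the intron's bases covered by the read's aligned blocks."""
    istart, iend = intron
    if iend <= istart:
        raise ValueError("intron length must be >= 1")
    covered = 0
    for s, e in read_blocks:
        covered += max(0, min(e, iend) - max(s, istart))
    return covered / (iend - istart)


def call_splicing(
    molecule: MoleculeConsensus,
    model: GeneModel,
    ratio_threshold: float = IR_RATIO_THRESHOLD,
) -> SpliceCall:
    """Classify one molecule as spliced/unspliced against its gene model.

    An intron is retained when its mapping ratio strictly exceeds the
    threshold; a molecule with at least one retained intron is unspliced.
    Introns entirely outside the aligned span are unobserved (``None``) and
    count neither way.  Intronless genes yield a spliced call with no flags.
    """
    blocks = tuple(sorted(molecule.blocks))
    span_lo = blocks[0][0]
    span_hi = blocks[-1][1]
    flags: list[bool | None] = []
    for intron in model.introns:
        if intron[1] <= span_lo or intron[0] >= span_hi:
            flags.append(None)
        else:
            flags.append(intron_mapping_ratio(blocks, intron) > ratio_threshold)
    status = UNSPLICED if any(f is True for f in flags) else SPLICED
    return SpliceCall(molecule.barcode, molecule.umi, molecule.gene_id, tuple(flags), status)


# ---------------------------------------------------------------------------
# polyA sites
# ---------------------------------------------------------------------------


def extract_polya_site(molecule: MoleculeConsensus) -> int:
    """Genomic coordinate of the molecule's aligned 3' terminus.

    Strand-aware: the rightmost block end on '+', the leftmost block start
    on '-'.  The strand is the molecule's transcript strand.
    """
    blocks = sorted(molecule.blocks)
    return blocks[-1][1] if molecule.strand == "+" else blocks[0][0]


def cluster_polya_sites(
    sites: Sequence[int],
    threshold: int = PA_CLUSTER_THRESHOLD,
    chrom: str = "",
    strand: str = "+",
    gene_id: str = "",
) -> list[PolyACluster]:
    """Single-linkage clustering of 3' termini with the given gap threshold.

    Sites are sorted and cut wherever the gap to the next site exceeds the
    threshold; chains of gaps each <= threshold merge transitively.  The
    representative is the median member (lower of the two middles for even
    cluster sizes).  Invariant under input permutation.
    """
    if not sites:
        return []
    ordered = sorted(sites)
    groups: list[list[int]] = [[ordered[0]]]
    for s in ordered[1:]:
        if s - groups[-1][-1] <= threshold:
            groups[-1].append(s)
        else:
            groups.append([s])
    clusters = []
    for i, g in enumerate(groups, start=1):
        rep = g[(len(g) - 1) // 2]
        clusters.append(
            PolyACluster(
                cluster_id=f"{gene_id}|PA{i}",
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                member_sites=tuple(g),
                representative=rep,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _sparse_from_counts(
    counts: Mapping[tuple[str, str], int], nuclei: list[str], features: list[str]
) -> sp.csr_matrix:
    bidx = {b: i for i, b in enumerate(nuclei)}
    fidx = {f: i for i, f in enumerate(features)}
    rows, cols, vals = [], [], []
    for (b, f), v in counts.items():
        rows.append(bidx[b])
        cols.append(fidx[f])
        vals.append(v)
    return sp.coo_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(len(nuclei), len(features))
    ).tocsr()


def build_splicing_matrix(calls: Iterable[SpliceCall]) -> LayerMatrix:
    """Two features per gene — ``gene|spliced`` and ``gene|unspliced`` counts."""
    counts: dict[tuple[str, str], int] = defaultdict(int)
    genes: set[str] = set()
    nuclei_seen: set[str] = set()
    for c in calls:
        counts[(c.barcode, f"{c.gene_id}|{c.status}")] += 1
        genes.add(c.gene_id)
        nuclei_seen.add(c.barcode)
    nuclei = sorted(nuclei_seen)
    features = [f"{g}|{s}" for g in sorted(genes) for s in (SPLICED, UNSPLICED)]
    used = {f for _, f in counts}
    features = [f for f in features if f in used]
    return LayerMatrix("splicing", nuclei, features, _sparse_from_counts(counts, nuclei, features))


def build_apa_matrix(
    molecules: Iterable[MoleculeConsensus],
    clusters_by_gene: Mapping[str, list[PolyACluster]] | None = None,
    threshold: int = PA_CLUSTER_THRESHOLD,
) -> tuple[LayerMatrix, dict[str, list[PolyACluster]]]:
    """Count molecules per (nucleus, polyA-site cluster).

    Clusters are derived per (gene, strand) from the molecules themselves
    unless supplied.  Every molecule's site belongs to exactly one cluster
    (the clustering is a partition of observed sites), so per-gene cluster
    counts sum to per-gene molecule counts.
    """
    mols = list(molecules)
    sites_by_gene: dict[str, list[int]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    for m in mols:
        sites_by_gene[m.gene_id].append(extract_polya_site(m))
        meta[m.gene_id] = (m.chrom, m.strand)
    if clusters_by_gene is None:
        clusters_by_gene = {
            g: cluster_polya_sites(s, threshold, meta[g][0], meta[g][1], g)
            for g, s in sites_by_gene.items()
        }
    # map site -> cluster per gene
    site_to_cluster: dict[str, dict[int, str]] = {}
    for g, clusters in clusters_by_gene.items():
        lut: dict[int, str] = {}
        for c in clusters:
            for s in c.member_sites:
                lut[s] = c.cluster_id
        site_to_cluster[g] = lut

    counts: dict[tuple[str, str], int] = defaultdict(int)
    nuclei_seen: set[str] = set()
    used_features: set[str] = set()
    for m in mols:
        site = extract_polya_site(m)
        lut = site_to_cluster.get(m.gene_id, {})
        if site not in lut:
            raise RuntimeError(
                f"polyA site {site} of gene {m.gene_id} not in any cluster (partition violated)"
            )
        cid = lut[site]
        counts[(m.barcode, cid)] += 1
        nuclei_seen.add(m.barcode)
        used_features.add(cid)
    nuclei = sorted(nuclei_seen)
    features = [
        c.cluster_id
        for g in sorted(clusters_by_gene)
        for c in clusters_by_gene[g]
        if c.cluster_id in used_features
    ]
    return (
        LayerMatrix("apa", nuclei, features, _sparse_from_counts(counts, nuclei, features)),
        dict(clusters_by_gene),
    )


def incompletely_spliced_ratio(
    calls: Iterable[SpliceCall], count_intronless_as_spliced: bool = True
) -> dict[str, float]:
    """Per-nucleus fraction of molecules with at least one retained intron.

    Molecules of intronless genes count as spliced (they are fully spliced
    mRNAs) unless ``count_intronless_as_spliced`` is off, in which case they
    are excluded.  Nuclei with no determinate molecule are absent from the
    result (undefined, not 0).
    """
    unspliced: dict[str, int] = defaultdict(int)
    total: dict[str, int] = defaultdict(int)
    for c in calls:
        if not c.retention_flags and not count_intronless_as_spliced:
            continue
        total[c.barcode] += 1
        if c.status == UNSPLICED:
            unspliced[c.barcode] += 1
    return {b: unspliced[b] / n for b, n in total.items() if n > 0}
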