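"""Rescue cell barcodes and UMIs on error-prone long reads.

The assignment problem: a long read's cell barcode and UMI sit in its
*unmapped* clip flanks, garbled by the sequencing error channel.  Accurate
short reads from the same cDNA pool provide the complete set of real
(barcode, UMI) combinations together with the genomic position of their
molecule.  For each long read we therefore only consider combinations whose
guide records fall in genome bins overlapping (or adjacent to) the read's
mapped span, and align each candidate's 26-nt barcode+UMI query against the
read's flanks with a seeded Smith-Waterman local alignment:

* seeding: a candidate/flank pair is only aligned when they share an exact
  7-mer (the word size of the heuristic pre-filter);
* scoring: match +1, mismatch -1, linear gap -2 per gap base;
* acceptance: the closest candidate wins if it has at most three base
  errors (mismatches + gap bases + unaligned query bases) in the barcode
  segment and at most three in the UMI segment; reads whose minimum is
  reached by more than one distinct (barcode, UMI) pair are discarded as
  ambiguous.

Reads sharing an assigned (barcode, UMI, gene) derive from one RNA molecule
and are collapsed to a consensus sequence by per-column majority vote
against the longest read as backbone.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from numba import njit

from .formats import AlignedLongRead, GuideRecord, revcomp
from .illumina_counts import BinIndex

logger = logging.getLogger(__name__)

STATUS_ASSIGNED = "assigned"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_CANDIDATE = "no_candidate"
STATUS_OVER_THRESHOLD = "over_threshold"
STATUS_FILTERED = "filtered"

DEFAULT_MAX_ERRORS = 3
DEFAULT_MAX_CLIP = 150
#: expected adapter(30) + barcode(16) + UMI(10) structural bases on the
#: barcode-bearing end; subtracted before the chimera clip test there.
DEFAULT_STRUCTURAL_ALLOWANCE = 56


@dataclass(frozen=True)
class AlignmentScoreScheme:
    """Local-alignment scoring: reward/penalty per base, linear gaps."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = 0
    gap_extend: int = -2
    seed_word_size: int = 7

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


DEFAULT_SCHEME = AlignmentScoreScheme()


@dataclass
class Assignment:
    """Outcome of barcode/UMI rescue for one read."""

    read_id: str
    barcode: str | None = None
    umi: str | None = None
    gene_id: str | None = None
    barcode_errors: int = -1
    umi_errors: int = -1
    n_best_candidates: int = 0
    status: str = STATUS_NO_CANDIDATE

    def __post_init__(self) -> None:
        if self.status == STATUS_ASSIGNED and self.n_best_candidates != 1:
            raise ValueError("an assigned read must have a unique best candidate")


@dataclass
class MoleculeConsensus:
    """Error-corrected consensus of the reads sharing one (barcode, UMI, gene)."""

    barcode: str
    umi: str
    gene_id: str
    consensus_seq: str
    n_supporting_reads: int
    blocks: tuple[tuple[int, int], ...]
    chrom: str = ""
    strand: str = "+"


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------


def filter_long_reads(
    reads: Iterable[AlignedLongRead],
    max_clip: int = DEFAULT_MAX_CLIP,
    structural_allowance: int = DEFAULT_STRUCTURAL_ALLOWANCE,
) -> tuple[list[AlignedLongRead], list[tuple[AlignedLongRead, str]]]:
    """Drop multi-mapped and chimeric reads.

    A read with any secondary/supplementary alignment record is multi-mapped
    and dropped entirely.  A read is chimeric when an unmapped end exceeds
    ``max_clip`` nt; the larger flank is presumed to carry the
    adapter+barcode+UMI structure and is granted ``structural_allowance``
    extra nt before the test (set it to 0 for the literal clip rule).
    Comparisons are strict: a clip of exactly ``max_clip`` is kept.
    """
    by_id: dict[str, list[AlignedLongRead]] = defaultdict(list)
    order: list[str] = []
    for r in reads:
        if r.read_id not in by_id:
            order.append(r.read_id)
        by_id[r.read_id].append(r)

    kept: list[AlignedLongRead] = []
    dropped: list[tuple[AlignedLongRead, str]] = []
    for rid in order:
        group = by_id[rid]
        primary = next(
            (r for r in group if not r.is_secondary and not r.is_supplementary), group[0]
        )
        if len(group) > 1 or any(r.is_secondary or r.is_supplementary for r in group):
            dropped.append((primary, "multimapped"))
            continue
        big, small = max(primary.clip5, primary.clip3), min(primary.clip5, primary.clip3)
        if big > max_clip + structural_allowance or small > max_clip:
            dropped.append((primary, "chimeric"))
            continue
        kept.append(primary)
    return kept, dropped


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def seed_scan(flank: str, query: str, word_size: int = 7) -> list[int]:
    """Offsets in ``flank`` where any exact ``word_size``-mer of ``query`` occurs.

    An empty result means the candidate is skipped before Smith-Waterman,
    mirroring the word-match gate of a heuristic aligner.
    """
    if len(query) < word_size or len(flank) < word_size:
        return []
    words = {query[i : i + word_size] for i in range(len(query) - word_size + 1)}
    return [i for i in range(len(flank) - word_size + 1) if flank[i : i + word_size] in words]


# ---------------------------------------------------------------------------
# Smith-Waterman with error attribution
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=False)
def _sw_kernel(a, b, match, mismatch, gap, boundary):  # pragma: no cover - numba
    """Linear-gap local alignment of query ``b`` against target ``a``.

    Returns (score, bc_err, umi_err, a_start, a_end, b_start, b_end) where
    errors are mismatches + gap bases within the optimal local alignment
    plus unaligned ``b`` bases, split at query position ``boundary``.
    The optimum cell is the first best in row-major order; traceback
    prefers diagonal, then gap-in-b, then gap-in-a.
    """
    la = a.shape[0]
    lb = b.shape[0]
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] and a[i - 1] < 4 else mismatch
            v = H[i - 1, j - 1] + s
            if H[i - 1, j] - gap > v:
                v = H[i - 1, j] - gap
            if H[i, j - 1] - gap > v:
                v = H[i, j - 1] - gap
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    bc_err = 0
    umi_err = 0
    i = bi
    j = bj
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if a[i - 1] == b[j - 1] and a[i - 1] < 4 else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == mismatch:
                if j - 1 < boundary:
                    bc_err += 1
                else:
                    umi_err += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - gap:
            # gap in query: attribute to the last query base consumed before it
            if j - 1 < boundary:
                bc_err += 1
            else:
                umi_err += 1
            i -= 1
        else:
            # gap in target: consumes query base j-1
            if j - 1 < boundary:
                bc_err += 1
            else:
                umi_err += 1
            j -= 1
    b_start = j
    b_end = bj
    a_start = i
    a_end = bi
    for p in range(0, b_start):
        if p < boundary:
            bc_err += 1
        else:
            umi_err += 1
    for p in range(b_end, lb):
        if p < boundary:
            bc_err += 1
        else:
            umi_err += 1
    return best, bc_err, umi_err, a_start, a_end, b_start, b_end


def smith_waterman(
    a: str, b: str, scheme: AlignmentScoreScheme = DEFAULT_SCHEME, boundary: int | None = None
) -> tuple[int, tuple[int, int, int, int], int, int]:
    """Local alignment of query ``b`` against target ``a``.

    Returns ``(score, (a_start, a_end, b_start, b_end), bc_errors, umi_errors)``
    where the error count is mismatches + gap bases inside the optimal local
    alignment plus unaligned ``b`` bases (a truncated query counts its
    missing bases), split at ``boundary`` (default: all in the first bucket).
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if boundary is None:
        boundary = len(b)
    score, bc, umi, a0, a1, b0, b1 = _sw_kernel(
        _encode(a), _encode(b), scheme.match, scheme.mismatch, -scheme.gap_extend, boundary
    )
    return int(score), (int(a0), int(a1), int(b0), int(b1)), int(bc), int(umi)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def _flank_targets(read: AlignedLongRead) -> list[str]:
    """Both flanks and their reverse complements (barcode orientation unknown)."""
    targets = []
    for flank in (read.flank5, read.flank3):
        if flank:
            targets.append(flank)
            targets.append(revcomp(flank))
    return targets


def _best_over_targets(
    targets: Sequence[str],
    query: str,
    scheme: AlignmentScoreScheme,
    boundary: int,
    use_seed: bool,
) -> tuple[int, int, int] | None:
    """Minimal-error alignment of ``query`` over the given flank targets.

    Returns ``(barcode_errors, umi_errors, score)`` of the best target or
    ``None`` when seeding rejects every target.
    """
    best: tuple[int, int, int] | None = None  # (total, -score, bc_err) ordering key
    result: tuple[int, int, int] | None = None
    for t in targets:
        if use_seed and not seed_scan(t, query, scheme.seed_word_size):
            continue
        score, _, bc_err, umi_err = smith_waterman(t, query, scheme, boundary)
        key = (bc_err + umi_err, -score, bc_err)
        if best is None or key < best:
            best = key
            result = (bc_err, umi_err, score)
    return result


def assign_read(
    read: AlignedLongRead,
    bin_index: BinIndex,
    scheme: AlignmentScoreScheme = DEFAULT_SCHEME,
    max_errors: int = DEFAULT_MAX_ERRORS,
    use_seed: bool = True,
) -> Assignment:
    """Assign the closest guide (barcode, UMI) to one filtered read.

    Candidates come from bins overlapping or adjacent to the read's mapped
    span.  Each candidate's 26-nt barcode+UMI query is aligned against both
    flanks and their reverse complements; the minimal-error candidate wins
    when unique and within ``max_errors`` for barcode and UMI separately.
    """
    candidates = bin_index.lookup(read.chrom, read.start, read.end)
    return _assign_from_candidates(read, candidates, scheme, max_errors, use_seed)


def exhaustive_assign(
    read: AlignedLongRead,
    records: Iterable[GuideRecord],
    scheme: AlignmentScoreScheme = DEFAULT_SCHEME,
    max_errors: int = DEFAULT_MAX_ERRORS,
) -> Assignment:
    """Assignment over an explicit candidate set with no seeding (oracle path)."""
    return _assign_from_candidates(read, list(records), scheme, max_errors, use_seed=False)


def _assign_from_candidates(
    read: AlignedLongRead,
    candidates: Sequence[GuideRecord],
    scheme: AlignmentScoreScheme,
    max_errors: int,
    use_seed: bool,
) -> Assignment:
    pairs: dict[tuple[str, str], str] = {}
    for rec in candidates:
        pairs.setdefault((rec.barcode, rec.umi), rec.gene_id)
    if not pairs:
        return Assignment(read_id=read.read_id, status=STATUS_NO_CANDIDATE)

    targets = _flank_targets(read)
    boundary = GuideRecord.BARCODE_LEN
    best_total: int | None = None
    best_pairs: list[tuple[str, str]] = []
    best_detail: tuple[int, int] = (-1, -1)
    best_score = -1
    for (bc, umi), gene in sorted(pairs.items()):
        hit = _best_over_targets(targets, bc + umi, scheme, boundary, use_seed)
        if hit is None:
            continue
        bc_err, umi_err, score = hit
        total = bc_err + umi_err
        if best_total is None or total < best_total:
            best_total = total
            best_pairs = [(bc, umi)]
            best_detail = (bc_err, umi_err)
            best_score = score
        elif total == best_total:
            best_pairs.append((bc, umi))
            if score > best_score:  # keep the detail of the best-scoring tie
                best_detail = (bc_err, umi_err)
                best_score = score
    if best_total is None:
        return Assignment(read_id=read.read_id, status=STATUS_NO_CANDIDATE)
    distinct = sorted(set(best_pairs))
    if len(distinct) > 1:
        return Assignment(
            read_id=read.read_id, n_best_candidates=len(distinct), status=STATUS_AMBIGUOUS
        )
    bc, umi = distinct[0]
    bc_err, umi_err = best_detail
    if bc_err > max_errors or umi_err > max_errors:
        return Assignment(
            read_id=read.read_id,
            barcode=bc,
            umi=umi,
            barcode_errors=bc_err,
            umi_errors=umi_err,
            n_best_candidates=1,
            status=STATUS_OVER_THRESHOLD,
        )
    return Assignment(
        read_id=read.read_id,
        barcode=bc,
        umi=umi,
        gene_id=pairs[(bc, umi)],
        barcode_errors=bc_err,
        umi_errors=umi_err,
        n_best_candidates=1,
        status=STATUS_ASSIGNED,
    )


def assign_all(
    reads: Iterable[AlignedLongRead],
    bin_index: BinIndex,
    scheme: AlignmentScoreScheme = DEFAULT_SCHEME,
    max_errors: int = DEFAULT_MAX_ERRORS,
    max_clip: int = DEFAULT_MAX_CLIP,
    structural_allowance: int = DEFAULT_STRUCTURAL_ALLOWANCE,
    use_seed: bool = True,
) -> Iterator[tuple[Assignment, AlignedLongRead | None]]:
    """Filter then assign a read stream; exactly one Assignment per read_id."""
    kept, dropped = filter_long_reads(reads, max_clip, structural_allowance)
    for read, reason in dropped:
        yield Assignment(read_id=read.read_id, status=STATUS_FILTERED), None
    for read in kept:
        yield assign_read(read, bin_index, scheme, max_errors, use_seed), read


# ---------------------------------------------------------------------------
# per-molecule consensus
# ---------------------------------------------------------------------------


def consensus_per_molecule(
    reads: Sequence[tuple[str, str]],
) -> str:
    """Consensus sequence of the reads (``(read_id, seq)``) of one molecule.

    A single read is its own consensus.  Otherwise the longest read is the
    backbone (ties broken by read_id for determinism) and every other read
    is globally aligned to it; each backbone column takes the majority base
    (ties keep the backbone base, a gap majority deletes the column) and
    majority insertions between columns are added.
    """
    import edlib

    if not reads:
        raise ValueError("molecule with no reads")
    if len(reads) == 1:
        return reads[0][1]
    ordered = sorted(reads, key=lambda r: (-len(r[1]), r[0]))
    backbone = ordered[0][1]
    n_cols = len(backbone)
    # column votes: backbone itself votes once everywhere
    base_votes: list[Counter] = [Counter({backbone[i]: 1}) for i in range(n_cols)]
    ins_votes: list[Counter] = [Counter({"": 1}) for _ in range(n_cols + 1)]

    for _, seq in ordered[1:]:
        aln = edlib.align(seq, backbone, mode="NW", task="path")
        qi = 0  # position in seq (query)
        ti = 0  # position in backbone (target)
        for length, op in _iter_cigar(aln["cigar"]):
            if op in "=X":
                for _ in range(length):
                    base_votes[ti][seq[qi]] += 1
                    ins_votes[ti + 1][""] += 1  # explicit no-insertion vote
                    qi += 1
                    ti += 1
            elif op == "I":  # extra bases in the read, between backbone cols
                ins_votes[ti][seq[qi : qi + length]] += 1
                ins_votes[ti][""] -= 1  # replace this read's implicit empty vote
                qi += length
            elif op == "D":  # read lacks backbone bases
                for _ in range(length):
                    base_votes[ti]["-"] += 1
                    ti += 1
            else:  # pragma: no cover
                raise ValueError(f"unexpected edlib op {op}")

    out: list[str] = []
    for i in range(n_cols):
        ins = _majority(ins_votes[i], default="")
        if ins:
            out.append(ins)
        base = _majority(base_votes[i], default=backbone[i], prefer=backbone[i])
        if base != "-":
            out.append(base)
    tail = _majority(ins_votes[n_cols], default="")
    if tail:
        out.append(tail)
    return "".join(out)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _majority(votes: Counter, default: str, prefer: str | None = None):
    if not votes:
        return default
    top = max(votes.values())
    winners = sorted(k for k, v in votes.items() if v == top)
    if prefer is not None and prefer in winners:
        return prefer
    if len(winners) > 1 and "" in winners:
        return ""
    return winners[0]


def collapse_molecules(
    assignments: Iterable[tuple[Assignment, AlignedLongRead]],
) -> list[MoleculeConsensus]:
    """Group assigned reads by (barcode, UMI, gene) into consensus molecules.

    The representative alignment blocks are those of the longest supporting
    read (the consensus backbone).
    """
    groups: dict[tuple[str, str, str], list[tuple[Assignment, AlignedLongRead]]] = defaultdict(list)
    for asn, read in assignments:
        if asn.status != STATUS_ASSIGNED or read is None:
            continue
        groups[(asn.barcode, asn.umi, asn.gene_id or "")].append((asn, read))
    out = []
    for (bc, umi, gene), members in sorted(groups.items()):
        reads = [(r.read_id, r.seq) for _, r in members]
        seq = consensus_per_molecule(reads)
        backbone = max(members, key=lambda m: (len(m[1].seq), m[1].read_id))[1]
        out.append(
            MoleculeConsensus(
                barcode=bc,
                umi=umi,
                gene_id=gene,
                consensus_seq=seq,
                n_supporting_reads=len(members),
                blocks=backbone.blocks,
                chrom=backbone.chrom,
                strand=backbone.strand,
            )
        )
    return out
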