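"""Small builders for hand-crafted reads shared by boundary tests."""

import numpy as np

from nucleolong import AlignedLongRead, GuideRecord, build_bin_index

_RNG = np.random.default_rng(99)


def _rand(n):
    return "".join(_RNG.choice(list("ACGT"), size=n))


def make_flanked_read(clip5, blocks=((1000, 1400),), read_id="r"):
    body = _rand(sum(e - s for s, e in blocks))
    flank = _rand(clip5)
    return AlignedLongRead(
        read_id=read_id,
        chrom="chr1",
        strand="+",
        blocks=tuple(blocks),
        clip5=clip5,
        clip3=0,
        seq=flank + body,
    )


def read_with_mutated_barcode(n_subs):
    """A read whose flank carries the candidate barcode with interior
    substitutions plus a verbatim UMI; returns (read, bin_index).

    Substituted positions are spread out so the optimal local alignment
    keeps the full barcode (isolated mismatches cost less than trimming),
    making the error count equal ``n_subs`` exactly.
    """
    bc, umi = _rand(16), _rand(10)
    mutated = list(bc)
    positions = [3, 7, 11, 14][:n_subs] if n_subs <= 4 else list(range(2, 2 + n_subs))
    for p in positions:
        mutated[p] = "ACGT".replace(mutated[p], "")[0]
    flank = _rand(30) + "".join(mutated) + umi + "T" * 20
    body = _rand(400)
    read = AlignedLongRead(
        read_id="r",
        chrom="chr1",
        strand="+",
        blocks=((1000, 1400),),
        clip5=len(flank),
        clip3=0,
        seq=flank + body,
    )
    index = build_bin_index([GuideRecord(bc, umi, "g1", "chr1", 1100)])
    return read, index
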