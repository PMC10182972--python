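"""Independent oracles used only by the tests.

These deliberately avoid the implementation's code paths: the run scanner
enumerates substrings, the coordinate walker expands exons base by base,
and the read interpreter goes through ``pysam.AlignedSegment
.get_aligned_pairs`` instead of walking cigartuples.
"""

from __future__ import annotations

import numpy as np
import pysam


def brute_force_runs(seq: str, min_length: int) -> list[tuple[str, int, int]]:
    """All maximal homopolymer runs, by testing every candidate substring."""
    n = len(seq)
    out = []
    for i in range(n):
        j = i + min_length - 1
        if j >= n:
            break
        if any(seq[k] != seq[i] for k in range(i, j + 1)):
            continue
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        left_ok = i == 0 or seq[i - 1] != seq[i]
        if left_ok:
            out.append((seq[i], i + 1, j + 1))
    return out


def walk_cds_positions(model) -> list[int]:
    """Genomic position of every cds base, by per-base exon walking."""
    out: list[int] = []
    for s, e in model.exons:
        if model.strand == "+":
            out.extend(range(s, e + 1))
        else:
            out.extend(range(e, s - 1, -1))
    return out


def _shift_del(ref: str, s1: int, e1: int) -> tuple[int, int]:
    while s1 > 1 and ref[s1 - 2] == ref[e1 - 1]:
        s1 -= 1
        e1 -= 1
    return s1, e1


def _shift_ins(ref: str, anchor1: int, seq: str) -> int:
    while anchor1 >= 1 and seq and ref[anchor1 - 1] == seq[-1]:
        seq = ref[anchor1 - 1] + seq[:-1]
        anchor1 -= 1
    return anchor1


def interpret_read(read, ref: str):
    """(covered, ins_anchors, del_positions) as 1-based sets, via aligned pairs.

    Leading/trailing query-only groups are soft clips; interior query-only
    runs are insertions anchored after the last aligned reference base.
    Indels are left-shifted against the full contig sequence ``ref``.
    """
    pairs = read.get_aligned_pairs()
    # strip soft clips
    lo = 0
    while lo < len(pairs) and pairs[lo][1] is None:
        lo += 1
    hi = len(pairs)
    while hi > lo and pairs[hi - 1][1] is None:
        hi -= 1
    pairs = pairs[lo:hi]

    covered: set[int] = set()
    ins_anchors: set[int] = set()
    del_positions: set[int] = set()
    last_ref: int | None = None
    i = 0
    while i < len(pairs):
        q, r = pairs[i]
        if r is not None and q is not None:  # aligned base
            covered.add(r + 1)
            last_ref = r + 1
            i += 1
        elif q is None:  # deletion stretch
            j = i
            while j < len(pairs) and pairs[j][0] is None:
                j += 1
            s1, e1 = pairs[i][1] + 1, pairs[j - 1][1] + 1
            covered.update(range(s1, e1 + 1))
            s1, e1 = _shift_del(ref, s1, e1)
            del_positions.update(range(s1, e1 + 1))
            last_ref = pairs[j - 1][1] + 1
            i = j
        else:  # insertion stretch
            j = i
            while j < len(pairs) and pairs[j][1] is None:
                j += 1
            seq = read.query_sequence[pairs[i][0] : pairs[j - 1][0] + 1]
            anchor = last_ref if last_ref is not None else 0
            ins_anchors.add(_shift_ins(ref, anchor, seq))
            i = j
    return covered, ins_anchors, del_positions


def oracle_counts(reads, region, ref: str):
    """Footprint tallies assembled from :func:`interpret_read`."""
    L = region.length
    fp_start = region.genomic_start - 1
    fp_end = region.genomic_end
    depth = np.zeros(L + 1, dtype=int)
    ins = np.zeros(L + 1, dtype=int)
    dele = np.zeros(L + 1, dtype=int)
    for read in reads:
        if (
            read.is_unmapped
            or read.is_duplicate
            or read.is_secondary
            or read.is_supplementary
            or read.is_qcfail
            or read.mapping_quality < 1
        ):
            continue
        covered, ins_anchors, del_positions = interpret_read(read, ref)
        for g in covered:
            if fp_start <= g <= fp_end:
                depth[g - fp_start] += 1
        for g in ins_anchors:
            if fp_start <= g <= fp_end:
                ins[g - fp_start] += 1
        for g in del_positions:
            if fp_start <= g <= fp_end:
                dele[g - fp_start] += 1
    return depth, ins, dele


def random_reads(rng, ref: str, region, n_reads: int, header):
    """Reads with randomized S/M/I/D structure around a homopolymer region."""
    reads = []
    for i in range(n_reads):
        start0 = int(
            rng.integers(
                max(0, region.genomic_start - 60), region.genomic_end + 5
            )
        )
        cigar: list[tuple[int, int]] = []
        seq_parts: list[str] = []
        if rng.random() < 0.25:
            sc = int(rng.integers(1, 6))
            cigar.append((4, sc))
            seq_parts.append("".join(rng.choice(list("ACGT"), sc)))
        ref_pos = start0
        n_blocks = int(rng.integers(1, 4))
        for b in range(n_blocks):
            m = int(rng.integers(5, 40))
            m = min(m, len(ref) - ref_pos)
            if m <= 0:
                break
            block = list(ref[ref_pos : ref_pos + m])
            for k in range(m):  # occasional mismatches
                if rng.random() < 0.03:
                    block[k] = str(rng.choice(list("ACGT")))
            seq_parts.append("".join(block))
            cigar.append((0, m))
            ref_pos += m
            if b < n_blocks - 1 and ref_pos < len(ref) - 5:
                if rng.random() < 0.5:
                    ln = int(rng.integers(1, 4))
                    ins = "".join(
                        region.base if rng.random() < 0.5 else str(rng.choice(list("ACGT")))
                        for _ in range(ln)
                    )
                    seq_parts.append(ins)
                    cigar.append((1, ln))
                else:
                    ln = int(rng.integers(1, 4))
                    ln = min(ln, len(ref) - ref_pos)
                    cigar.append((2, ln))
                    ref_pos += ln
        if cigar and cigar[-1][0] != 0:  # must end aligned
            cigar.append((0, min(5, len(ref) - ref_pos)))
            seq_parts.append(ref[ref_pos : ref_pos + cigar[-1][1]])
        if rng.random() < 0.25:
            sc = int(rng.integers(1, 6))
            cigar.append((4, sc))
            seq_parts.append("".join(rng.choice(list("ACGT"), sc)))
        if not any(op == 0 and ln > 0 for op, ln in cigar):
            continue
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"rand{i:04d}"
        seg.query_sequence = "".join(seq_parts)
        seg.flag = 0
        seg.reference_id = header.get_tid(region.chromosome)
        seg.reference_start = start0
        seg.mapping_quality = 60
        seg.cigartuples = [(op, ln) for op, ln in cigar if ln > 0]
        seg.query_qualities = pysam.qualitystring_to_array(
            "I" * len(seg.query_sequence)
        )
        reads.append(seg)
    return reads
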