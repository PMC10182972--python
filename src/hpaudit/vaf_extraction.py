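"""Per-sample indel VAFs at homopolymer regions from aligned reads.

This reproduces, programmatically, the manual read-count audit one would do
in a genome browser at each homopolymer: for every read overlapping a
region's footprint we walk the CIGAR string, left-align each indel against
the reference, and tally per reference position the reads opening an
insertion there or deleted there.  The per-region VAFs are then

    vaf_ins = max_p ins_reads[p] / total_reads
    vaf_del = max_p del_reads[p] / total_reads

with ``total_reads`` the depth at the *first base of the stretch* (the
anchor), i.e. the maximum per-position indel read tally over the footprint
divided by the anchor depth.  Because a 1-bp indel inside a homopolymer is
representationally ambiguous, left-alignment pushes insertions to open at
the flank base immediately 5' of the stretch and deletions to start at the
first run base; the footprint therefore carries one leading flank position.

Depth counts reads aligned (match/mismatch) or deleted at a position, using
the alignment as recorded; indel tallies use the left-shifted events.
Duplicate, secondary, supplementary and QC-fail reads are excluded;
``mapq_min`` defaults to 1 and ``baseq_min`` to 0, mirroring a browser's
default view (the counting convention, not an assertion about any
particular study's settings).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import VafMatrix
from .regions import HomopolymerRegion

__all__ = [
    "PileupCounts",
    "SampleRegionVaf",
    "count_indels_at_region",
    "summarize_region",
    "extract_cohort",
    "DEFAULT_DEPTH_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_THRESHOLD = 100  # regions under 100X are not evaluable

_MATCH_OPS = {0, 7, 8}  # M, =, X


@dataclass
class PileupCounts:
    """Per-position tallies over a region footprint (flank + stretch).

    Arrays have length ``region.length + 1``; index 0 is the flank position
    immediately 5' of the stretch (where left-aligned insertions open),
    indices 1..L are the run bases.  ``anchor_depth`` is the depth at the
    first base of the stretch.
    """

    region_id: str
    footprint_start: int  # 1-based genomic coordinate of the flank position
    per_position_depth: np.ndarray
    per_position_ins_reads: np.ndarray
    per_position_del_reads: np.ndarray

    @property
    def anchor_depth(self) -> int:
        return int(self.per_position_depth[1])


@dataclass(frozen=True)
class SampleRegionVaf:
    """One sample's insertion/deletion VAFs at one homopolymer region."""

    sample_id: str
    region_id: str
    total_reads: int
    max_ins_reads: int
    max_del_reads: int
    vaf_ins: float
    vaf_del: float
    evaluable: bool


def _fetch_window(reference, chrom: str, start1: int, end1: int) -> str:
    """Reference bases for [start1, end1] (1-based incl.), padded with 'N'.

    ``reference`` may be a pysam.FastaFile (anything with ``fetch``), a
    mapping contig→sequence, or a single contig's sequence string.
    """
    if hasattr(reference, "fetch"):
        contig_len = None
        if hasattr(reference, "get_reference_length"):
            contig_len = reference.get_reference_length(chrom)
        lo = max(start1, 1)
        hi = min(end1, contig_len) if contig_len else end1
        core = reference.fetch(chrom, lo - 1, hi).upper()
    else:
        seq = reference[chrom] if isinstance(reference, Mapping) else reference
        lo = max(start1, 1)
        hi = min(end1, len(seq))
        core = seq[lo - 1 : hi].upper()
    return "N" * (lo - start1) + core + "N" * (end1 - hi)


def _left_shift_insertion(
    window: str, w_start1: int, anchor1: int, seq: str
) -> tuple[int, str]:
    # insertion opens AFTER 1-based position anchor1; shift while the last
    # inserted base equals the reference base at the anchor
    if anchor1 > w_start1 + len(window) - 1:  # right of window: cannot reach it
        return anchor1, seq
    while anchor1 >= w_start1 and seq:
        ref_base = window[anchor1 - w_start1]
        if ref_base == "N" or seq[-1] != ref_base:
            break
        seq = ref_base + seq[:-1]
        anchor1 -= 1
    return anchor1, seq


def _left_shift_deletion(
    window: str, w_start1: int, s1: int, e1: int
) -> tuple[int, int]:
    w_end1 = w_start1 + len(window) - 1
    if e1 > w_end1:  # tail outside window: leave as recorded
        return s1, e1
    while s1 - 1 >= w_start1:
        prev, last = window[s1 - 1 - w_start1], window[e1 - w_start1]
        if prev == "N" or prev != last:
            break
        s1 -= 1
        e1 -= 1
    return s1, e1


def _use_read(read, mapq_min: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_duplicate
        or read.is_secondary
        or read.is_supplementary
        or read.is_qcfail
        or read.mapping_quality < mapq_min
    )


def count_indels_at_region(
    alignments: Iterable,
    region: HomopolymerRegion,
    reference,
    mapq_min: int = 1,
    baseq_min: int = 0,
) -> PileupCounts:
    """Explicit CIGAR-walk pileup over one region's footprint.

    ``alignments`` is any iterable of pysam ``AlignedSegment``s overlapping
    the region (e.g. ``AlignmentFile.fetch(...)`` or an in-memory list).
    Reads lacking a CIGAR are skipped.  A read carrying both an insertion
    and a deletion in the footprint increments both tallies.
    """
    L = region.length
    fp_start = region.genomic_start - 1  # flank position, 1-based
    fp_end = region.genomic_end
    n = L + 1
    depth = np.zeros(n, dtype=np.int64)
    ins_counts = np.zeros(n, dtype=np.int64)
    del_counts = np.zeros(n, dtype=np.int64)

    pad = L + 32
    w_start1 = fp_start - pad
    window = _fetch_window(reference, region.chromosome, w_start1, fp_end + pad)

    for read in alignments:
        if not _use_read(read, mapq_min) or read.cigartuples is None:
            continue
        ref_pos = read.reference_start  # 0-based
        qpos = 0
        seq = read.query_sequence
        quals = read.query_qualities
        covered: set[int] = set()
        ins_at: set[int] = set()
        del_at: set[int] = set()
        for op, ln in read.cigartuples:
            if op in _MATCH_OPS:
                g_first = ref_pos + 1
                for g in range(max(g_first, fp_start), min(ref_pos + ln, fp_end) + 1):
                    if (
                        baseq_min <= 0
                        or quals is None
                        or quals[qpos + (g - g_first)] >= baseq_min
                    ):
                        covered.add(g)
                ref_pos += ln
                qpos += ln
            elif op == 1:  # I — opens after the last aligned base (= ref_pos, 1-based)
                ins_seq = seq[qpos : qpos + ln] if seq else region.base * ln
                anchor, _ = _left_shift_insertion(window, w_start1, ref_pos, ins_seq)
                if fp_start <= anchor <= fp_end:
                    ins_at.add(anchor)
                qpos += ln
            elif op == 2:  # D
                s1, e1 = ref_pos + 1, ref_pos + ln
                # depth: the read spans these bases (as recorded)
                for g in range(max(s1, fp_start), min(e1, fp_end) + 1):
                    covered.add(g)
                s1, e1 = _left_shift_deletion(window, w_start1, s1, e1)
                for g in range(max(s1, fp_start), min(e1, fp_end) + 1):
                    del_at.add(g)
                ref_pos += ln
            elif op == 3:  # N
                ref_pos += ln
            elif op == 4:  # S
                qpos += ln
            # H and P consume neither sequence we track
        for g in covered:
            depth[g - fp_start] += 1
        for g in ins_at:
            ins_counts[g - fp_start] += 1
        for g in del_at:
            del_counts[g - fp_start] += 1

    return PileupCounts(
        region_id=region.region_id,
        footprint_start=fp_start,
        per_position_depth=depth,
        per_position_ins_reads=ins_counts,
        per_position_del_reads=del_counts,
    )


def summarize_region(
    counts: PileupCounts,
    sample_id: str,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
) -> SampleRegionVaf:
    """Collapse per-position tallies to the two per-region VAFs.

    The VAF numerators are the maxima of the per-position tallies across the
    footprint; the denominator is the anchor depth.  Zero depth yields
    missing VAFs and ``evaluable=False``.
    """
    total = counts.anchor_depth
    max_ins = int(counts.per_position_ins_reads.max())
    max_del = int(counts.per_position_del_reads.max())
    if total > 0:
        vaf_ins = max_ins / total
        vaf_del = max_del / total
    else:
        vaf_ins = vaf_del = math.nan
    return SampleRegionVaf(
        sample_id=sample_id,
        region_id=counts.region_id,
        total_reads=total,
        max_ins_reads=max_ins,
        max_del_reads=max_del,
        vaf_ins=vaf_ins,
        vaf_del=vaf_del,
        evaluable=total >= depth_threshold,
    )


def extract_cohort(
    bam_manifest: Mapping[str, str | Path] | pd.DataFrame,
    regions: Iterable[HomopolymerRegion],
    reference,
    labels: Mapping[str, str] | None = None,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    mapq_min: int = 1,
    baseq_min: int = 0,
) -> VafMatrix:
    """Batch :func:`count_indels_at_region` over samples × regions.

    ``bam_manifest`` maps sample_id → indexed BAM path (or a DataFrame with
    ``sample_id``/``path`` columns); ``reference`` is a FASTA path or an
    object accepted by :func:`count_indels_at_region`.  Samples without a
    cohort label default to ``study``.  Missing files fail fast, naming the
    sample; per-sample non-evaluable region counts are logged.
    """
    import pysam

    if isinstance(bam_manifest, pd.DataFrame):
        manifest = dict(zip(bam_manifest["sample_id"], bam_manifest["path"]))
    else:
        manifest = dict(bam_manifest)
    regions = list(regions)

    missing = [s for s, p in manifest.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"BAM missing for samples: {missing}")

    ref_obj = reference
    opened_ref = False
    if isinstance(reference, (str, Path)):
        ref_obj = pysam.FastaFile(str(reference))
        opened_ref = True

    rows: list[SampleRegionVaf] = []
    try:
        for sample_id, path in manifest.items():
            with pysam.AlignmentFile(str(path)) as bam:
                n_failed = 0
                for region in regions:
                    try:
                        reads = bam.fetch(
                            region.chromosome,
                            max(region.genomic_start - 2, 0),
                            region.genomic_end,
                        )
                    except ValueError as exc:
                        raise OSError(
                            f"{sample_id}: cannot fetch {region.region_id} "
                            f"from {path} (unindexed input or unknown contig)"
                        ) from exc
                    counts = count_indels_at_region(
                        reads, region, ref_obj, mapq_min, baseq_min
                    )
                    rec = summarize_region(counts, sample_id, depth_threshold)
                    rows.append(rec)
                    n_failed += not rec.evaluable
                if n_failed:
                    logger.info(
                        "sample %s: %d/%d regions below %dX",
                        sample_id, n_failed, len(regions), depth_threshold,
                    )
    finally:
        if opened_ref:
            ref_obj.close()

    label_map = {s: "study" for s in manifest}
    if labels is not None:
        label_map.update(dict(labels))
    return VafMatrix.from_sample_records(rows, label_map)
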