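"""Homopolymer region discovery and coordinate bookkeeping.

Ion-semiconductor chemistry misestimates the length of runs of identical
nucleotides, so the audit starts from a catalogue of every coding homopolymer
of at least ``min_length`` bases in BRCA1/2.  This module finds maximal runs
in a coding sequence, applies the inclusion policy (BRCA2 runs downstream of
c.9976 — beyond codon 3326, where truncating variants are not high-risk — are
dropped), maps coding (c.) coordinates to genomic ones through an exon
structure, and reads/writes the catalogue as TSV or BED.

Coordinate conventions: all public I/O and dataclass fields are 1-based
inclusive (matching c.-notation and the GRCh37 table shipped in
``data/brca12_homopolymers_grch37.tsv``); BED export is 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneModel",
    "HomopolymerRun",
    "HomopolymerRegion",
    "find_runs",
    "apply_region_policy",
    "cds_to_genomic",
    "genomic_to_cds",
    "discover_regions",
    "load_region_table",
    "write_region_table",
    "write_bed",
    "packaged_catalogue",
    "POLICY_CDS_CUTOFFS",
    "DEFAULT_STRANDS",
]

_BASES = frozenset("ACGT")

#: Inclusion policy: keep runs with cds_start <= cutoff (inclusive-keep).
POLICY_CDS_CUTOFFS: dict[str, int] = {"BRCA2": 9976}

#: Strand of the packaged genes (BRCA1 is transcribed from the minus strand).
DEFAULT_STRANDS: dict[str, str] = {"BRCA1": "-", "BRCA2": "+"}

_PACKAGED_TABLE = "brca12_homopolymers_grch37.tsv"


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical bases in a coding sequence (c. coordinates)."""

    base: str
    cds_start: int  # 1-based inclusive
    cds_end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.base not in _BASES:
            raise ValueError(f"run base must be one of ACGT, got {self.base!r}")
        if self.cds_end < self.cds_start or self.cds_start < 1:
            raise ValueError(
                f"invalid run interval c.{self.cds_start}_{self.cds_end}"
            )

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class GeneModel:
    """A transcript's coding sequence plus its genomic exon structure.

    ``exons`` are genomic intervals (1-based inclusive) holding coding
    sequence only, ordered 5'→3' in *transcript* orientation; for a
    minus-strand gene the first exon therefore has the largest coordinates.
    """

    gene_symbol: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        bad = set(self.cds_sequence) - _BASES
        if bad:
            pos = next(
                i for i, b in enumerate(self.cds_sequence, start=1) if b in bad
            )
            raise ValueError(
                f"cds_sequence contains non-ACGT character at position {pos}"
            )
        spans = [e - s + 1 for s, e in self.exons]
        if any(sp <= 0 for sp in spans):
            raise ValueError("exon intervals must be 1-based inclusive, end >= start")
        if sum(spans) != len(self.cds_sequence):
            raise ValueError(
                f"exon spans sum to {sum(spans)} but cds_sequence has "
                f"{len(self.cds_sequence)} bases"
            )
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)


@dataclass(frozen=True)
class HomopolymerRegion:
    """A catalogued homopolymer with both coding and genomic coordinates."""

    region_id: str
    gene_symbol: str
    transcript_id: str
    chromosome: str
    genomic_start: int  # 1-based inclusive
    genomic_end: int  # 1-based inclusive
    run: HomopolymerRun
    strand: str = "+"

    def __post_init__(self) -> None:
        span = self.genomic_end - self.genomic_start + 1
        if span != self.run.length:
            raise ValueError(
                f"{self.region_id}: genomic span {span} does not match "
                f"run length {self.run.length}"
            )

    @property
    def length(self) -> int:
        return self.run.length

    @property
    def base(self) -> str:
        return self.run.base


def find_runs(sequence: str, min_length: int = 6) -> list[HomopolymerRun]:
    """Return all maximal homopolymer runs of ``min_length`` or more.

    Runs are reported in 1-based c. coordinates, ordered by start, and are
    maximal by construction (the scan only closes a run when the base
    changes).  Non-ACGT characters raise with the offending 1-based position.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    runs: list[HomopolymerRun] = []
    start = 0
    prev = sequence[0]
    for i, ch in enumerate(sequence):
        if ch not in _BASES:
            raise ValueError(f"non-ACGT character {ch!r} at position {i + 1}")
        if ch != prev:
            if i - start >= min_length:
                runs.append(HomopolymerRun(prev, start + 1, i))
            start = i
            prev = ch
    if len(sequence) - start >= min_length:
        runs.append(HomopolymerRun(prev, start + 1, len(sequence)))
    return runs


def apply_region_policy(
    runs: Sequence[HomopolymerRun],
    gene_symbol: str,
    cds_cutoff: int | None = None,
) -> list[HomopolymerRun]:
    """Drop runs starting downstream of ``cds_cutoff`` (inclusive-keep).

    With ``cds_cutoff=None`` the gene's default from ``POLICY_CDS_CUTOFFS``
    is used (9976 for BRCA2, no cutoff otherwise).  Pass an explicit cutoff
    to override.
    """
    if cds_cutoff is None:
        cds_cutoff = POLICY_CDS_CUTOFFS.get(gene_symbol)
    if cds_cutoff is None:
        return list(runs)
    return [r for r in runs if r.cds_start <= cds_cutoff]


def _cumulative_exon_starts(model: GeneModel) -> list[int]:
    # cds offset (0-based) at which each exon begins, transcript order
    out, acc = [], 0
    for s, e in model.exons:
        out.append(acc)
        acc += e - s + 1
    return out


def cds_position_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Map one 1-based c. position to its 1-based genomic coordinate."""
    if not 1 <= cds_pos <= model.cds_length:
        raise ValueError(f"c.{cds_pos} outside coding sequence")
    offsets = _cumulative_exon_starts(model)
    for (s, e), off in zip(model.exons, offsets):
        within = cds_pos - 1 - off
        if 0 <= within <= e - s:
            if model.strand == "+":
                return s + within
            return e - within
    raise AssertionError("unreachable: exon spans validated against cds length")


def genomic_to_cds(model: GeneModel, genomic_pos: int) -> int:
    """Inverse of :func:`cds_position_to_genomic` for in-exon positions."""
    offsets = _cumulative_exon_starts(model)
    for (s, e), off in zip(model.exons, offsets):
        if s <= genomic_pos <= e:
            within = genomic_pos - s if model.strand == "+" else e - genomic_pos
            return off + within + 1
    raise ValueError(f"genomic position {genomic_pos} not in any exon")


def cds_to_genomic(run: HomopolymerRun, model: GeneModel) -> HomopolymerRegion:
    """Lift a coding-coordinate run to genomic coordinates.

    The run must lie within a single exon (true for every catalogued BRCA1/2
    run); a run spanning a junction raises.  For minus-strand genes the
    genomic interval is the reflection of the coding one, so
    ``genomic_start <= genomic_end`` always holds.
    """
    offsets = _cumulative_exon_starts(model)
    for (s, e), off in zip(model.exons, offsets):
        lo, hi = off + 1, off + (e - s + 1)
        if lo <= run.cds_start <= hi:
            if run.cds_end > hi:
                raise ValueError(
                    f"run c.{run.cds_start}_{run.cds_end} spans an exon "
                    "junction; not supported"
                )
            g1 = cds_position_to_genomic(model, run.cds_start)
            g2 = cds_position_to_genomic(model, run.cds_end)
            gs, ge = min(g1, g2), max(g1, g2)
            return HomopolymerRegion(
                region_id=f"{model.gene_symbol}_c.{run.cds_start}_{run.cds_end}",
                gene_symbol=model.gene_symbol,
                transcript_id=model.transcript_id,
                chromosome=model.chromosome,
                genomic_start=gs,
                genomic_end=ge,
                run=run,
                strand=model.strand,
            )
    raise ValueError(f"run c.{run.cds_start}_{run.cds_end} outside coding sequence")


def discover_regions(
    model: GeneModel,
    min_length: int = 6,
    cds_cutoff: int | None = None,
) -> list[HomopolymerRegion]:
    """Full discovery for one gene: scan, policy filter, genomic lift."""
    runs = find_runs(model.cds_sequence, min_length)
    runs = apply_region_policy(runs, model.gene_symbol, cds_cutoff)
    return [cds_to_genomic(r, model) for r in runs]


_TSV_COLUMNS = [
    "gene",
    "transcript",
    "chromosome",
    "genomic_start",
    "genomic_end",
    "cds_start",
    "cds_end",
    "length",
    "base",
]


def load_region_table(
    path: str | Path,
    strand_by_gene: Mapping[str, str] | None = None,
) -> list[HomopolymerRegion]:
    """Read a region catalogue TSV, validating every row.

    A row whose stated length disagrees with either its coding or its genomic
    interval raises a ``ValueError`` naming the row — inconsistencies are
    flagged, never silently corrected.
    """
    strands = dict(DEFAULT_STRANDS)
    if strand_by_gene:
        strands.update(strand_by_gene)
    regions: list[HomopolymerRegion] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        reader = csv.DictReader(rows, delimiter="\t")
        for i, row in enumerate(reader, start=1):
            try:
                run = HomopolymerRun(
                    row["base"], int(row["cds_start"]), int(row["cds_end"])
                )
                if run.length != int(row["length"]):
                    raise ValueError(
                        f"stated length {row['length']} != coding interval "
                        f"length {run.length}"
                    )
                region = HomopolymerRegion(
                    region_id=f"{row['gene']}_c.{run.cds_start}_{run.cds_end}",
                    gene_symbol=row["gene"],
                    transcript_id=row["transcript"],
                    chromosome=row["chromosome"],
                    genomic_start=int(row["genomic_start"]),
                    genomic_end=int(row["genomic_end"]),
                    run=run,
                    strand=strands.get(row["gene"], "+"),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
            if region.region_id in seen:
                raise ValueError(f"{path}: duplicate region {region.region_id}")
            seen.add(region.region_id)
            regions.append(region)
    return regions


def write_region_table(
    regions: Iterable[HomopolymerRegion], path: str | Path
) -> None:
    """Write the catalogue TSV (1-based inclusive coordinates)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for r in regions:
            writer.writerow(
                [
                    r.gene_symbol,
                    r.transcript_id,
                    r.chromosome,
                    r.genomic_start,
                    r.genomic_end,
                    r.run.cds_start,
                    r.run.cds_end,
                    r.length,
                    r.base,
                ]
            )


def write_bed(regions: Iterable[HomopolymerRegion], path: str | Path) -> None:
    """BED6 export: 0-based half-open, name=region_id, score=run length."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chromosome}\t{r.genomic_start - 1}\t{r.genomic_end}\t"
                f"{r.region_id}\t{r.length}\t{r.strand}\n"
            )


def packaged_catalogue() -> list[HomopolymerRegion]:
    """The BRCA1/2 GRCh37 homopolymer catalogue shipped with the package."""
    ref = resources.files("hpaudit.data").joinpath(_PACKAGED_TABLE)
    with resources.as_file(ref) as p:
        return load_region_table(p)
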