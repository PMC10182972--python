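"""Synthetic cohorts with the statistical structure the audit assumes.

Two levels of synthesis are provided so every pipeline stage is testable
without any external data:

* :func:`simulate_vaf_cohort` draws a cohort-level VAF matrix directly —
  per-sample region depths (log-normal around a per-sample median drawn
  uniformly from the 1045–6989X range typical of deep amplicon panels),
  skewed Beta background indel VAFs whose mean grows with homopolymer
  length (ion-semiconductor error worsens with run length), and rare
  germline carriers at tumour VAF ≈ 0.5, possibly LOH-elevated to 0.70–0.90.
  Observed VAFs are binomial draws at the realized depth.
* :func:`simulate_reads` / :func:`write_fixture_bundle` build small
  reference FASTA + BAM fixtures with explicit CIGAR indel events,
  left-aligned at the homopolymer, carrying a truth ledger in the read
  names — the read-level oracle for the pileup engine.

Background model: per (region, kind), VAF ~ Beta with mean
``m(L) = min(m0 * (L - 4), m_max)`` (defaults m0 = 0.015, m_max = 0.12;
insertion means scaled by 0.6) and concentration ``(1 - phi) / phi`` where
``phi`` is the dispersion (variance = phi * m * (1 - m)).  Two presets:
``clean`` (phi ≈ 0.0033, light tails — background never approaches the
0.15 VAF filter, so a null cohort yields essentially no validated calls)
and ``heavy`` (phi = 0.25, heavy tails that do produce false nominations,
the regime in which orthogonal confirmation of nominated outliers is
indispensable).  Controls are carrier-free by construction: the control
population is defined by an already-identified extra-homopolymer variant,
and a second hit at these regions is vanishingly unlikely.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import KINDS, VafMatrix
from .regions import (
    GeneModel,
    HomopolymerRegion,
    HomopolymerRun,
    packaged_catalogue,
    write_region_table,
)

__all__ = [
    "BackgroundModel",
    "DepthModel",
    "CarrierModel",
    "SimulationConfig",
    "preset",
    "simulate_vaf_cohort",
    "toy_reference",
    "simulate_reads",
    "write_fixture_bundle",
    "BundleConfig",
    "synthetic_coding_models",
    "benchmark_cohort",
    "BenchmarkCohort",
    "CLEAN_DISPERSION",
    "HEAVY_DISPERSION",
]

#: Light-tailed background (concentration 300): chosen so that the largest
#: background mean (0.06, 8-mer deletions) has P(VAF > 0.15) ~ 4e-7 and a
#: null cohort is expected to yield (far) fewer than 0.1 validated calls.
CLEAN_DISPERSION = 1.0 / 301.0

#: Heavy-tailed background (concentration 3): P(VAF > 0.15) up to ~0.13 per
#: draw, producing false nominations that only orthogonal confirmation
#: removes.
HEAVY_DISPERSION = 0.25


@dataclass(frozen=True)
class BackgroundModel:
    """Length-dependent Beta background for homopolymer indel VAFs."""

    m0: float = 0.015  # per-extra-base increment of the mean, deletions
    m_max: float = 0.12  # cap on the background mean
    ins_scale: float = 0.6  # insertion means relative to deletion means
    dispersion: float = CLEAN_DISPERSION  # variance = dispersion * m * (1-m)

    def mean(self, length: int, kind: str) -> float:
        m = min(self.m0 * (length - 4), self.m_max)
        if kind == "ins":
            m *= self.ins_scale
        return m

    def beta_params(self, length: int, kind: str) -> tuple[float, float]:
        m = self.mean(length, kind)
        conc = (1.0 - self.dispersion) / self.dispersion
        return m * conc, (1.0 - m) * conc


@dataclass(frozen=True)
class DepthModel:
    """Log-normal region depths around a per-sample median."""

    median_low: float = 1045.0
    median_high: float = 6989.0
    sigma: float = 0.35  # log-scale spread across regions within a sample
    dropout_rate: float = 0.01  # chance a region falls below 100X


@dataclass(frozen=True)
class CarrierModel:
    """Tumour VAF of a germline heterozygous indel, with possible LOH."""

    vaf_mean: float = 0.5
    vaf_sd: float = 0.05
    p_loh: float = 0.3
    loh_low: float = 0.70
    loh_high: float = 0.90


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative model (defaults emulate the audited cohort)."""

    n_control: int = 46
    n_study: int = 157
    n_carriers: int = 1
    background: BackgroundModel = field(default_factory=BackgroundModel)
    depth: DepthModel = field(default_factory=DepthModel)
    carrier: CarrierModel = field(default_factory=CarrierModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carriers > self.n_study:
            raise ValueError(
                f"n_carriers ({self.n_carriers}) cannot exceed n_study "
                f"({self.n_study})"
            )
        if not 0 <= self.depth.dropout_rate <= 1:
            raise ValueError("dropout_rate must be a probability")


def preset(name: str, **overrides) -> SimulationConfig:
    """Named configurations: ``clean`` (defaults) or ``heavy`` tails."""
    if name == "clean":
        cfg = SimulationConfig(**overrides)
    elif name == "heavy":
        bg = overrides.pop(
            "background", BackgroundModel(dispersion=HEAVY_DISPERSION)
        )
        cfg = SimulationConfig(background=bg, **overrides)
    else:
        raise ValueError(f"unknown preset {name!r} (use 'clean' or 'heavy')")
    return cfg


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_vaf_cohort(
    config: SimulationConfig,
    regions: Sequence[HomopolymerRegion] | None = None,
) -> tuple[VafMatrix, pd.DataFrame]:
    """Draw a cohort VAF matrix plus its truth table.

    Deterministic given ``config.seed``; per-sample RNG substreams are
    spawned by counter from a single seed sequence, so a cohort is
    reproducible independently of sample processing order.  Returns the
    matrix (with cohort labels) and a truth DataFrame with one row per
    carrier assignment (sample, region, kind, true/observed VAF, depth,
    LOH flag).  Carriers are study samples only.
    """
    if regions is None:
        regions = packaged_catalogue()
    regions = list(regions)
    n_regions = len(regions)
    lengths = np.array([r.length for r in regions])

    samples = [f"ctrl_{i:03d}" for i in range(config.n_control)] + [
        f"study_{i:03d}" for i in range(config.n_study)
    ]
    labels = {
        s: ("control" if s.startswith("ctrl_") else "study") for s in samples
    }

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(samples) + 1)
    cohort_rng = np.random.default_rng(streams[0])

    # carrier assignments (study cohort only)
    study_ids = samples[config.n_control :]
    carrier_rows: list[dict] = []
    carrier_cells: dict[tuple[str, str, str], float] = {}
    if config.n_carriers:
        chosen = cohort_rng.choice(
            len(study_ids), size=config.n_carriers, replace=False
        )
        for idx in np.sort(chosen):
            sample = study_ids[int(idx)]
            region = regions[int(cohort_rng.integers(n_regions))]
            kind = str(cohort_rng.choice(KINDS))
            loh = bool(cohort_rng.random() < config.carrier.p_loh)
            if loh:
                mean = float(
                    cohort_rng.uniform(config.carrier.loh_low, config.carrier.loh_high)
                )
            else:
                mean = config.carrier.vaf_mean
            true_vaf = _truncnorm01(cohort_rng, mean, config.carrier.vaf_sd)
            carrier_cells[(sample, region.region_id, kind)] = true_vaf
            carrier_rows.append(
                {
                    "sample_id": sample,
                    "region_id": region.region_id,
                    "kind": kind,
                    "true_vaf": true_vaf,
                    "loh": loh,
                }
            )

    bg = config.background
    a = {k: np.array([bg.beta_params(L, k)[0] for L in lengths]) for k in KINDS}
    b = {k: np.array([bg.beta_params(L, k)[1] for L in lengths]) for k in KINDS}
    region_ids = [r.region_id for r in regions]
    region_index = {rid: i for i, rid in enumerate(region_ids)}

    depth_col = np.empty(len(samples) * n_regions, dtype=np.int64)
    vaf_cols = {k: np.empty(len(samples) * n_regions) for k in KINDS}
    for s_idx, sample in enumerate(samples):
        rng = np.random.default_rng(streams[s_idx + 1])
        median_depth = rng.uniform(config.depth.median_low, config.depth.median_high)
        depths = np.rint(
            median_depth * rng.lognormal(0.0, config.depth.sigma, n_regions)
        ).astype(np.int64)
        drop = rng.random(n_regions) < config.depth.dropout_rate
        depths[drop] = rng.integers(0, 100, size=int(drop.sum()))
        sl = slice(s_idx * n_regions, (s_idx + 1) * n_regions)
        depth_col[sl] = depths
        for kind in KINDS:
            p = rng.beta(a[kind], b[kind])
            for (cs, rid, ck), tv in carrier_cells.items():
                if cs == sample and ck == kind:
                    p[region_index[rid]] = tv
            counts = rng.binomial(np.maximum(depths, 0), p)
            with np.errstate(invalid="ignore", divide="ignore"):
                vaf = np.where(depths > 0, counts / np.maximum(depths, 1), np.nan)
            vaf_cols[kind][sl] = vaf

    matrix = VafMatrix(
        pd.DataFrame(
            {
                "sample_id": np.repeat(samples, n_regions),
                "region_id": np.tile(region_ids, len(samples)),
                "depth": depth_col,
                "vaf_ins": vaf_cols["ins"],
                "vaf_del": vaf_cols["del"],
            }
        ),
        labels,
    )
    truth = pd.DataFrame(
        carrier_rows,
        columns=["sample_id", "region_id", "kind", "true_vaf", "loh"],
    )
    if len(truth):
        depth_map = matrix.records.set_index(["sample_id", "region_id"])["depth"]
        truth["depth"] = [
            int(depth_map.loc[(s, r)])
            for s, r in zip(truth["sample_id"], truth["region_id"])
        ]
        obs = {
            k: matrix.records.set_index(["sample_id", "region_id"])[f"vaf_{k}"]
            for k in KINDS
        }
        truth["observed_vaf"] = [
            float(obs[k].loc[(s, r)])
            for s, r, k in zip(truth["sample_id"], truth["region_id"], truth["kind"])
        ]
    else:
        truth["depth"] = pd.Series(dtype=int)
        truth["observed_vaf"] = pd.Series(dtype=float)
    return matrix, truth


# ---------------------------------------------------------------------------
# read-level fixtures
# ---------------------------------------------------------------------------

_CYCLE = "ACGT"


def _filler(n: int, offset: int = 0) -> str:
    return "".join(_CYCLE[(offset + i) % 4] for i in range(n))


def toy_reference(
    region: HomopolymerRegion, flank: int = 200
) -> tuple[str, HomopolymerRegion]:
    """A small contig holding one homopolymer run with clean flanks.

    Returns the contig sequence and a re-coordinated copy of ``region``
    whose chromosome is the region_id and whose run sits at
    [flank+1, flank+L] (1-based).  Flanks are a 4-base cycle with the two
    boundary bases forced to differ from the run base, so the run stays
    maximal and no other run of >= 2 identical bases borders it.
    """
    L = region.length
    base = region.base
    left = list(_filler(flank))
    right = list(_filler(flank, offset=flank + L))
    other = "C" if base != "C" else "G"
    if left and left[-1] == base:
        left[-1] = other
    if right and right[0] == base:
        right[0] = other
    seq = "".join(left) + base * L + "".join(right)
    toy = HomopolymerRegion(
        region_id=region.region_id,
        gene_symbol=region.gene_symbol,
        transcript_id=region.transcript_id,
        chromosome=region.region_id,
        genomic_start=flank + 1,
        genomic_end=flank + L,
        run=region.run,
        strand="+",
    )
    return seq, toy


def simulate_reads(
    region: HomopolymerRegion,
    ref_seq: str,
    n_reads: int,
    rng: np.random.Generator,
    ins_fraction: float = 0.0,
    del_fraction: float = 0.0,
    carrier_kind: str | None = None,
    carrier_vaf: float = 0.0,
    read_length: int = 150,
    header=None,
):
    """Reads spanning one toy region with explicit left-aligned CIGAR indels.

    Each read is independently assigned a category — carrier indel (with
    probability ``carrier_vaf`` when ``carrier_kind`` is set), background
    insertion/deletion, or reference — recorded in its name
    (``r00042_bg_del`` etc.) as a truth ledger.  Indels are 1 bp, placed in
    left-aligned form (insertion opening after the 5' flank base, deletion
    at the first run base).  Returns (header, reads, truth_counts).
    """
    import pysam

    L = region.length
    run_start0 = region.genomic_start - 1  # 0-based first run base
    run_end0 = region.genomic_end - 1
    lo = max(0, run_end0 + 4 - read_length)
    hi = run_start0 - 3
    if hi < lo or read_length > len(ref_seq):
        raise ValueError(
            f"read_length {read_length} too short to span region "
            f"{region.region_id} (length {L}) with flanks"
        )
    probs = {"ref": 1.0}
    if carrier_kind is not None and carrier_vaf > 0:
        probs[f"carrier_{carrier_kind}"] = carrier_vaf
    probs["bg_ins"] = ins_fraction
    probs["bg_del"] = del_fraction
    probs["ref"] = 1.0 - sum(v for k, v in probs.items() if k != "ref")
    if probs["ref"] < 0:
        raise ValueError("event fractions sum to more than 1")
    cats = list(probs)
    p = np.array([probs[c] for c in cats])

    if header is None:
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": region.chromosome, "LN": len(ref_seq)}],
            }
        )
    tid = header.get_tid(region.chromosome)
    draws = rng.choice(len(cats), size=n_reads, p=p)
    starts = rng.integers(lo, hi + 1, size=n_reads)
    reads = []
    truth_counts = {c: 0 for c in cats}
    for i in range(n_reads):
        cat = cats[int(draws[i])]
        truth_counts[cat] += 1
        start0 = int(starts[i])
        a = run_start0 - start0  # aligned bases before the first run base
        if cat.endswith("del"):
            seq = ref_seq[start0 : start0 + a] + ref_seq[
                start0 + a + 1 : start0 + read_length + 1
            ]
            cigar = [(0, a), (2, 1), (0, read_length - a)]
        elif cat.endswith("ins"):
            seq = (
                ref_seq[start0 : start0 + a]
                + region.base
                + ref_seq[start0 + a : start0 + read_length - 1]
            )
            cigar = [(0, a), (1, 1), (0, read_length - a - 1)]
        else:
            seq = ref_seq[start0 : start0 + read_length]
            cigar = [(0, read_length)]
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"r{i:05d}_{cat}"
        seg.query_sequence = seq
        seg.flag = 0
        seg.reference_id = tid
        seg.reference_start = start0
        seg.mapping_quality = 60
        seg.cigartuples = cigar
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        reads.append(seg)
    reads.sort(key=lambda r: r.reference_start)
    return header, reads, truth_counts


@dataclass(frozen=True)
class BundleConfig:
    """Configuration of a small on-disk FASTA+BAM fixture bundle."""

    n_control: int = 2
    n_study: int = 3
    reads_per_region: int = 200
    read_length: int = 150
    flank: int = 200
    carrier_region_id: str = "BRCA2_c.4279_4284"
    carrier_kind: str = "del"
    carrier_vaf: float = 0.5
    dropout_region_id: str | None = "BRCA1_c.324_329"
    dropout_reads: int = 60  # planted sub-100X region in the last study sample
    background: BackgroundModel = field(default_factory=BackgroundModel)
    seed: int = 0


def write_fixture_bundle(
    outdir: str | Path,
    config: BundleConfig = BundleConfig(),
    regions: Sequence[HomopolymerRegion] | None = None,
) -> dict:
    """Emit reference FASTA (+index), sorted indexed BAMs and truth tables.

    The first study sample carries the configured germline indel; the last
    study sample has one region planted below 100X.  Rerunning with the
    same seed reproduces identical truth tables.  Returns a manifest dict
    with all paths, loadable by :func:`hpaudit.vaf_extraction.extract_cohort`.
    """
    import pysam
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if regions is None:
        regions = packaged_catalogue()
    regions = list(regions)

    toys: list[HomopolymerRegion] = []
    contigs: dict[str, str] = {}
    for region in regions:
        seq, toy = toy_reference(region, flank=config.flank)
        contigs[toy.chromosome] = seq
        toys.append(toy)

    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    regions_path = outdir / "regions.tsv"
    write_region_table(toys, regions_path)

    samples = [f"ctrl_{i:03d}" for i in range(config.n_control)] + [
        f"study_{i:03d}" for i in range(config.n_study)
    ]
    labels = {
        s: ("control" if s.startswith("ctrl_") else "study") for s in samples
    }
    carrier_sample = f"study_{0:03d}" if config.n_study else None
    dropout_sample = f"study_{config.n_study - 1:03d}" if config.n_study else None

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(samples))
    bam_paths: dict[str, Path] = {}
    truth_rows = []
    header_dict = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": t.chromosome, "LN": len(contigs[t.chromosome])} for t in toys],
    }
    for s_idx, sample in enumerate(samples):
        rng = np.random.default_rng(streams[s_idx])
        header = pysam.AlignmentHeader.from_dict(header_dict)
        unsorted = outdir / f"{sample}.unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for toy in toys:
                n_reads = config.reads_per_region
                if (
                    sample == dropout_sample
                    and toy.region_id == config.dropout_region_id
                ):
                    n_reads = config.dropout_reads
                a_ins, b_ins = config.background.beta_params(toy.length, "ins")
                a_del, b_del = config.background.beta_params(toy.length, "del")
                ins_frac = float(rng.beta(a_ins, b_ins))
                del_frac = float(rng.beta(a_del, b_del))
                carrier_kind, carrier_vaf = None, 0.0
                if (
                    sample == carrier_sample
                    and toy.region_id == config.carrier_region_id
                ):
                    carrier_kind = config.carrier_kind
                    carrier_vaf = config.carrier_vaf
                _, reads, counts = simulate_reads(
                    toy,
                    contigs[toy.chromosome],
                    n_reads,
                    rng,
                    ins_fraction=ins_frac,
                    del_fraction=del_frac,
                    carrier_kind=carrier_kind,
                    carrier_vaf=carrier_vaf,
                    read_length=config.read_length,
                    header=header,
                )
                for seg in reads:
                    bam.write(seg)
                truth_rows.append(
                    {
                        "sample_id": sample,
                        "region_id": toy.region_id,
                        "n_reads": n_reads,
                        "bg_ins_reads": counts.get("bg_ins", 0),
                        "bg_del_reads": counts.get("bg_del", 0),
                        "carrier_reads": counts.get(
                            f"carrier_{config.carrier_kind}", 0
                        ),
                    }
                )
        sorted_path = outdir / f"{sample}.bam"
        pysam.sort("-o", str(sorted_path), str(unsorted))
        unsorted.unlink()
        pysam.index(str(sorted_path))
        bam_paths[sample] = sorted_path

    labels_path = outdir / "labels.tsv"
    pd.Series(labels, name="cohort").rename_axis("sample_id").reset_index().to_csv(
        labels_path, sep="\t", index=False
    )
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    config_path = outdir / "config.yaml"
    cfg = asdict(config)
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))

    return {
        "reference": fasta_path,
        "regions": regions_path,
        "labels": labels_path,
        "truth": truth_path,
        "config": config_path,
        "bams": bam_paths,
        "carrier_sample": carrier_sample,
        "dropout_sample": dropout_sample,
    }


# ---------------------------------------------------------------------------
# synthetic coding-sequence models realizing the packaged catalogue
# ---------------------------------------------------------------------------

_CDS_LENGTHS = {"BRCA1": 5592, "BRCA2": 10257}
_TOY_EXONS = {
    # ordered 5'->3' in transcript orientation; BRCA1 is minus-strand
    "BRCA1": ("-", "17", ((507001, 509000), (504001, 506000), (500001, 501592))),
    "BRCA2": ("+", "13", ((100001, 103000), (105001, 109000), (110001, 113257))),
}
#: Decoy BRCA2 run downstream of the c.9976 policy cutoff (dropped by policy).
_DECOY_RUN = HomopolymerRun("A", 10100, 10106)


def synthetic_coding_models(include_decoy: bool = True) -> dict[str, GeneModel]:
    """Gene models whose CDS realize the packaged run catalogue.

    SYNTHETIC: filler sequence is a 4-base cycle (no spurious runs) with the
    catalogued homopolymers planted at their true c. positions and boundary
    bases forced to keep each run maximal; exon structures are toy.  BRCA2
    additionally carries a decoy run downstream of c.9976 so the inclusion
    policy has something to remove.  Intended for discovery demos and
    tests, not as transcript sequence.
    """
    catalogue = packaged_catalogue()
    models: dict[str, GeneModel] = {}
    for gene, (strand, chrom, exons) in _TOY_EXONS.items():
        n = _CDS_LENGTHS[gene]
        seq = list(_filler(n))
        runs = [r.run for r in catalogue if r.gene_symbol == gene]
        if gene == "BRCA2" and include_decoy:
            runs = runs + [_DECOY_RUN]
        for run in runs:
            seq[run.cds_start - 1 : run.cds_end] = run.base * run.length
        for run in runs:
            other = "C" if run.base != "C" else "G"
            if run.cds_start >= 2 and seq[run.cds_start - 2] == run.base:
                seq[run.cds_start - 2] = other
            if run.cds_end < n and seq[run.cds_end] == run.base:
                seq[run.cds_end] = other
        transcript = {"BRCA1": "SYNTH_BRCA1", "BRCA2": "SYNTH_BRCA2"}[gene]
        models[gene] = GeneModel(
            gene_symbol=gene,
            transcript_id=transcript,
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_sequence="".join(seq),
        )
    return models


# ---------------------------------------------------------------------------
# benchmark cohort: printed summary values injected over a clean background
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkCohort:
    """A cohort shaped like the audited one, for end-to-end checks.

    46 controls and 157 tumour-PV-negative study samples over the clean
    synthetic background; five candidate indels injected into four study
    samples (two deletions 41.43%/22.42%, three duplications 18.93%,
    50.22%, 35.37%), of which only the 50.22% duplication is
    germline-confirmed; two further study samples planted with 9 and 16
    regions below 100X (hence excluded from the prevalence denominator);
    and a separate 19-sample upfront-tested set containing two known
    germline homopolymeric variants at 75.80% and 85.87% to be projected
    through the fitted thresholds.  Only the injected VAFs and cohort
    sizes are fixed inputs; the background is synthetic.
    """

    matrix: VafMatrix
    upfront: VafMatrix
    injected: pd.DataFrame
    confirmations: dict[str, str]
    depth_failed_samples: tuple[str, str]


_STUDY_INJECTIONS = [
    # (sample, region_id, kind, vaf)
    ("study_000", "BRCA1_c.1954_1961", "del", 0.4143),
    ("study_000", "BRCA2_c.8934_8940", "del", 0.2242),
    ("study_001", "BRCA2_c.3854_3860", "ins", 0.1893),
    ("study_002", "BRCA2_c.4279_4284", "ins", 0.5022),
    ("study_003", "BRCA2_c.8016_8021", "ins", 0.3537),
]
_UPFRONT_INJECTIONS = [
    ("upfront_000", "BRCA1_c.1010_1016", "ins", 0.7580),
    ("upfront_001", "BRCA2_c.1806_1813", "del", 0.8587),
]


def _inject(matrix: VafMatrix, sample: str, region: str, kind: str, vaf: float) -> None:
    rec = matrix.records
    mask = (rec["sample_id"] == sample) & (rec["region_id"] == region)
    if not mask.any():
        raise KeyError(f"no record for ({sample}, {region})")
    depth = int(rec.loc[mask, "depth"].iloc[0])
    count = int(round(vaf * depth))
    rec.loc[mask, f"vaf_{kind}"] = count / depth


def benchmark_cohort(seed: int = 0) -> BenchmarkCohort:
    """Build the benchmark cohort (see :class:`BenchmarkCohort`)."""
    cfg = SimulationConfig(
        n_control=46,
        n_study=157,
        n_carriers=0,
        depth=DepthModel(dropout_rate=0.0),
        seed=seed,
    )
    matrix, _ = simulate_vaf_cohort(cfg)
    for sample, region, kind, vaf in _STUDY_INJECTIONS:
        _inject(matrix, sample, region, kind, vaf)

    # two study samples with planted depth failures (9 and 16 regions < 100X)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xD0)))
    failed = ("study_155", "study_156")
    for sample, n_fail in zip(failed, (9, 16)):
        region_ids = rng.choice(matrix.regions, size=n_fail, replace=False)
        mask = matrix.records["sample_id"].eq(sample) & matrix.records[
            "region_id"
        ].isin(region_ids)
        matrix.records.loc[mask, "depth"] = rng.integers(
            40, 100, size=int(mask.sum())
        )

    up_cfg = replace(cfg, n_control=0, n_study=19, seed=seed + 1)
    upfront, _ = simulate_vaf_cohort(up_cfg)
    upfront.records["sample_id"] = upfront.records["sample_id"].str.replace(
        "study_", "upfront_", regex=False
    )
    upfront = VafMatrix(
        upfront.records,
        {f"upfront_{i:03d}": "study" for i in range(19)},
    )
    for sample, region, kind, vaf in _UPFRONT_INJECTIONS:
        _inject(upfront, sample, region, kind, vaf)

    injected = pd.DataFrame(
        _STUDY_INJECTIONS + _UPFRONT_INJECTIONS,
        columns=["sample_id", "region_id", "kind", "vaf"],
    )
    confirmations = {
        "study_000": "refuted",
        "study_001": "refuted",
        "study_002": "confirmed",
        "study_003": "refuted",
        "upfront_000": "confirmed",
        "upfront_001": "confirmed",
    }
    return BenchmarkCohort(
        matrix=matrix,
        upfront=upfront,
        injected=injected,
        confirmations=confirmations,
        depth_failed_samples=failed,
    )
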