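"""Prevalence arithmetic, per-region distribution summaries and reporting.

The headline quantity is the prevalence of homopolymeric indels missed by
the variant caller: confirmed carriers among evaluable tumour-PV-negative
samples.  A sample enters the denominator only if it is depth-evaluable at
every catalogued region (see ``sample_evaluability``); the numerator is the
count of study samples with at least one validated outlier confirmed by an
orthogonal assay.  A Wilson 95% interval is attached as an extension — the
procedure itself defines only the point estimate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import VafMatrix
from .regions import HomopolymerRegion

__all__ = [
    "PrevalenceEstimate",
    "pct_round_half_up",
    "estimate_prevalence",
    "confirmation_rate",
    "summarize_distributions",
    "plot_distributions",
    "make_report",
]

CONFIRMATION_STATES = ("confirmed", "refuted", "untested")


def pct_round_half_up(fraction: float, ndigits: int = 1) -> float:
    """Percentage from a fraction, rounded half-up to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(
        Decimal(repr(float(fraction) * 100)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Confirmed-carrier fraction among evaluable study samples."""

    numerator: int
    denominator: int
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")

    @property
    def point(self) -> float:
        return self.numerator / self.denominator

    @property
    def point_pct_1dp(self) -> float:
        return pct_round_half_up(self.point, 1)

    def __str__(self) -> str:
        return f"{self.point_pct_1dp}% ({self.numerator}/{self.denominator})"


def estimate_prevalence(
    validated: pd.DataFrame,
    confirmations: Mapping[str, str] | pd.Series,
    evaluability: pd.Series,
) -> PrevalenceEstimate:
    """Prevalence of confirmed homopolymeric-indel carriers.

    ``validated`` is a validated-calls table (``sample_id`` column);
    ``confirmations`` maps each sample with >= 1 validated call to
    confirmed/refuted/untested; ``evaluability`` is the study cohort's
    map from :func:`hpaudit.outlier_model.sample_evaluability`.
    """
    from statsmodels.stats.proportion import proportion_confint

    conf = pd.Series(dict(confirmations) if not isinstance(confirmations, pd.Series)
                     else confirmations)
    bad = set(conf.unique()) - set(CONFIRMATION_STATES)
    if bad:
        raise ValueError(f"unknown confirmation states: {sorted(bad)}")
    called = set(validated["sample_id"])
    uncovered = called - set(conf.index)
    if uncovered:
        raise ValueError(
            f"confirmation status missing for samples {sorted(uncovered)}"
        )
    denominator = int((evaluability == "evaluable").sum())
    if denominator == 0:
        raise ZeroDivisionError("no evaluable study samples; prevalence undefined")
    numerator = sum(1 for s in called if conf.get(s) == "confirmed")
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    return PrevalenceEstimate(numerator, denominator, (float(lo), float(hi)))


def confirmation_rate(n_confirmed: int, n_tested: int) -> float:
    """Auxiliary germline-confirmation percentage (integer rounding)."""
    if not 0 <= n_confirmed <= n_tested:
        raise ValueError("need 0 <= n_confirmed <= n_tested")
    return pct_round_half_up(n_confirmed / n_tested, 0)


def summarize_distributions(matrix: VafMatrix) -> pd.DataFrame:
    """Boxplot-style summary per region × indel type × cohort.

    Quartiles use linear interpolation; whiskers sit at the Tukey 1.5·IQR
    fences clamped to the observed range; points beyond the fences are
    listed per sample in ``outlier_points``.
    """
    long = matrix.long()
    long = long[long["vaf"].notna()]
    rows = []
    for (region_id, kind, cohort), grp in long.groupby(
        ["region_id", "kind", "cohort"], sort=True
    ):
        v = grp["vaf"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        whisker_lo = float(inside.min()) if inside.size else float(v.min())
        whisker_hi = float(inside.max()) if inside.size else float(v.max())
        outliers = [
            (s, float(x))
            for s, x in zip(grp["sample_id"], v)
            if x < lo_fence or x > hi_fence
        ]
        rows.append(
            {
                "region_id": region_id,
                "kind": kind,
                "cohort": cohort,
                "n": int(v.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_lo": whisker_lo,
                "whisker_hi": whisker_hi,
                "outlier_points": sorted(outliers, key=lambda t: -t[1]),
            }
        )
    return pd.DataFrame(rows)


def plot_distributions(
    matrix: VafMatrix, path: str | Path, regions: Iterable[str] | None = None
) -> None:
    """Side-by-side control/study VAF boxplots per region × indel type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    long = matrix.long()
    long = long[long["vaf"].notna()]
    region_ids = list(regions) if regions is not None else sorted(long["region_id"].unique())
    fig, axes = plt.subplots(
        len(region_ids), 2, figsize=(8, 2.2 * len(region_ids)), squeeze=False
    )
    for i, region_id in enumerate(region_ids):
        for j, kind in enumerate(("ins", "del")):
            ax = axes[i][j]
            sub = long[(long["region_id"] == region_id) & (long["kind"] == kind)]
            data = [
                sub.loc[sub["cohort"] == c, "vaf"].to_numpy() for c in ("control", "study")
            ]
            bp = ax.boxplot(
                data, tick_labels=["control", "study"], patch_artist=True, widths=0.6
            )
            for patch, colour in zip(bp["boxes"], ("#c44e52", "#55a868")):
                patch.set_facecolor(colour)
            ax.set_title(f"{region_id} ({kind})", fontsize=8)
            ax.set_ylabel("VAF", fontsize=7)
            ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _variant_label(region: HomopolymerRegion, kind: str) -> str:
    # display-only HGVS-style label: 3'-most run position, dup for insertions
    suffix = "dup" if kind == "ins" else "del"
    return f"{region.gene_symbol} c.{region.run.cds_end}{suffix}"


def make_report(
    validated: pd.DataFrame,
    regions: Iterable[HomopolymerRegion],
    confirmations: Mapping[str, str] | pd.Series,
    prevalence: PrevalenceEstimate,
    outdir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Emit the outlier table (TSV) and a machine-readable run summary.

    The TSV has one row per validated call with an HGVS-style display label
    assembled from region metadata; the JSON carries counts, the prevalence
    estimate, a config hash and the seed.  Reruns with identical inputs are
    byte-identical except for the timestamp.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conf = dict(confirmations) if not isinstance(confirmations, dict) else confirmations
    by_id = {r.region_id: r for r in regions}

    rows = []
    for _, call in validated.iterrows():
        region = by_id[call["region_id"]]
        rows.append(
            {
                "sample_id": call["sample_id"],
                "region_id": call["region_id"],
                "variant": _variant_label(region, call["kind"]),
                "vaf_pct": pct_round_half_up(call["vaf"], 2),
                "confirmed": conf.get(call["sample_id"], "untested"),
            }
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "region_id", "variant", "vaf_pct", "confirmed"]
    )
    table_path = outdir / "outlier_report.tsv"
    table.to_csv(table_path, sep="\t", index=False)

    config = dict(config or {})
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    summary = {
        "n_validated_calls": int(len(validated)),
        "n_samples_with_calls": int(validated["sample_id"].nunique()),
        "n_confirmed": int(
            sum(conf.get(s) == "confirmed" for s in set(validated["sample_id"]))
        ),
        "prevalence": {
            "numerator": prevalence.numerator,
            "denominator": prevalence.denominator,
            "point": prevalence.point,
            "point_pct_1dp": prevalence.point_pct_1dp,
            "ci95": list(prevalence.ci95),
        },
        "config_hash": config_hash,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    json_path = outdir / "run_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"table": table_path, "summary": json_path}
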