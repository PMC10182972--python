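"""Control-referenced outlier calling for homopolymeric indel VAFs.

Background indel rates at homopolymers are strongly skewed, so ordinary
mean/SD thresholds are useless.  Following the COPA (cancer outlier profile
analysis) convention, each (region, indel-type) cell is robustly
standardized on the *control* cohort — patients already carrying an
extra-homopolymer pathogenic variant, hence with negligible probability of
a second hit at these regions:

    z_i = (x_i - median(x)) / (c * MAD(x)),   c = 1.4826

with MAD the median absolute deviation from the median; the consistency
constant c makes c*MAD estimate the normal standard deviation (the
"median-adjusted deviation").  A study value is an outlier candidate when
its projected z exceeds ``mu + k*sigma`` computed on the normalized control
values (k = 3 by default).  Candidates then pass a filter cascade: absolute
VAF >= 0.15, VAF strictly above the control maximum for that cell, and
anchor depth >= 100.  A call is *validated* only when all four flags hold.

An alternative normalization (``rank-int``: Blom rank-based inverse-normal
transform, average ranks for ties) is provided because robust
standardization and a distributional transform are both defensible readings
of "scaling to a normal distribution"; robust-z is the default and the two
agree on which extreme values are outliers in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import KINDS, VafMatrix

__all__ = [
    "MAD_CONSTANT",
    "FilterConstants",
    "DegenerateScaleError",
    "copa_scale",
    "ThresholdSet",
    "fit_thresholds",
    "call_outliers",
    "validated_calls",
    "sample_evaluability",
]

logger = logging.getLogger(__name__)

MAD_CONSTANT = 1.4826  # consistency with the normal SD

NORMALIZATIONS = ("robust-z", "rank-int")


class DegenerateScaleError(ValueError):
    """Raised when MAD = 0 and the robust scale is undefined."""


@dataclass(frozen=True)
class FilterConstants:
    """Decision constants of the filter cascade."""

    min_vaf: float = 0.15  # keep vaf >= min_vaf (boundary kept)
    min_depth: int = 100  # keep depth >= min_depth
    k_sigma: float = 3.0  # threshold mu + k*sigma on the normalized scale
    mad_constant: float = MAD_CONSTANT

    def __post_init__(self) -> None:
        if not 0 <= self.min_vaf <= 1:
            raise ValueError(f"min_vaf must be in [0, 1], got {self.min_vaf}")
        if self.min_depth < 0 or self.k_sigma <= 0 or self.mad_constant <= 0:
            raise ValueError("filter constants must be positive")


def copa_scale(values, mad_constant: float = MAD_CONSTANT) -> np.ndarray:
    """Robust z-scores: (x - median) / (c * MAD).  NaNs propagate.

    Requires >= 3 non-missing values; raises :class:`DegenerateScaleError`
    when the MAD is zero (constant vector), in which case callers fall back
    to the raw filters for that cell.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 3:
        raise ValueError(f"need >= 3 non-missing values, got {finite.size}")
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    if mad == 0.0:
        raise DegenerateScaleError("MAD is zero; robust scale undefined")
    return (x - med) / (mad_constant * mad)


def _rank_int(x: np.ndarray) -> np.ndarray:
    # Blom offset 3/8, average ranks for ties
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (x.size + 0.25))


def _rank_int_project(controls_sorted: np.ndarray, v: float) -> float:
    """Project ``v`` through the control normal-scores map.

    The control values define a monotone piecewise-linear map x → z (Blom
    scores at the observed values, ties collapsed); values beyond the
    control range extrapolate linearly along the outermost segment, so an
    extreme outlier is not rank-capped at the largest achievable score.
    """
    z = _rank_int(controls_sorted)
    xs = np.unique(controls_sorted)
    zs = np.array([z[controls_sorted == x].mean() for x in xs])
    if xs.size == 1:
        return 0.0
    if v <= xs[0]:
        slope = (zs[1] - zs[0]) / (xs[1] - xs[0])
        return float(zs[0] + slope * (v - xs[0]))
    if v >= xs[-1]:
        slope = (zs[-1] - zs[-2]) / (xs[-1] - xs[-2])
        return float(zs[-1] + slope * (v - xs[-1]))
    return float(np.interp(v, xs, zs))


@dataclass
class ThresholdSet:
    """Per (region, kind) decision boundaries fitted on controls.

    ``cells`` is indexed by (region_id, kind) with columns
    ``n, center, scale, mu, sigma, z_threshold, max_control_vaf, degenerate``
    plus an object column ``control_values`` retained for rank projection
    and audit.  ``center``/``scale`` define the robust-z projection; for a
    degenerate cell (MAD = 0 or < 3 controls) only the raw filters apply.
    """

    cells: pd.DataFrame
    constants: FilterConstants
    normalization: str = "robust-z"

    def z_score(self, region_id: str, kind: str, vaf: float) -> float:
        row = self.cells.loc[(region_id, kind)]
        if row["degenerate"]:
            return float("nan")
        if self.normalization == "rank-int":
            return _rank_int_project(row["control_values"], vaf)
        return (vaf - row["center"]) / row["scale"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.drop(columns=["control_values"]).reset_index()
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def fit_thresholds(
    matrix: VafMatrix,
    constants: FilterConstants = FilterConstants(),
    normalization: str = "robust-z",
) -> ThresholdSet:
    """Fit per-(region, kind) thresholds on the control cohort.

    Uses control-labelled samples of ``matrix`` (or all samples if the
    matrix was already restricted and carries only controls).  Only
    evaluable records (depth >= min_depth, non-missing VAF) enter the fit.
    Cells with < 3 usable controls or zero MAD are marked degenerate and
    logged; an entirely empty control set is a configuration error.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    matrix = matrix.cohort("control")
    long = matrix.long()
    usable = long[(long["depth"] >= constants.min_depth) & long["vaf"].notna()]
    if usable.empty:
        raise ValueError("no evaluable control records; cannot fit thresholds")

    grouped = {
        key: grp["vaf"].to_numpy(dtype=float)
        for key, grp in usable.groupby(["region_id", "kind"], sort=False)
    }
    rows = []
    for region_id in matrix.regions:
        for kind in KINDS:
            x = grouped.get((region_id, kind), np.empty(0))
            rec = {
                "region_id": region_id,
                "kind": kind,
                "n": x.size,
                "control_values": np.sort(x),
                "max_control_vaf": float(x.max()) if x.size else float("nan"),
                "center": float("nan"),
                "scale": float("nan"),
                "mu": float("nan"),
                "sigma": float("nan"),
                "z_threshold": float("nan"),
                "degenerate": True,
            }
            if x.size >= 3:
                med = float(np.median(x))
                mad = float(np.median(np.abs(x - med)))
                if mad > 0:
                    if normalization == "robust-z":
                        z = (x - med) / (constants.mad_constant * mad)
                    else:
                        z = _rank_int(x)
                    zmed = float(np.median(z))
                    zmad = float(np.median(np.abs(z - zmed)))
                    rec.update(
                        center=med,
                        scale=constants.mad_constant * mad,
                        mu=float(np.mean(z)),
                        sigma=constants.mad_constant * zmad,
                        degenerate=False,
                    )
                    rec["z_threshold"] = rec["mu"] + constants.k_sigma * rec["sigma"]
                else:
                    logger.info(
                        "cell (%s, %s): MAD = 0, falling back to raw filters",
                        region_id, kind,
                    )
            else:
                logger.info(
                    "cell (%s, %s): only %d evaluable controls; unfittable",
                    region_id, kind, x.size,
                )
            rows.append(rec)
    cells = pd.DataFrame(rows).set_index(["region_id", "kind"])
    return ThresholdSet(cells=cells, constants=constants, normalization=normalization)


def call_outliers(
    matrix: VafMatrix,
    thresholds: ThresholdSet,
    cohort: str = "study",
) -> pd.DataFrame:
    """Project a cohort through the thresholds and apply the filter cascade.

    Returns the full audit table — one row per (sample, region, kind) with a
    non-missing VAF — with the four flags and ``validated`` (their
    conjunction).  Near-misses are therefore inspectable; use
    :func:`validated_calls` for the final call set.  For degenerate cells
    the z filter is waived (raw filters only); a cell with no control values
    at all cannot pass the max-control filter and is conservatively dropped.
    """
    if (matrix.labels == cohort).any():
        matrix = matrix.cohort(cohort)
    consts = thresholds.constants
    long = matrix.long()
    long = long[long["vaf"].notna()].copy()

    known = set(thresholds.cells.index)
    unknown = {
        (r, k) for r, k in zip(long["region_id"], long["kind"])
    } - known
    if unknown:
        raise ValueError(
            f"thresholds were not fitted for cells {sorted(unknown)[:5]}; "
            "fit on the same region catalogue"
        )

    cells = thresholds.cells.drop(columns=["control_values"]).reset_index()
    long = long.merge(cells, on=["region_id", "kind"], how="left", validate="m:1")
    if thresholds.normalization == "rank-int":
        z = np.array(
            [
                thresholds.z_score(r, k, float(v)) if not d else np.nan
                for r, k, v, d in zip(
                    long["region_id"], long["kind"], long["vaf"], long["degenerate"]
                )
            ]
        )
    else:
        z = (long["vaf"] - long["center"]) / long["scale"]
        z = np.where(long["degenerate"], np.nan, z)
    long["z_score"] = z
    # degenerate cells: the z filter is waived (raw filters only), provided the
    # cell has at least one control value for the raw maximum filter
    long["passed_z"] = np.where(
        long["degenerate"], long["n"] > 0, z > long["z_threshold"].to_numpy()
    )
    long["passed_min_vaf"] = long["vaf"] >= consts.min_vaf
    long["passed_max_control"] = long["vaf"] > long["max_control_vaf"]
    long["passed_max_control"] = long["passed_max_control"].fillna(False)
    long["passed_depth"] = long["depth"] >= consts.min_depth
    long["validated"] = (
        long["passed_z"]
        & long["passed_min_vaf"]
        & long["passed_max_control"]
        & long["passed_depth"]
    )
    long = long.sort_values(
        ["validated", "vaf"], ascending=[False, False]
    ).reset_index(drop=True)
    cols = [
        "sample_id", "region_id", "kind", "vaf", "depth", "z_score",
        "max_control_vaf", "passed_z", "passed_min_vaf",
        "passed_max_control", "passed_depth", "validated",
    ]
    return long[cols]


def validated_calls(audit: pd.DataFrame) -> pd.DataFrame:
    """Validated rows of an audit table, sorted by VAF descending."""
    out = audit[audit["validated"]].sort_values("vaf", ascending=False)
    return out.reset_index(drop=True)


def sample_evaluability(
    matrix: VafMatrix,
    min_depth: int = 100,
    max_failed_regions: int = 0,
) -> pd.Series:
    """Classify samples as 'evaluable' or 'excluded' by region depth.

    A sample is excluded when more than ``max_failed_regions`` of its
    regions fall below ``min_depth`` (default 0: any failing region
    excludes the sample from the prevalence denominator).
    """
    failed = (
        matrix.records.assign(fail=matrix.records["depth"] < min_depth)
        .groupby("sample_id")["fail"]
        .sum()
    )
    out = failed.map(
        lambda k: "excluded" if k > max_failed_regions else "evaluable"
    )
    out.name = "evaluability"
    return out
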