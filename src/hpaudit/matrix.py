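"""Cohort-wide VAF container shared by extraction, modelling and reporting.

A :class:`VafMatrix` is a long-format table with one row per
(sample, region) holding the anchor depth and the insertion/deletion VAFs,
plus a sample→cohort label map (``control`` = carriers of an
extra-homopolymer pathogenic variant, ``study`` = tumour-PV-negative).
Pivoted samples×regions views are derived on demand.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

KINDS = ("ins", "del")
COHORTS = ("control", "study")

_CORE_COLUMNS = ["sample_id", "region_id", "depth", "vaf_ins", "vaf_del"]


class VafMatrix:
    """Samples × regions × {ins, del} VAFs with depths and cohort labels.

    ``records`` must contain the core columns ``sample_id, region_id, depth,
    vaf_ins, vaf_del``; extra columns (read counts, evaluability) are kept.
    VAFs are fractions in [0, 1]; a VAF is missing (NaN) iff the record has
    zero depth or is absent.  ``labels`` maps every sample to ``control`` or
    ``study``.
    """

    def __init__(self, records: pd.DataFrame, labels: Mapping[str, str] | pd.Series):
        missing = [c for c in _CORE_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        records = records.reset_index(drop=True).copy()
        labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
        labels.index.name = "sample_id"
        labels.name = "cohort"
        bad = set(labels.unique()) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        unlabelled = set(records["sample_id"]) - set(labels.index)
        if unlabelled:
            raise ValueError(f"samples without cohort label: {sorted(unlabelled)[:5]}")
        for kind in KINDS:
            v = records[f"vaf_{kind}"]
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"vaf_{kind} outside [0, 1]")
            zero = records["depth"] <= 0
            if v[zero].notna().any():
                raise ValueError("non-missing VAF at zero depth")
        self.records = records
        self.labels = labels

    # -- views ------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample_id"]))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.records["region_id"]))

    def vaf(self, kind: str) -> pd.DataFrame:
        """Samples × regions pivot of one indel type ('ins' or 'del')."""
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        return self.records.pivot(
            index="sample_id", columns="region_id", values=f"vaf_{kind}"
        )

    def depth(self) -> pd.DataFrame:
        return self.records.pivot(
            index="sample_id", columns="region_id", values="depth"
        )

    def cohort(self, name: str) -> "VafMatrix":
        """Restrict to one cohort, keeping labels for the retained samples."""
        keep = set(self.labels[self.labels == name].index)
        rec = self.records[self.records["sample_id"].isin(keep)]
        return VafMatrix(rec, self.labels[self.labels.index.isin(keep)])

    def long(self) -> pd.DataFrame:
        """One row per (sample, region, kind) with a single ``vaf`` column."""
        frames = []
        for kind in KINDS:
            f = self.records[["sample_id", "region_id", "depth", f"vaf_{kind}"]].copy()
            f = f.rename(columns={f"vaf_{kind}": "vaf"})
            f["kind"] = kind
            frames.append(f)
        out = pd.concat(frames, ignore_index=True)
        out["cohort"] = out["sample_id"].map(self.labels)
        return out

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, records_path: str | Path, labels_path: str | Path) -> None:
        self.records.to_csv(records_path, sep="\t", index=False, na_rep="NA")
        self.labels.reset_index().to_csv(labels_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, records_path: str | Path, labels_path: str | Path
    ) -> "VafMatrix":
        rec = pd.read_csv(records_path, sep="\t", na_values=["NA"])
        lab = pd.read_csv(labels_path, sep="\t").set_index("sample_id")["cohort"]
        return cls(rec, lab)

    @classmethod
    def from_sample_records(
        cls, rows: Iterable, labels: Mapping[str, str]
    ) -> "VafMatrix":
        """Build from an iterable of per-(sample, region) summary objects."""
        rec = pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "region_id": r.region_id,
                    "depth": r.total_reads,
                    "vaf_ins": r.vaf_ins,
                    "vaf_del": r.vaf_del,
                    "max_ins_reads": r.max_ins_reads,
                    "max_del_reads": r.max_del_reads,
                    "evaluable": r.evaluable,
                }
                for r in rows
            ]
        )
        return cls(rec, labels)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"VafMatrix({len(self.samples)} samples x {len(self.regions)} "
            f"regions, cohorts={dict(self.labels.value_counts())})"
        )
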