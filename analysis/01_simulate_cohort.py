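#!/usr/bin/env python
"""Simulate the default synthetic cohort and write its VAF matrix.

46 control samples (carriers of an extra-homopolymer pathogenic variant)
and 157 tumour-PV-negative study samples over the 29-region BRCA1/2
homopolymer catalogue, clean background preset, one injected germline
carrier.  Outputs land in results/cohort/.
"""

from pathlib import Path

from hpaudit.synthetic_data import preset, simulate_vaf_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20230513


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = preset("clean", n_carriers=1, seed=SEED)
    matrix, truth = simulate_vaf_cohort(cfg)
    matrix.to_tsv(OUT / "vaf_records.tsv", OUT / "labels.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    print(f"cohort: {len(matrix.samples)} samples x {len(matrix.regions)} regions")
    depths = matrix.records["depth"]
    print(f"depth: median {depths.median():.0f}X, range {depths.min()}-{depths.max()}X")
    for _, row in truth.iterrows():
        print(
            f"injected carrier: {row.sample_id} {row.region_id} {row.kind} "
            f"true VAF {row.true_vaf:.3f} (LOH={row.loh}), "
            f"observed {row.observed_vaf:.3f} at {row.depth}X"
        )
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
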