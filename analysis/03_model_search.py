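"""Pretreatment x selector model search for both acquisition systems.

For each indicator and each system (traditional tube, through-vial) this
runs the full calibration workflow — shared 10% external-validation holdout,
per-indicator SPXY 3:1 division, five-pretreatment scan with leave-one-out
RMSECV, the three wavenumber selectors, final PLSR refit — and writes the
optimal-model table per system plus the side-by-side system comparison.

Usage: python analysis/03_model_search.py [--data results/data] [--seed N]
"""

import argparse
import pickle
from pathlib import Path

from nirqc import (
    AcquisitionMode,
    compare_systems,
    join_by_sample_id,
    load_references,
    load_spectra,
    run_model_search,
)
from nirqc.partitioning import random_holdout
from nirqc.pipeline import SearchGrid


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=2022)
    args = ap.parse_args()

    refs = load_references(args.data / "references.csv")
    grid = SearchGrid()
    reports = {}
    validation_ids = None
    for label, fname, mode in (
        ("traditional", "spectra_traditional.csv", AcquisitionMode.TRADITIONAL),
        ("through_vial", "spectra_through_vial.csv", AcquisitionMode.THROUGH_VIAL),
    ):
        spectra = load_spectra(args.data / fname, mode=mode)
        spectra, joined_refs = join_by_sample_id(spectra, refs)
        if validation_ids is None:
            # one shared holdout so both systems validate on the same batches
            validation_ids = random_holdout(spectra.sample_ids, grid.holdout_fraction,
                                            args.seed)
        report = run_model_search(spectra, joined_refs, grid=grid, seed=args.seed,
                                  validation_ids=validation_ids)
        reports[label] = report
        frame = report.to_frame()
        frame.to_csv(args.out / f"optimal_models_{label}.csv", index=False,
                     float_format="%.4g")
        print(f"\noptimal models — {label} system:")
        print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        if report.failures:
            print("failures:", report.failures)

    cmp = compare_systems(reports["traditional"], reports["through_vial"])
    cmp.to_csv(args.out / "system_comparison.csv", index=False, float_format="%.4g")
    print("\nthrough-vial minus traditional deltas:")
    print(cmp[["indicator", "dRc", "dRp", "dRMSEP", "dRPD"]].to_string(
        index=False, float_format=lambda v: f"{v:+.4f}"))

    with open(args.out / "search_reports.pkl", "wb") as fh:
        pickle.dump(reports, fh)  # consumed by 04_external_validation.py


if __name__ == "__main__":
    main()
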