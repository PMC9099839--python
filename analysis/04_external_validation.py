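"""External validation of the chosen models on the held-out batches.

Loads the search reports written by 03_model_search.py, predicts the
external-validation samples that no modelling stage ever saw, and writes
per-sample reference/predicted tables with Rv, RMSEV, RSEV and the Wilcoxon
rank-sum p per indicator and system.

Usage: python analysis/04_external_validation.py [--data results/data]
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from nirqc import AcquisitionMode, external_validate, join_by_sample_id, load_references, load_spectra


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.out / "search_reports.pkl", "rb") as fh:
        reports = pickle.load(fh)
    refs = load_references(args.data / "references.csv")

    rows = []
    for label, fname, mode in (
        ("traditional", "spectra_traditional.csv", AcquisitionMode.TRADITIONAL),
        ("through_vial", "spectra_through_vial.csv", AcquisitionMode.THROUGH_VIAL),
    ):
        spectra = load_spectra(args.data / fname, mode=mode)
        spectra, joined_refs = join_by_sample_id(spectra, refs)
        for indicator, model in reports[label].models.items():
            out = external_validate(model, spectra, joined_refs)
            out["table"].to_csv(
                args.out / f"validation_{label}_{indicator}.csv", index=False,
                float_format="%.5g",
            )
            rows.append({
                "system": label, "indicator": indicator, "n": out["n"],
                "Rv": out["Rv"], "RMSEV": out["RMSEV"], "RSEV": out["RSEV"],
                "wilcoxon_p": out["wilcoxon_p"], "range_warning": out["range_warning"],
            })
            print(f"{label:12s} {indicator:10s} Rv={out['Rv']:.4f} "
                  f"RMSEV={out['RMSEV']:.4g} RSEV={out['RSEV']:.2f}% "
                  f"p={out['wilcoxon_p']:.3f}")
    pd.DataFrame(rows).to_csv(args.out / "validation_summary.csv", index=False,
                              float_format="%.5g")
    print("a rank-sum p above 0.05 for every cell means no systematic shift"
          " between reference and NIR-predicted values")


if __name__ == "__main__":
    main()
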