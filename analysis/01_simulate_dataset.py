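"""Generate the synthetic 101-batch dataset and write it to results/data/.

Emulates the study conditions: 35 undiluted commercial batches plus 66
water-diluted ones, scanned three ways (traditional 4 mm tube, through the
intact vial, empty vial), with ANTI-NO bioactivity and the three analyte
concentrations as reference values.  Writes the four spectra/reference CSVs,
the ground-truth table, and a JSON run manifest.

Usage: python analysis/01_simulate_dataset.py [--seed N]
"""

import argparse
from pathlib import Path

from nirqc import SyntheticConfig, generate_dataset, write_references, write_spectra
from nirqc.io_core import write_manifest


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2022)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig()
    bundle = generate_dataset(cfg, seed=args.seed)

    write_spectra(bundle.spectra_traditional, out / "spectra_traditional.csv")
    write_spectra(bundle.spectra_through_vial, out / "spectra_through_vial.csv")
    write_spectra(bundle.spectra_empty_vial, out / "spectra_empty_vial.csv")
    write_references(bundle.references, out / "references.csv")
    bundle.truth.to_csv(out / "truth.csv", float_format="%.17g")
    write_manifest(out / "manifest.json", seed=args.seed, config=cfg.__dict__)

    refs = bundle.references.values
    print(f"wrote {refs.shape[0]} samples x {bundle.spectra_traditional.n_vars} wavenumbers to {out}/")
    print("reference value ranges:")
    print(refs.agg(["min", "max", "mean"]).T.to_string(float_format="%.4f"))


if __name__ == "__main__":
    main()
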