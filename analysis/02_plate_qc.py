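"""Plate-level z'-factor QC of a screen plate table.

One row per (plate, batch, arm, readout) with the z'-factor from the siPLK1
and siNC control wells and its EXCELLENT/BORDERLINE/FAIL classification.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

import siscreen as ss


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--plate-table", default="results/plate_table.csv")
    ap.add_argument("--out", default="results/plate_qc.csv")
    ap.add_argument("--z-variant", choices=["STANDARD", "AS_PRINTED"], default="STANDARD")
    args = ap.parse_args()

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    wells = ss.read_plate_table(args.plate_table)
    report = ss.qc_report(wells, variant=args.z_variant)
    df = pd.DataFrame([dataclasses.asdict(r) for r in report])
    df.to_csv(args.out, index=False)
    print(df["quality"].value_counts().to_string())
    print(f"wrote {len(df)} QC rows to {args.out}")


if __name__ == "__main__":
    main()
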