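"""Simulate the study-shaped siRNA screen and write its plate table.

390 genes in triplicate 384-well batches, vehicle and cisplatin arms, with
37 planted common inhibitors and 9 cisplatin-sensitized genes.
"""

import argparse
from pathlib import Path

import siscreen as ss
from siscreen.simulate import study_screen_config


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/plate_table.csv")
    args = ap.parse_args()

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    wells = ss.generate_screen(study_screen_config(seed=args.seed))
    ss.write_plate_table(wells, args.out)
    print(f"wrote {len(wells)} wells to {args.out}")


if __name__ == "__main__":
    main()
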