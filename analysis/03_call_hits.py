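"""Normalize a screen plate table and call anti-proliferative hits.

Per-plate log2 normalization against the siNC median, pooled-variance t-test
per gene and arm, then hit categories (COMMON, CISPLATIN_SENSITIZED,
SINGLE_ONLY, COMBINED_ONLY, NONE) at p < 0.01 and >= twofold inhibition.
"""

import argparse
from pathlib import Path

import siscreen as ss


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--plate-table", default="results/plate_table.csv")
    ap.add_argument("--out-effects", default="results/gene_effects.csv")
    ap.add_argument("--out-hits", default="results/hit_calls.csv")
    args = ap.parse_args()

    Path(args.out_effects).parent.mkdir(parents=True, exist_ok=True)
    norm = ss.normalize_screen(ss.read_plate_table(args.plate_table))
    effects = ss.aggregate_effects(norm)
    calls = ss.call_hits(effects)
    ss.effects_frame(effects).to_csv(args.out_effects, index=False)
    hits = ss.hits_frame(calls)
    hits.to_csv(args.out_hits, index=False)
    print(hits["category"].value_counts().to_string())
    print(f"wrote {args.out_effects} and {args.out_hits}")


if __name__ == "__main__":
    main()
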