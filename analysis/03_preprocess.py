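#!/usr/bin/env python
"""Preprocess each platform's raw matrix: impute (min-positive/5), RSD filter,
quantile normalise, log + autoscale.  Writes scaled matrices and the drop log."""

import argparse
from pathlib import Path

import pandas as pd

from cortidyn.preprocess import preprocess_chain, read_matrix_tsv, write_matrix_tsv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--keep-fraction", type=float, default=0.9)
    args = ap.parse_args()
    out = args.out_dir

    droplogs = []
    for raw_path in sorted(out.glob("raw_*.tsv")):
        platform = raw_path.stem.removeprefix("raw_")
        m = read_matrix_tsv(raw_path, out / f"samples_{platform}.tsv")
        scaled = preprocess_chain(m, keep_fraction=args.keep_fraction)
        write_matrix_tsv(scaled, out / f"scaled_{platform}.tsv")
        droplogs.append(scaled.drop_log)
        print(f"{platform:24s} {m.n_features:4d} -> {scaled.n_features:4d} features "
              f"({len(scaled.drop_log)} dropped)")
    pd.concat(droplogs, ignore_index=True).to_csv(out / "drop_log.tsv", sep="\t", index=False)
    print(f"drop reasons: {pd.concat(droplogs)['reason'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
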