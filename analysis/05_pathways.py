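#!/usr/bin/env python
"""Pathway enrichment (hypergeometric ORA) + topology impact (betweenness) for
each unique-correlation class, serum and urine separately, with BH FDR."""

import argparse
from pathlib import Path

import pandas as pd

from cortidyn.pathway import InsufficientDEMsError, load_default_library, run_pathway_analysis


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    out = args.out_dir

    classified = pd.read_csv(out / "classified_features.tsv", sep="\t")
    library = load_default_library()
    for matrix_kind in sorted(classified["matrix"].dropna().unique()):
        sub = classified[classified["matrix"] == matrix_kind]
        for cls in ("unique_AUC", "unique_AUTO"):
            try:
                res = run_pathway_analysis(sub, library, cls)
            except InsufficientDEMsError as e:
                print(f"{matrix_kind}/{cls}: {e}")
                continue
            res.to_csv(out / f"pathways_{cls}_{matrix_kind}.tsv", sep="\t", index=False)
            sig = res[res["significant"]]
            print(f"{matrix_kind}/{cls}: {len(sig)} significant pathway(s) "
                  f"of {len(res)} tested")
            for _, r in sig.iterrows():
                print(f"   {r['name']:55s} P={r['p_raw']:.2e} q={r['q_fdr']:.2e} "
                      f"impact={r['impact']:.2f}")


if __name__ == "__main__":
    main()
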