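#!/usr/bin/env python
"""Integrate proteome and transcriptome: composition, category-level
stimulation effects, protein-transcript correlation, and the report bundle.

Runs the full pipeline on one study directory and exports composition
fractions at every level (proteome / secretome / ECM / transcriptome of
secreted genes), category-sum paired comparisons per stimulus, the
Spearman protein-transcript correlation, and volcano/heatmap tables.
"""

import argparse
from pathlib import Path

from cfsecretome.pipeline import load_bundle, run_pipeline
from cfsecretome.report import export_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/sim"))
    parser.add_argument("--outdir", type=Path, default=Path("results/report"))
    parser.add_argument("--figures", action="store_true", help="also render pie charts")
    args = parser.parse_args()

    bundle = load_bundle(args.indir)
    res = run_pipeline(bundle)

    for level, rep in res.compositions.items():
        print(f"{level}: {rep.as_percent()} (n={rep.n_features})")
    for contrast, diffs in res.category_protein_diff.items():
        sig = [f"{r.feature} {r.direction} ({r.log2fc:+.2f})" for r in diffs if r.direction != "ns"]
        print(f"protein category sums, {contrast}: {sig or 'no significant categories'}")
    rho, p, n = res.correlation
    print(f"secretome vs transcriptome Spearman rho = {rho:.3f} (p = {p:.2e}, n = {n})")

    files = export_report(res, args.outdir, figures=args.figures)
    print(f"wrote {len(files)} report files to {args.outdir}")


if __name__ == "__main__":
    main()
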