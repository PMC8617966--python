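#!/usr/bin/env python
"""Process the probe-level expression matrix and the qPCR Ct table.

Quantile normalization across all 12 arrays, log2 transformation, the
detection filter (log2 >= 5 in at least 2 of 12 samples), probe collapsing
(highest control mean per gene), paired differential expression per
stimulus, and 2^-dCt ratio-paired tests for the qPCR panel.
"""

import argparse
from pathlib import Path

import pandas as pd

from cfsecretome.pipeline import load_bundle, process_arrays
from cfsecretome.report import diff_table
from cfsecretome.stats import classify_volcano
from cfsecretome.transcriptomics import differential_expression, qpcr_contrast


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/sim"))
    parser.add_argument("--outdir", type=Path, default=Path("results/arrays"))
    parser.add_argument("--threshold", type=float, default=5.0)
    parser.add_argument("--min-detected", type=int, default=2)
    parser.add_argument("--contrasts", nargs="+", default=["TNFA", "TGFB"])
    args = parser.parse_args()

    bundle = load_bundle(args.indir)
    gene_matrix = process_arrays(
        bundle["probe_matrix"], bundle["probe_map"], args.threshold, args.min_detected
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    out = gene_matrix.data.copy()
    out.insert(0, "probe_id", gene_matrix.chosen_probe)
    out.to_csv(args.outdir / "gene_matrix_log2.tsv", sep="\t")
    n_probes = bundle["probe_matrix"].shape[0]
    print(f"{n_probes} probes -> {len(gene_matrix.data)} genes above detection")

    for contrast in args.contrasts:
        results = differential_expression(gene_matrix, contrast)
        _, _, _, counts = classify_volcano(results)
        diff_table(results).to_csv(
            args.outdir / f"volcano_{contrast}.tsv", sep="\t", index=False
        )
        print(f"{contrast}: {counts.total_significant} genes regulated "
              f"({counts.n_up} up, {counts.n_down} down)")

    qpcr = bundle["qpcr_table"]
    rows = []
    for gene in sorted(qpcr["gene"].unique()):
        for contrast in args.contrasts:
            r = qpcr_contrast(qpcr, gene, contrast)
            rows.append(
                {
                    "gene": gene,
                    "contrast": contrast,
                    "geometric_ratio": r.geometric_ratio,
                    "p": r.p,
                }
            )
    pd.DataFrame(rows).to_csv(args.outdir / "qpcr_results.tsv", sep="\t", index=False)
    print(f"qPCR panel: {len(rows)} gene x contrast tests; tables in {args.outdir}")


if __name__ == "__main__":
    main()
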