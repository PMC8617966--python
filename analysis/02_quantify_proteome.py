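#!/usr/bin/env python
"""Quantify the extracellular proteome from the peptide intensity table.

Excludes tryptic peptides shared with the serum species, sums unique
peptides per protein, defines the extracellular proteome (detected in every
patient's control), log10+median normalizes, attaches iBAQ values, and runs
paired differential-secretion tests for each stimulus.
"""

import argparse
from pathlib import Path

from cfsecretome.pipeline import load_bundle, process_proteome
from cfsecretome.proteomics import differential_secretion
from cfsecretome.report import diff_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/sim"))
    parser.add_argument("--outdir", type=Path, default=Path("results/proteome"))
    parser.add_argument("--min-pep-len", type=int, default=6)
    parser.add_argument("--max-pep-len", type=int, default=30)
    parser.add_argument("--contrasts", nargs="+", default=["TNFA", "TGFB"])
    args = parser.parse_args()

    bundle = load_bundle(args.indir)
    matrix, extracellular, shared = process_proteome(
        bundle["peptide_table"],
        bundle["cell_db"],
        bundle["serum_db"],
        args.min_pep_len,
        args.max_pep_len,
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    matrix.raw.to_csv(args.outdir / "protein_raw.tsv", sep="\t")
    matrix.normalized.to_csv(args.outdir / "protein_normalized_log10.tsv", sep="\t")
    matrix.ibaq.to_csv(args.outdir / "protein_ibaq.tsv", sep="\t")
    (args.outdir / "extracellular_proteins.txt").write_text(
        "\n".join(sorted(extracellular)) + "\n"
    )
    print(f"excluded {len(shared)} shared (serum) peptides; "
          f"dropped {matrix.dropped_peptides}")
    print(f"extracellular proteome: {len(extracellular)} proteins "
          f"(detected in controls of all patients)")
    for contrast in args.contrasts:
        results = differential_secretion(matrix, contrast)
        n_sig = sum(r.direction != "ns" for r in results)
        diff_table(results).to_csv(
            args.outdir / f"differential_{contrast}.tsv", sep="\t", index=False
        )
        print(f"{contrast}: {n_sig} of {len(results)} proteins significant (p < 0.05)")
    print(f"tables written to {args.outdir}")


if __name__ == "__main__":
    main()
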