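#!/usr/bin/env python
"""Generate one synthetic secretome/transcriptome study with known truth.

Emulates the paired design: 4 patients x (control, TNF-alpha, TGF-beta),
log-normal peptide intensities with abundance-dependent MS dropout, a
whole-transcriptome probe matrix with 1-5 probes per gene, a qPCR Ct table
against the CDKN1B housekeeping gene, and serum near-homolog proteins that
plant a known shared-peptide set.  Writes FASTA/TSV inputs plus truth.json
to the output directory.
"""

import argparse
from pathlib import Path

from cfsecretome import SimConfig, load_config, simulate_all


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, help="optional YAML overriding defaults")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = parser.parse_args()

    config = load_config(args.config) if args.config else SimConfig()
    bundle = simulate_all(config, args.seed, outdir=args.outdir)
    truth = bundle["truth"]
    n_genes = len(truth.gene_category)
    print(f"simulated {len(bundle['cell_db'])} cell proteins, "
          f"{len(bundle['serum_db'])} serum proteins, {n_genes} genes")
    print(f"planted shared peptides: {len(truth.shared_peptides)}")
    print(f"peptide rows: {len(bundle['peptide_table'])}, "
          f"probes: {bundle['probe_matrix'].shape[0]}")
    print(f"inputs + truth written to {args.outdir}")


if __name__ == "__main__":
    main()
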