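#!/usr/bin/env python
"""Assign localization and functional categories from the annotation table.

Keyword-driven localization (secreted / membrane / ER / other) and
functional tags: collagens, MMPs/TIMPs and fibronectin by gene-symbol
pattern (implying ECM), extracellular matrix and cytokines by keyword.
"""

import argparse
from pathlib import Path

from cfsecretome.annotation import assign_categories, assignments_table
from cfsecretome.records import read_annotation_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotations", type=Path, default=Path("results/sim/annotation.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/assignments.tsv"))
    args = parser.parse_args()

    annotation = read_annotation_table(args.annotations)
    assignments = assign_categories(annotation)
    table = assignments_table(assignments)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    by_loc = table["localization"].value_counts().to_dict()
    print(f"categorized {len(table)} features: {by_loc}")
    print(f"assignments written to {args.out}")


if __name__ == "__main__":
    main()
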