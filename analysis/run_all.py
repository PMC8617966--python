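#!/usr/bin/env python
"""Run the whole analysis chain from one config: simulate, quantify the
proteome, process the arrays, categorize, integrate.

Each stage writes its outputs under --outdir so stages can also be rerun
individually with the numbered scripts.
"""

import argparse
import subprocess
import sys
import time
from pathlib import Path

STAGES = [
    ("01_simulate.py", lambda a: ["--seed", str(a.seed), "--outdir", str(a.outdir / "sim")]
     + (["--config", str(a.config)] if a.config else [])),
    ("02_quantify_proteome.py", lambda a: ["--indir", str(a.outdir / "sim"),
                                           "--outdir", str(a.outdir / "proteome")]),
    ("03_process_arrays.py", lambda a: ["--indir", str(a.outdir / "sim"),
                                        "--outdir", str(a.outdir / "arrays")]),
    ("04_categorize.py", lambda a: ["--annotations", str(a.outdir / "sim/annotation.tsv"),
                                    "--out", str(a.outdir / "assignments.tsv")]),
    ("05_integrate.py", lambda a: ["--indir", str(a.outdir / "sim"),
                                   "--outdir", str(a.outdir / "report")]),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, help="optional simulation YAML")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    here = Path(__file__).parent
    for script, argfn in STAGES:
        t0 = time.time()
        print(f"=== {script} ===", file=sys.stderr)
        subprocess.run(
            [sys.executable, str(here / script), *argfn(args)], check=True
        )
        print(f"=== {script} done in {time.time() - t0:.1f}s ===", file=sys.stderr)


if __name__ == "__main__":
    main()
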