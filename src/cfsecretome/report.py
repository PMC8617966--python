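"""Deterministic report export: composition JSON, differential/volcano and
heatmap TSVs, correlation JSON, optional pie-chart figures.

Identical inputs give byte-identical tables: rows follow documented sort
orders and floats are written with a fixed format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .composition import CompositionReport
from .config import CONTROL
from .pipeline import PipelineResult
from .samples import condition_columns
from .stats import DiffResult

FLOAT_FORMAT = "%.6g"


def diff_table(results: Sequence[DiffResult]) -> pd.DataFrame:
    """Volcano-ready table (feature, log2fc, p, direction), sorted by feature."""
    return pd.DataFrame(
        [
            {"feature": r.feature, "log2fc": r.log2fc, "p": r.p, "direction": r.direction}
            for r in results
        ]
    ).sort_values("feature", ignore_index=True)


def heatmap_table(
    matrix: pd.DataFrame, control_condition: str = CONTROL
) -> pd.DataFrame:
    """Feature x sample table sorted by descending control-sample mean —
    the ranking convention of expression heatmaps (most abundant on top)."""
    control_cols = condition_columns(matrix.columns, control_condition)
    order = matrix[control_cols].mean(axis=1).sort_values(ascending=False, kind="mergesort")
    return matrix.loc[order.index]


def composition_json(reports: dict[str, CompositionReport]) -> str:
    payload = {
        level: {
            "fractions": rep.fractions,
            "percent": rep.as_percent(),
            "denominator": rep.denominator,
            "n_features": rep.n_features,
        }
        for level, rep in sorted(reports.items())
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def export_report(
    result: PipelineResult, outdir: str | Path, figures: bool = False
) -> list[Path]:
    """Write the full report bundle; returns the paths written.

    With ``figures=True`` pie charts of the compositional levels are also
    rendered (requires matplotlib, an optional dependency).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
        written.append(path)

    path = out / "composition.json"
    path.write_text(composition_json(result.compositions))
    written.append(path)

    for contrast, diffs in sorted(result.protein_diff.items()):
        _write_tsv(diff_table(diffs), f"protein_diff_{contrast}.tsv")
    for contrast, diffs in sorted(result.gene_diff.items()):
        _write_tsv(diff_table(diffs), f"gene_volcano_{contrast}.tsv")
    for contrast, diffs in sorted(result.category_protein_diff.items()):
        _write_tsv(diff_table(diffs), f"category_protein_{contrast}.tsv")
    for contrast, diffs in sorted(result.category_gene_diff.items()):
        _write_tsv(diff_table(diffs), f"category_gene_{contrast}.tsv")

    _write_tsv(heatmap_table(result.matrix.normalized), "protein_heatmap.tsv", index=True)
    _write_tsv(heatmap_table(result.gene_matrix.data), "gene_heatmap.tsv", index=True)

    rho, p, n = result.correlation
    path = out / "correlation.json"
    path.write_text(
        json.dumps({"method": "spearman", "rho": rho, "p": p, "n": n}, indent=1)
    )
    written.append(path)

    counts = {
        contrast: {
            "up": vc.n_up,
            "down": vc.n_down,
            "ns": vc.n_ns,
            "total_significant": vc.total_significant,
        }
        for contrast, vc in sorted(result.volcano_counts.items())
    }
    path = out / "volcano_counts.json"
    path.write_text(json.dumps(counts, indent=1, sort_keys=True))
    written.append(path)

    if figures:
        written.extend(_write_figures(result, out))
    return written


def _write_figures(result: PipelineResult, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for level, rep in sorted(result.compositions.items()):
        fig, ax = plt.subplots(figsize=(4, 4))
        labels = list(rep.fractions)
        ax.pie([rep.fractions[k] for k in labels], labels=labels, autopct="%d%%")
        ax.set_title(level)
        path = out / f"composition_{level}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
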