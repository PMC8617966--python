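"""Probe-level expression processing, gene collapsing, paired differential
expression and qPCR delta-Ct quantification.

Processing order for the 12-sample (4 patients x 3 conditions) array data:
quantile normalization of probe intensities across all arrays, log2
transformation, a detection filter (a feature must reach log2 >= 5 in at
least 2 of 12 samples), then collapsing to one representative probe per
gene — the probe with the highest mean expression in the control samples.
Differential expression is a paired t-test on log2 values per gene; qPCR
expression is quantified relative to a housekeeping gene as 2^-dCt and
tested with the ratio paired t-test (a paired t-test on log2 expression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CONTROL
from .samples import condition_columns
from .stats import DiffResult, paired_t_table, ratio_paired_t_test

DETECTION_THRESHOLD = 5.0
MIN_DETECTED_SAMPLES = 2


@dataclass
class GeneMatrix:
    """Gene x sample log2 expression with the provenance of each row.

    ``chosen_probe`` records which probe represents each gene (the one
    with the highest control-sample mean; ties go to the
    lexicographically smallest probe id).
    """

    data: pd.DataFrame
    chosen_probe: pd.Series

    def condition_columns(self, condition: str) -> list[str]:
        return condition_columns(self.data.columns, condition)


def quantile_normalize(probe_matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: every column is mapped onto the row-wise
    mean of the column-sorted values, by rank.

    After normalization all columns have identical sorted values.  Tied
    values within a column receive the mean of the reference values over
    the tied block.  Missing values are not supported.
    """
    if probe_matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if probe_matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    values = probe_matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # ties: average the reference values assigned to the tied block
        mapped = pd.Series(mapped).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = mapped
    return pd.DataFrame(out, index=probe_matrix.index, columns=probe_matrix.columns)


def detection_filter(
    matrix: pd.DataFrame,
    threshold: float = DETECTION_THRESHOLD,
    min_detected: int = MIN_DETECTED_SAMPLES,
) -> set[str]:
    """Features whose log2 value reaches ``threshold`` (inclusive) in at
    least ``min_detected`` samples.

    With the defaults this is the published rule: a feature detected in
    none or only one of the 12 samples is excluded.
    """
    n_above = (matrix >= threshold).sum(axis=1)
    return set(matrix.index[n_above >= min_detected])


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    control_condition: str = CONTROL,
) -> GeneMatrix:
    """One representative probe per gene: the highest-expressed in controls.

    ``probe_map`` has columns (probe_id, gene_symbol) and must cover every
    row of ``probe_matrix``.  Exact ties on the control mean are broken by
    the lexicographically smallest probe id.  Genes whose probes were all
    filtered out upstream are simply absent.
    """
    mapping = probe_map.set_index("probe_id")["gene_symbol"]
    unmapped = probe_matrix.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"probes without gene mapping: {list(unmapped[:5])} ...")
    control_cols = condition_columns(probe_matrix.columns, control_condition)
    if not control_cols:
        raise ValueError(f"no {control_condition!r} samples in matrix")
    control_mean = probe_matrix[control_cols].mean(axis=1)
    choice = (
        pd.DataFrame(
            {
                "gene": mapping.reindex(probe_matrix.index),
                "control_mean": control_mean,
            }
        )
        .sort_index()  # lexicographic probe order => first max wins ties
        .groupby("gene")["control_mean"]
        .idxmax()
    )
    data = probe_matrix.loc[choice.values].copy()
    data.index = pd.Index(choice.index, name="gene_symbol")
    chosen = pd.Series(choice.values, index=choice.index, name="probe_id")
    return GeneMatrix(data=data, chosen_probe=chosen)


def differential_expression(
    gene_matrix: GeneMatrix,
    contrast: str,
    alpha: float = 0.05,
    control_condition: str = CONTROL,
) -> list[DiffResult]:
    """Per-gene paired t-test of log2 expression, treated vs control.

    The log2 fold change is the mean within-patient difference of log2
    values (fold changes and p-values as plotted on a volcano).
    """
    treated = gene_matrix.condition_columns(contrast)
    control = gene_matrix.condition_columns(control_condition)
    if not treated:
        raise ValueError(f"no samples for contrast {contrast!r}")
    return paired_t_table(gene_matrix.data, treated, control, alpha=alpha, log2fc_scale=1.0)


def delta_ct_expression(ct_target: float, ct_housekeeping: float) -> float:
    """Relative expression 2^-(Ct_target - Ct_housekeeping)."""
    if ct_housekeeping is None or not np.isfinite(ct_housekeeping):
        raise ValueError("missing housekeeping Ct value")
    if ct_target is None or not np.isfinite(ct_target):
        raise ValueError("missing target Ct value")
    return float(2.0 ** (-(ct_target - ct_housekeeping)))


@dataclass(frozen=True)
class QpcrResult:
    """Relative expression and the ratio-paired test for one gene/contrast."""

    gene: str
    contrast: str
    geometric_ratio: float
    p: float
    n_pairs: int
    untestable: bool
    zero_variance: bool


def qpcr_relative_expression(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``relative_expression`` (2^-dCt) column to a Ct table with
    columns (patient, condition, gene, ct, ct_housekeeping)."""
    required = {"patient", "condition", "gene", "ct", "ct_housekeeping"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    out = ct_table.copy()
    out["relative_expression"] = [
        delta_ct_expression(t, h) for t, h in zip(out["ct"], out["ct_housekeeping"])
    ]
    return out


def qpcr_contrast(
    ct_table: pd.DataFrame, gene: str, contrast: str, control_condition: str = CONTROL
) -> QpcrResult:
    """Ratio paired t-test of 2^-dCt expression, treated vs control, for one gene."""
    expr = qpcr_relative_expression(ct_table[ct_table["gene"] == gene])
    wide = expr.pivot(index="patient", columns="condition", values="relative_expression")
    if contrast not in wide.columns or control_condition not in wide.columns:
        raise ValueError(f"gene {gene!r}: conditions missing from Ct table")
    ratio, res = ratio_paired_t_test(wide[contrast], wide[control_condition])
    return QpcrResult(
        gene, contrast, ratio, res.p, res.n_pairs, res.untestable, res.zero_variance
    )
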