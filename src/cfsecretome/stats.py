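"""Paired statistics shared by the proteome and transcriptome layers.

The study design is fully paired: every patient contributes one control and
one treated sample per stimulus, so all comparisons reduce to one-sample
t-tests on within-patient differences of log-scale values.  Significance is
a raw two-sided p < alpha throughout — no multiple-testing correction is
applied anywhere in this package, deliberately mirroring the original
analysis; interpret gene-level hit lists accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

LOG2_PER_LOG10 = 1.0 / math.log10(2.0)

__all__ = [
    "PairedTestResult",
    "DiffResult",
    "VolcanoCounts",
    "paired_t_test",
    "ratio_paired_t_test",
    "paired_t_table",
    "classify_volcano",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one paired t-test.

    ``mean_diff`` is the mean of within-pair differences on the scale the
    values were supplied on (already log-transformed by the caller).
    ``untestable`` marks fewer than two complete pairs; ``zero_variance``
    marks identical differences across pairs, where t (and hence p) is
    undefined.
    """

    mean_diff: float
    t: float
    p: float
    n_pairs: int
    untestable: bool = False
    zero_variance: bool = False


@dataclass(frozen=True)
class DiffResult:
    """Per-feature differential result for one treated-vs-control contrast."""

    feature: str
    log2fc: float
    p: float
    direction: str  # "up" | "down" | "ns"
    n_pairs: int = 0


@dataclass(frozen=True)
class VolcanoCounts:
    n_up: int
    n_down: int
    n_ns: int

    @property
    def total_significant(self) -> int:
        return self.n_up + self.n_down

    @property
    def total(self) -> int:
        return self.n_up + self.n_down + self.n_ns


def _complete_pairs(
    treated: Sequence[float], control: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treated and control must have equal length (paired design)")
    keep = np.isfinite(t) & np.isfinite(c)
    return t[keep], c[keep]


def paired_t_test(
    values_treated: Sequence[float], values_control: Sequence[float]
) -> PairedTestResult:
    """Classical paired t-test on already log-transformed values.

    Pairs with a missing (NaN) member are dropped.  With fewer than two
    complete pairs the result is flagged ``untestable`` (p = NaN); with
    zero-variance differences t is infinite-or-0/0 and the result is
    flagged ``zero_variance`` (p = NaN, mean difference still reported).
    """
    t_vals, c_vals = _complete_pairs(values_treated, values_control)
    n = t_vals.size
    if n < 2:
        md = float(t_vals.mean() - c_vals.mean()) if n else float("nan")
        return PairedTestResult(md, float("nan"), float("nan"), n, untestable=True)
    diffs = t_vals - c_vals
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(md, float("nan"), float("nan"), n, zero_variance=True)
    t_stat = md / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t_stat), df=n - 1))
    return PairedTestResult(md, float(t_stat), p, n)


def ratio_paired_t_test(
    expr_treated: Sequence[float], expr_control: Sequence[float]
) -> tuple[float, PairedTestResult]:
    """Ratio paired t-test: paired t-test on log2-transformed expression.

    Returns the geometric mean of per-pair treated/control ratios together
    with the test result (whose ``mean_diff`` is the mean log2 ratio, so
    the geometric-mean ratio equals ``2**mean_diff``).  Raises on
    non-positive expression values, which have no ratio interpretation.
    """
    t = np.asarray(expr_treated, dtype=float)
    c = np.asarray(expr_control, dtype=float)
    finite = np.isfinite(t) & np.isfinite(c)
    if np.any((t[finite] <= 0) | (c[finite] <= 0)):
        raise ValueError("ratio paired t-test requires strictly positive expression")
    res = paired_t_test(np.log2(t), np.log2(c))
    geo_ratio = float(2.0 ** res.mean_diff) if np.isfinite(res.mean_diff) else float("nan")
    return geo_ratio, res


def paired_t_table(
    matrix: pd.DataFrame,
    treated_cols: Sequence[str],
    control_cols: Sequence[str],
    alpha: float = 0.05,
    log2fc_scale: float = 1.0,
) -> list[DiffResult]:
    """Row-wise paired t-tests on a feature x sample matrix.

    ``treated_cols[i]`` is paired with ``control_cols[i]`` (same patient).
    ``log2fc_scale`` converts the mean difference to a log2 fold change
    (use ``LOG2_PER_LOG10`` when the matrix holds log10 values).
    Untestable or zero-variance rows are classified "ns" with p = NaN.
    """
    if len(treated_cols) != len(control_cols):
        raise ValueError("treated and control column lists must align by patient")
    out: list[DiffResult] = []
    for feature, row in matrix.iterrows():
        res = paired_t_test(row[list(treated_cols)], row[list(control_cols)])
        log2fc = res.mean_diff * log2fc_scale
        if np.isfinite(res.p) and res.p < alpha and log2fc > 0:
            direction = "up"
        elif np.isfinite(res.p) and res.p < alpha and log2fc < 0:
            direction = "down"
        else:
            direction = "ns"
        out.append(DiffResult(str(feature), float(log2fc), float(res.p), direction, res.n_pairs))
    return out


def classify_volcano(
    diff_results: Sequence[DiffResult], alpha: float = 0.05
) -> tuple[set[str], set[str], set[str], VolcanoCounts]:
    """Partition differential results into up / down / non-significant.

    A feature is "regulated" only with p < alpha AND a nonzero fold change;
    a zero fold change is never counted as regulated regardless of p.
    """
    up: set[str] = set()
    down: set[str] = set()
    ns: set[str] = set()
    for r in diff_results:
        if np.isfinite(r.p) and r.p < alpha and r.log2fc > 0:
            up.add(r.feature)
        elif np.isfinite(r.p) and r.p < alpha and r.log2fc < 0:
            down.add(r.feature)
        else:
            ns.add(r.feature)
    return up, down, ns, VolcanoCounts(len(up), len(down), len(ns))
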