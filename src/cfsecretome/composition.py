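"""Compositional analysis of the secretome and its transcriptome, category-
level stimulation comparisons, and protein-transcript correlation.

Composition is computed on linear-scale abundances — iBAQ values for
proteins, 2**log2 expression for transcripts — summed over the control
(quiescent) samples, as fractions of a level-specific denominator:

* ``proteome``:   all quantified proteins, sliced by localization;
* ``secretome``:  secreted proteins, sliced into cytokines / ECM / other;
* ``ecm``:        ECM proteins, sliced into fibronectin / collagens /
                  MMPs-TIMPs / other ECM.

Fractions at a level always sum to 1, and the nesting is consistent:
a subcategory's share of the whole equals its share of its parent times
the parent's share of the whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import (
    SECRETED,
    TAG_CYTOKINE,
    TAG_ECM,
    TAG_OTHER_SECRETED,
    CategoryAssignment,
)
from .config import CONTROL
from .samples import condition_columns
from .stats import LOG2_PER_LOG10, DiffResult, paired_t_test

logger = logging.getLogger(__name__)

PROTEOME_LEVEL = "proteome"
SECRETOME_LEVEL = "secretome"
ECM_LEVEL = "ecm"
TRANSCRIPTOME_LEVEL = "transcriptome_of_secreted"


@dataclass(frozen=True)
class CompositionReport:
    """category -> fraction of summed intensity at one compositional level."""

    level: str
    fractions: dict[str, float]
    denominator: float  # summed intensity over the level's feature set
    n_features: int
    category_sums: dict[str, float] = field(default_factory=dict)

    def as_percent(self) -> dict[str, int]:
        """Fractions as integer percentages (presentation convention)."""
        return {k: round(100.0 * v) for k, v in self.fractions.items()}


def _level_slices(
    assignments: dict[str, CategoryAssignment], level: str
) -> tuple[list[str], dict[str, str]]:
    """Feature ids in a level's denominator and their slice labels."""
    members: dict[str, str] = {}
    if level == PROTEOME_LEVEL:
        for f, a in assignments.items():
            members[f] = SECRETED if a.is_secreted else a.localization
    elif level in (SECRETOME_LEVEL, TRANSCRIPTOME_LEVEL):
        for f, a in assignments.items():
            cat = a.secretome_category()
            if cat is not None:
                members[f] = cat
    elif level == ECM_LEVEL:
        for f, a in assignments.items():
            sub = a.ecm_subcategory()
            if sub is not None:
                members[f] = sub
    else:
        raise ValueError(f"unknown composition level {level!r}")
    return list(members), members


def composition_fractions(
    ibaq: pd.DataFrame,
    assignments: dict[str, CategoryAssignment],
    level: str,
    control_condition: str = CONTROL,
) -> CompositionReport:
    """Intensity fractions per category at one level, from iBAQ values
    summed over control samples.

    Raises if any included protein lacks a defined iBAQ value (undefined
    theoretical-peptide count) or if the denominator is zero.
    """
    control_cols = condition_columns(ibaq.columns, control_condition)
    if not control_cols:
        raise ValueError("no control samples in iBAQ layer")
    features, slice_of = _level_slices(assignments, level)
    features = [f for f in features if f in ibaq.index]
    sub = ibaq.loc[features, control_cols]
    if sub.isna().any().any():
        bad = list(sub.index[sub.isna().any(axis=1)])
        raise ValueError(f"iBAQ undefined for included proteins: {bad[:5]}")
    totals = sub.sum(axis=1)
    denom = float(totals.sum())
    if denom <= 0:
        raise ValueError(f"zero total intensity at level {level!r}")
    sums: dict[str, float] = {}
    for f, value in totals.items():
        sums[slice_of[f]] = sums.get(slice_of[f], 0.0) + float(value)
    fractions = {k: v / denom for k, v in sorted(sums.items())}
    return CompositionReport(level, fractions, denom, len(features), dict(sorted(sums.items())))


def transcript_composition(
    gene_log2: pd.DataFrame,
    gene_assignments: dict[str, CategoryAssignment],
    control_condition: str = CONTROL,
    linear: bool = True,
) -> CompositionReport:
    """Category shares of summed expression over genes coding for secreted
    proteins (control samples).

    ``gene_log2`` is a gene x sample log2 matrix (detection-filtered).
    Shares are computed on the linear scale (2**log2) by default — log2
    values are not additive abundances — with a log-scale switch for
    sensitivity analysis.
    """
    control_cols = condition_columns(gene_log2.columns, control_condition)
    if not control_cols:
        raise ValueError("no control samples in gene matrix")
    _, slice_of = _level_slices(gene_assignments, TRANSCRIPTOME_LEVEL)
    genes = [g for g in gene_log2.index if g in slice_of]
    values = gene_log2.loc[genes, control_cols]
    totals = (2.0 ** values).sum(axis=1) if linear else values.sum(axis=1)
    denom = float(totals.sum())
    if denom <= 0:
        raise ValueError("zero total expression over secreted genes")
    sums: dict[str, float] = {}
    for g, value in totals.items():
        sums[slice_of[g]] = sums.get(slice_of[g], 0.0) + float(value)
    # report empty categories as 0 so protein/transcript tables align
    for cat in (TAG_CYTOKINE, TAG_ECM, TAG_OTHER_SECRETED):
        sums.setdefault(cat, 0.0)
    fractions = {k: v / denom for k, v in sorted(sums.items())}
    return CompositionReport(
        TRANSCRIPTOME_LEVEL, fractions, denom, len(genes), dict(sorted(sums.items()))
    )


def category_sum_comparison(
    linear_matrix: pd.DataFrame,
    category_of: dict[str, str],
    contrast: str,
    alpha: float = 0.05,
    log_base: int = 10,
    control_condition: str = CONTROL,
) -> list[DiffResult]:
    """Paired test of per-patient summed category intensity, treated vs control.

    ``linear_matrix`` holds linear-scale abundances (raw/iBAQ protein
    intensities, or 2**log2 expression); features map to categories via
    ``category_of`` (features absent from the map are ignored).  Per
    category and sample the member intensities are summed, log-transformed
    (``log_base`` 10 for proteins, 2 for transcripts), and compared with a
    paired t-test.  Empty categories are skipped with a warning.
    """
    if log_base not in (2, 10):
        raise ValueError("log_base must be 2 or 10")
    treated_cols = condition_columns(linear_matrix.columns, contrast)
    control_cols = condition_columns(linear_matrix.columns, control_condition)
    if not treated_cols or len(treated_cols) != len(control_cols):
        raise ValueError(f"unpaired or missing samples for contrast {contrast!r}")
    results: list[DiffResult] = []
    categories = sorted(set(category_of.values()))
    for cat in categories:
        members = [f for f, c in category_of.items() if c == cat and f in linear_matrix.index]
        if not members:
            logger.warning("category %r has no quantified members; skipped", cat)
            continue
        sums_t = linear_matrix.loc[members, treated_cols].sum(axis=0)
        sums_c = linear_matrix.loc[members, control_cols].sum(axis=0)
        log = np.log10 if log_base == 10 else np.log2
        res = paired_t_test(log(sums_t.to_numpy()), log(sums_c.to_numpy()))
        scale = LOG2_PER_LOG10 if log_base == 10 else 1.0
        log2fc = res.mean_diff * scale
        if np.isfinite(res.p) and res.p < alpha and log2fc > 0:
            direction = "up"
        elif np.isfinite(res.p) and res.p < alpha and log2fc < 0:
            direction = "down"
        else:
            direction = "ns"
        results.append(DiffResult(cat, float(log2fc), float(res.p), direction, res.n_pairs))
    return results


MAX_EXACT_PERMUTATION_N = 7


def spearman_correlation(
    x, y, exact_max_n: int = MAX_EXACT_PERMUTATION_N
) -> tuple[float, float, int]:
    """Spearman rank correlation with an exact permutation p for small n.

    For n <= ``exact_max_n`` the two-sided p-value is the exact fraction
    of the n! rank arrangements with |rho| at least the observed |rho|;
    beyond that the asymptotic p from scipy is used.  Returns
    (rho, p, n); with n < 3 the correlation is untestable (NaNs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        return float("nan"), float("nan"), n
    rho, p_asym = sps.spearmanr(x, y)
    rho = float(rho)
    if n > exact_max_n:
        return rho, float(p_asym), n
    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    eps = 1e-12
    hits = 0
    total = 0
    for perm in permutations(ry):
        r = float(sps.spearmanr(rx, np.array(perm)).statistic)
        if abs(r) >= abs(rho) - eps:
            hits += 1
        total += 1
    return rho, hits / total, n


def protein_transcript_correlation(
    protein_log10_means: pd.Series,
    gene_log2_means: pd.Series,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlate mean control protein abundance with mean control expression
    over features matched by index (gene symbol).

    Default is Spearman rank correlation (exact permutation p for small n),
    switchable to Pearson.  Fewer than 3 matched features is untestable.
    """
    common = protein_log10_means.index.intersection(gene_log2_means.index)
    x = protein_log10_means.loc[common].to_numpy(dtype=float)
    y = gene_log2_means.loc[common].to_numpy(dtype=float)
    if method == "spearman":
        return spearman_correlation(x, y)
    if method == "pearson":
        if len(common) < 3:
            return float("nan"), float("nan"), len(common)
        r, p = sps.pearsonr(x, y)
        return float(r), float(p), len(common)
    raise ValueError(f"unknown correlation method {method!r}")


def check_nested_consistency(
    parent: CompositionReport, child: CompositionReport, parent_category: str
) -> float:
    """Max absolute violation of the nesting identity
    fraction_of_total(sub) = fraction_of_parent(sub) * fraction_of_total(parent).

    The child's denominator must be the intensity of ``parent_category``
    within the parent report.
    """
    parent_share = parent.fractions[parent_category]
    worst = abs(child.denominator - parent.category_sums[parent_category]) / max(
        parent.denominator, 1e-300
    )
    for sub, frac in child.fractions.items():
        of_total = child.category_sums[sub] / parent.denominator
        worst = max(worst, abs(of_total - frac * parent_share))
    return worst
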