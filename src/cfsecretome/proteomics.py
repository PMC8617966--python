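"""Peptide intensities -> protein quantification -> paired differential secretion.

The quantification path follows label-free convention for serum-supplemented
cell culture supernatants: tryptic peptides shared between the cultured-cell
species and the serum species are excluded outright (they cannot be
attributed to the cells), peptides ambiguous among several cell proteins
are likewise excluded (unique-peptide quantification), and a protein's raw
intensity is the sum of its surviving peptides.  Intensities are log10
transformed and median normalized before paired t-tests; iBAQ values (raw
intensity / number of theoretical tryptic peptides of 6-30 residues) make
abundances comparable across proteins for compositional analysis.

A raw intensity of 0 means "not detected" and stays missing on the log
scale — nothing is ever imputed; paired tests drop incomplete pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONTROL
from .digestion import (
    DEFAULT_MAX_PEPTIDE_LEN,
    DEFAULT_MIN_PEPTIDE_LEN,
    count_theoretical_peptides,
    digest_tryptic,
)
from .records import ProteinRecord
from .stats import LOG2_PER_LOG10, DiffResult, paired_t_table

logger = logging.getLogger(__name__)


@dataclass
class ProteinQuantMatrix:
    """Protein x sample quantification with derived layers.

    ``raw``: summed peptide intensities, 0 = not detected.
    ``log10``: log10(raw), NaN where not detected.
    ``normalized``: median-normalized log10 layer (see
    :func:`normalize_log10_median`).
    ``ibaq``: raw / theoretical-peptide count, NaN where the count is 0.
    Columns are labelled ``P<patient>_<condition>``.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    ibaq: pd.DataFrame | None = None
    peptide_counts: pd.Series | None = None
    dropped_peptides: dict[str, int] = field(default_factory=dict)

    @property
    def log10(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return np.log10(self.raw.where(self.raw > 0))

    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def patients(self) -> list[int]:
        return sorted({int(c.split("_")[0][1:]) for c in self.raw.columns})

    def condition_columns(self, condition: str) -> list[str]:
        """Columns of one condition, ordered by patient number."""
        cols = [c for c in self.raw.columns if c.split("_", 1)[1] == condition]
        return sorted(cols, key=lambda c: int(c.split("_")[0][1:]))


def _peptide_index(cell_db: list[ProteinRecord]) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for rec in cell_db:
        for pep in set(digest_tryptic(rec.sequence)):
            index.setdefault(pep, []).append(rec.accession)
    return index


def quantify_proteins(
    peptide_table: pd.DataFrame,
    cell_db: list[ProteinRecord],
    shared_set: set[str],
) -> ProteinQuantMatrix:
    """Aggregate a long-format peptide table into the raw protein layer.

    Rules, in order: peptides in ``shared_set`` contribute nothing;
    peptides matching no cell protein are logged and dropped; peptides
    matching more than one cell protein are dropped (unique-peptide rule);
    the rest are summed into their protein per sample (replicate
    measurements of a peptide are averaged first).  Proteins with no
    surviving peptide are absent from the matrix.
    """
    required = {"peptide", "patient", "condition", "intensity"}
    missing = required - set(peptide_table.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")

    index = _peptide_index(cell_db)
    table = peptide_table.copy()
    dropped = {"shared": 0, "unmatched": 0, "ambiguous": 0}

    def resolve(pep: str) -> str | None:
        if pep in shared_set:
            dropped["shared"] += 1
            return None
        owners = index.get(pep)
        if owners is None:
            dropped["unmatched"] += 1
            return None
        if len(owners) > 1:
            dropped["ambiguous"] += 1
            return None
        return owners[0]

    unique_peps = table["peptide"].unique()
    owner_of = {p: resolve(p) for p in unique_peps}
    if dropped["unmatched"]:
        logger.warning(
            "%d peptide sequences matched no cell-database protein and were dropped",
            dropped["unmatched"],
        )
    table["accession"] = table["peptide"].map(owner_of)
    table = table.dropna(subset=["accession"])

    if "replicate" in table.columns:
        table = (
            table.groupby(["accession", "peptide", "patient", "condition"], sort=True)[
                "intensity"
            ]
            .mean()
            .reset_index()
        )
    table["sample"] = "P" + table["patient"].astype(str) + "_" + table["condition"]
    raw = (
        table.groupby(["accession", "sample"], sort=True)["intensity"]
        .sum()
        .unstack(fill_value=0.0)
    )
    raw.index.name = "accession"
    # stable sample order: by patient then condition order of appearance
    cond_order = list(dict.fromkeys(peptide_table["condition"]))
    patients = sorted(peptide_table["patient"].unique())
    cols = [f"P{p}_{c}" for p in patients for c in cond_order if f"P{p}_{c}" in raw.columns]
    raw = raw.reindex(columns=cols, fill_value=0.0)
    return ProteinQuantMatrix(raw=raw, dropped_peptides=dropped)


def define_extracellular_proteome(
    matrix: ProteinQuantMatrix, control_condition: str = CONTROL
) -> set[str]:
    """Proteins detected in the control supernatant of *every* patient.

    Consistent detection across all patients is what defines the
    extracellular proteome; detection in treated samples does not count
    (the secretome is defined on quiescent cells).
    """
    control_cols = matrix.condition_columns(control_condition)
    patients_with_control = {c.split("_")[0] for c in control_cols}
    all_patients = {f"P{p}" for p in matrix.patients()}
    if patients_with_control != all_patients:
        raise ValueError("every patient needs a control sample to define the proteome")
    detected = (matrix.raw[control_cols] > 0).all(axis=1)
    return set(matrix.raw.index[detected])


def normalize_log10_median(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Median-normalize the log10 layer in place (and return the matrix).

    Each sample is shifted additively so its median over detected proteins
    equals the global median of per-sample medians.  Zeros (not detected)
    remain missing; they are never imputed.
    """
    log10 = matrix.log10
    medians = log10.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with no detected proteins: {bad}")
    target = float(medians.median())
    matrix.normalized = log10 + (target - medians)
    return matrix


def compute_ibaq(
    matrix: ProteinQuantMatrix,
    cell_db: list[ProteinRecord],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> ProteinQuantMatrix:
    """Attach the iBAQ layer: raw intensity / theoretical peptide count.

    A detected protein whose sequence yields zero in-bounds theoretical
    peptides has no defined iBAQ value; it is flagged with a warning and
    left NaN.
    """
    counts = pd.Series(
        {
            rec.accession: count_theoretical_peptides(rec.sequence, min_len, max_len)
            for rec in cell_db
        },
        name="theoretical_peptides",
    )
    counts = counts.reindex(matrix.raw.index)
    zero = counts[counts == 0]
    if len(zero):
        logger.warning(
            "iBAQ undefined for %d proteins with no theoretical peptides in [%d, %d]: %s",
            len(zero),
            min_len,
            max_len,
            list(zero.index),
        )
    divisor = counts.where(counts >= 1)
    matrix.ibaq = matrix.raw.div(divisor, axis=0)
    matrix.peptide_counts = counts
    return matrix


def differential_secretion(
    matrix: ProteinQuantMatrix,
    contrast: str,
    alpha: float = 0.05,
    control_condition: str = CONTROL,
) -> list[DiffResult]:
    """Paired t-test per protein, treated vs control, on normalized log10.

    ``contrast`` names the treated condition (e.g. "TNFA").  The reported
    log2 fold change is the mean paired log10 difference divided by
    log10(2).  Proteins missing in a patient's pair lose that pair.
    """
    if matrix.normalized is None:
        raise ValueError("normalize_log10_median must run before differential testing")
    treated = matrix.condition_columns(contrast)
    control = matrix.condition_columns(control_condition)
    if not treated:
        raise ValueError(f"no samples for contrast {contrast!r}")
    return paired_t_table(
        matrix.normalized, treated, control, alpha=alpha, log2fc_scale=LOG2_PER_LOG10
    )
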