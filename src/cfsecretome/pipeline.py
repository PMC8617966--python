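"""End-to-end orchestration of the secretome/transcriptome analysis.

Stages (each independently callable from its own module):

1. shared-peptide exclusion set from the two species databases;
2. peptide -> protein quantification, extracellular-proteome definition
   (detected in every patient's control), log10 + median normalization,
   iBAQ;
3. keyword/name categorization of proteins and genes;
4. array processing: quantile normalization, log2, detection filter,
   probe collapsing, paired differential expression;
5. compositional reports, category-sum stimulation comparisons,
   protein-transcript correlation.

``run_pipeline`` takes the in-memory bundle produced by
``simulate.simulate_all`` (or equivalently loaded input files) and returns
a PipelineResult with every intermediate the reports need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CategoryAssignment, assign_categories
from .composition import (
    ECM_LEVEL,
    PROTEOME_LEVEL,
    SECRETOME_LEVEL,
    CompositionReport,
    category_sum_comparison,
    composition_fractions,
    protein_transcript_correlation,
    transcript_composition,
)
from .config import CONTROL, SimConfig
from .digestion import build_shared_peptide_set
from .proteomics import (
    ProteinQuantMatrix,
    compute_ibaq,
    define_extracellular_proteome,
    differential_secretion,
    normalize_log10_median,
    quantify_proteins,
)
from .records import ProteinRecord, sequences_by_accession
from .samples import condition_columns
from .stats import DiffResult, classify_volcano, VolcanoCounts
from .transcriptomics import (
    GeneMatrix,
    collapse_probes,
    detection_filter,
    differential_expression,
    quantile_normalize,
)


def load_bundle(indir) -> dict:
    """Load a simulated (or equivalently formatted real) study from disk:
    cell/serum FASTA, annotation TSV, peptide TSV, probe matrix + map TSV,
    qPCR Ct TSV — the inverse of ``simulate.simulate_all(..., outdir=...)``."""
    from pathlib import Path

    from .records import read_annotation_table, read_fasta

    d = Path(indir)
    bundle = {
        "cell_db": read_fasta(d / "cell_db.fasta", species="cell"),
        "serum_db": read_fasta(d / "serum_db.fasta", species="serum"),
        "annotation": read_annotation_table(d / "annotation.tsv"),
        "peptide_table": pd.read_csv(d / "peptides.tsv", sep="\t"),
        "probe_matrix": pd.read_csv(d / "probe_matrix.tsv", sep="\t", index_col=0),
        "probe_map": pd.read_csv(d / "probe_map.tsv", sep="\t"),
        "qpcr_table": pd.read_csv(d / "qpcr_ct.tsv", sep="\t"),
    }
    truth_path = d / "truth.json"
    if truth_path.exists():
        from .simulate import SimTruth

        bundle["truth"] = SimTruth.from_json(truth_path)
    return bundle


@dataclass
class PipelineResult:
    matrix: ProteinQuantMatrix  # restricted to the extracellular proteome
    extracellular: set[str]
    secretome: set[str]
    assignments: dict[str, CategoryAssignment]  # by accession
    gene_assignments: dict[str, CategoryAssignment]  # by gene symbol
    protein_diff: dict[str, list[DiffResult]]
    gene_matrix: GeneMatrix
    gene_diff: dict[str, list[DiffResult]]  # over secreted genes
    volcano_counts: dict[str, VolcanoCounts]
    compositions: dict[str, CompositionReport]
    category_protein_diff: dict[str, list[DiffResult]]
    category_gene_diff: dict[str, list[DiffResult]]
    correlation: tuple[float, float, int]
    shared_peptides: set[str] = field(default_factory=set)


def process_proteome(
    peptide_table: pd.DataFrame,
    cell_db: list[ProteinRecord],
    serum_db: list[ProteinRecord],
    min_pep_len: int = 6,
    max_pep_len: int = 30,
) -> tuple[ProteinQuantMatrix, set[str], set[str]]:
    """Quantification stage: returns (quant matrix restricted to the
    extracellular proteome, extracellular accession set, shared peptides)."""
    shared = build_shared_peptide_set(
        sequences_by_accession(cell_db),
        sequences_by_accession(serum_db),
        min_pep_len,
        max_pep_len,
    )
    matrix = quantify_proteins(peptide_table, cell_db, shared)
    extracellular = define_extracellular_proteome(matrix)
    matrix.raw = matrix.raw.loc[sorted(extracellular)]
    normalize_log10_median(matrix)
    compute_ibaq(matrix, cell_db, min_pep_len, max_pep_len)
    return matrix, extracellular, shared


def process_arrays(
    probe_matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    threshold: float = 5.0,
    min_detected: int = 2,
) -> GeneMatrix:
    """Array stage: quantile normalize linear probe intensities, log2,
    detection-filter at probe level, collapse to one probe per gene."""
    normalized = quantile_normalize(probe_matrix)
    log2 = np.log2(normalized)
    retained = detection_filter(log2, threshold, min_detected)
    filtered = log2.loc[log2.index.isin(retained)]
    return collapse_probes(filtered, probe_map)


def gene_level_assignments(
    assignments: dict[str, CategoryAssignment]
) -> dict[str, CategoryAssignment]:
    """Collapse accession-level assignments to gene level (first wins on
    duplicate symbols; synthetic symbols are unique per gene)."""
    out: dict[str, CategoryAssignment] = {}
    for a in assignments.values():
        out.setdefault(a.gene_symbol, a)
    return out


def run_pipeline(
    bundle: dict,
    contrasts: tuple[str, ...] = ("TNFA", "TGFB"),
    alpha: float = 0.05,
    control_condition: str = CONTROL,
) -> PipelineResult:
    """Run every analysis stage on a simulate_all-style input bundle."""
    cell_db = bundle["cell_db"]
    matrix, extracellular, shared = process_proteome(
        bundle["peptide_table"], cell_db, bundle["serum_db"]
    )
    assignments = assign_categories(bundle["annotation"])
    assignments = {a: v for a, v in assignments.items() if a in extracellular}
    gene_assignments = gene_level_assignments(assignments)
    secretome = {a for a, v in assignments.items() if v.is_secreted}

    protein_diff = {
        c: differential_secretion(matrix, c, alpha, control_condition) for c in contrasts
    }

    gene_matrix = process_arrays(bundle["probe_matrix"], bundle["probe_map"])
    all_gene_assignments = gene_level_assignments(assign_categories(bundle["annotation"]))
    secreted_genes = [
        g for g in gene_matrix.data.index if all_gene_assignments.get(g) is not None
        and all_gene_assignments[g].is_secreted
    ]
    secreted_gene_matrix = GeneMatrix(
        gene_matrix.data.loc[secreted_genes],
        gene_matrix.chosen_probe.loc[secreted_genes],
    )
    gene_diff = {
        c: differential_expression(secreted_gene_matrix, c, alpha, control_condition)
        for c in contrasts
    }
    volcano_counts = {c: classify_volcano(gene_diff[c], alpha)[3] for c in contrasts}

    compositions = {
        level: composition_fractions(matrix.ibaq, assignments, level, control_condition)
        for level in (PROTEOME_LEVEL, SECRETOME_LEVEL, ECM_LEVEL)
    }
    secreted_assign = {g: all_gene_assignments[g] for g in secreted_genes}
    compositions["transcriptome_of_secreted"] = transcript_composition(
        secreted_gene_matrix.data, secreted_assign, control_condition
    )

    protein_cat = {
        a: v.flat_category() for a, v in assignments.items() if v.flat_category()
    }
    gene_cat = {
        g: v.flat_category() for g, v in secreted_assign.items() if v.flat_category()
    }
    category_protein_diff = {
        c: category_sum_comparison(
            matrix.raw.where(matrix.raw > 0), protein_cat, c, alpha, 10, control_condition
        )
        for c in contrasts
    }
    linear_genes = 2.0 ** secreted_gene_matrix.data
    category_gene_diff = {
        c: category_sum_comparison(linear_genes, gene_cat, c, alpha, 2, control_condition)
        for c in contrasts
    }

    ctrl_p = condition_columns(matrix.normalized.columns, control_condition)
    protein_means = matrix.normalized[ctrl_p].mean(axis=1)
    protein_means.index = [assignments[a].gene_symbol for a in protein_means.index]
    ctrl_g = secreted_gene_matrix.condition_columns(control_condition)
    gene_means = secreted_gene_matrix.data[ctrl_g].mean(axis=1)
    secreted_protein_means = protein_means.loc[
        [assignments[a].gene_symbol for a in sorted(secretome)]
    ]
    correlation = protein_transcript_correlation(secreted_protein_means, gene_means)

    return PipelineResult(
        matrix=matrix,
        extracellular=extracellular,
        secretome=secretome,
        assignments=assignments,
        gene_assignments=gene_assignments,
        protein_diff=protein_diff,
        gene_matrix=gene_matrix,
        gene_diff=gene_diff,
        volcano_counts=volcano_counts,
        compositions=compositions,
        category_protein_diff=category_protein_diff,
        category_gene_diff=category_gene_diff,
        correlation=correlation,
        shared_peptides=shared,
    )
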