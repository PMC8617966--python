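"""Ground-truth synthetic data for the paired secretome/transcriptome study.

Generates every pipeline input — two species' protein databases (FASTA),
an annotation table, a peptide-level MS intensity table, a probe-level
expression matrix with probe->gene map, and a qPCR Ct table — from one
master seed, together with a SimTruth record of everything planted:
category labels, true log2 fold changes, base abundances and the
serum-shared tryptic peptides.

Intensity model (paired design): on the log scale, a peptide observed in
sample (patient p, condition c) for protein i is

    log10 I = base_i + [fc(gene_i, c) + u_{i,p}] * log10(2) + offset_pep + eps

with ``u_{i,p} ~ N(0, patient_sd)`` a patient random effect shared across
conditions (it cancels in within-patient differences, which is what makes
the paired t-test the right analysis), ``offset_pep`` a fixed per-peptide
ionization efficiency, and ``eps`` residual noise.  Transcript probes use
the same structure on the log2 scale with per-probe affinity offsets.
MS detection is abundance-dependent (logistic dropout, see DropoutConfig).

All randomness flows from the master seed through ``numpy``
``SeedSequence.spawn`` streams (one per generator stage), so identical
(config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import log10
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    CATEGORIES,
    COLLAGEN,
    CONTROL,
    CYTOKINE,
    ECM_SCAFFOLD,
    ER,
    HOUSEKEEPING_GENE,
    INTRACELLULAR,
    MEMBRANE,
    MMP_TIMP,
    OTHER_SECRETED,
    SimConfig,
    config_to_dict,
)
from .digestion import digest_tryptic
from .records import ProteinRecord, write_annotation_table, write_fasta

LOG10_2 = log10(2.0)

# residues usable inside a tryptic segment (no K/R; P additionally excluded
# at segment starts so planted cleavage sites are never suppressed)
_INTERIOR_AA = np.array(list("ACDEFGHILMNPQSTVWY"))
_START_AA = np.array(list("ACDEFGHILMNQSTVWY"))

_CYTOKINE_SYMBOLS = ["IL6", "IL8", "IL11", "CCL2", "CCL7", "CCL8", "CXCL1", "CXCL2"]


@dataclass
class SimTruth:
    """Everything the generator planted, for downstream verification."""

    category: dict[str, str]  # accession -> category
    gene_of: dict[str, str]  # accession -> gene symbol
    base_log10: dict[str, float]  # accession -> MS base abundance (log10)
    log2fc: dict[str, dict[str, float]]  # gene -> condition -> true log2FC
    shared_peptides: list[str]  # planted human/serum shared tryptic peptides
    gene_category: dict[str, str]  # gene -> category (incl. array-only genes)
    below_threshold_genes: list[str] = field(default_factory=list)
    housekeeping_gene: str = HOUSEKEEPING_GENE

    def genes(self) -> list[str]:
        return list(self.gene_category)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_symbols(category: str, n: int) -> list[str]:
    """Field-realistic synthetic gene symbols honouring the name patterns
    the annotation layer matches on (COL<d>A<d>, MMP<d>/TIMP<d>, FN1)."""
    if category == COLLAGEN:
        return [f"COL{i // 2 + 1}A{i % 2 + 1}" for i in range(n)]
    if category == MMP_TIMP:
        return [("MMP" if i % 2 == 0 else "TIMP") + str(i // 2 + 1) for i in range(n)]
    if category == CYTOKINE:
        extra = [f"CCL{i + 9}" for i in range(max(0, n - len(_CYTOKINE_SYMBOLS)))]
        return (_CYTOKINE_SYMBOLS + extra)[:n]
    if category == ECM_SCAFFOLD:
        return (["FN1"] + [f"ECMP{i}" for i in range(1, n)])[:n]
    if category == OTHER_SECRETED:
        return [f"IGFBP{i + 1}" for i in range(n)]
    if category == MEMBRANE:
        return [f"MEMP{i + 1}" for i in range(n)]
    if category == ER:
        return [f"ERP{i + 1}" for i in range(n)]
    if category == INTRACELLULAR:
        return ([HOUSEKEEPING_GENE] + [f"ICP{i}" for i in range(1, n)])[:n]
    raise ValueError(f"unknown category {category!r}")


_KEYWORDS = {
    ECM_SCAFFOLD: frozenset({"Secreted", "Extracellular matrix"}),
    COLLAGEN: frozenset({"Secreted"}),  # ECM membership comes from the name
    MMP_TIMP: frozenset({"Secreted"}),
    CYTOKINE: frozenset({"Secreted", "Cytokine"}),
    OTHER_SECRETED: frozenset({"Secreted"}),
    MEMBRANE: frozenset({"Membrane"}),
    ER: frozenset({"Endoplasmic reticulum"}),
    INTRACELLULAR: frozenset(),
}


def _random_tryptic_segment(rng: np.random.Generator, min_len: int = 6, max_len: int = 24) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    body = rng.choice(_START_AA, 1).tolist() + rng.choice(_INTERIOR_AA, n - 2).tolist()
    tail = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + tail


def _random_sequence(rng: np.random.Generator, n_segments_range=(6, 12)) -> str:
    n_seg = int(rng.integers(*n_segments_range, endpoint=True))
    return "".join(_random_tryptic_segment(rng) for _ in range(n_seg))


def _mutate_outside_peptide(
    sequence: str, keep_peptide_index: int, rng: np.random.Generator
) -> str:
    """Serum near-homolog: mutate one interior residue of every tryptic
    peptide except the kept one, so exactly that peptide stays shared."""
    peptides = digest_tryptic(sequence)
    mutated = []
    for i, pep in enumerate(peptides):
        if i == keep_peptide_index or len(pep) < 3:
            mutated.append(pep)
            continue
        pos = int(rng.integers(1, len(pep) - 1))
        alternatives = [a for a in _START_AA if a != pep[pos]]
        repl = alternatives[int(rng.integers(len(alternatives)))]
        mutated.append(pep[:pos] + repl + pep[pos + 1 :])
    return "".join(mutated)


def generate_protein_database(
    config: SimConfig, seed: int
) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame, SimTruth]:
    """Cell- and serum-species sequence databases with ground truth.

    A ``shared_fraction`` of cell proteins receives a serum near-homolog
    (same sequence mutated everywhere outside one tryptic peptide), so the
    cross-species shared-peptide set is known exactly.  Returns
    (cell records, serum records, annotation table, truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    cell: list[ProteinRecord] = []
    truth = SimTruth({}, {}, {}, {}, [], {})

    acc_no = 0
    for category in CATEGORIES:
        n = config.n_proteins.get(category, 0)
        for symbol in _gene_symbols(category, n):
            acc_no += 1
            acc = f"CF{acc_no:04d}"
            seq = _random_sequence(rng)
            cell.append(ProteinRecord(acc, symbol, "cell", seq, _KEYWORDS[category]))
            truth.category[acc] = category
            truth.gene_of[acc] = symbol
            truth.gene_category[symbol] = category
            lo, hi = config.base_log10_range
            truth.base_log10[acc] = float(rng.uniform(lo, hi))
            truth.log2fc[symbol] = {
                cond: config.true_log2fc(cond, category) for cond in config.conditions
            }

    serum: list[ProteinRecord] = []
    n_homologs = int(round(config.shared_fraction * len(cell)))
    homolog_idx = rng.choice(len(cell), size=n_homologs, replace=False) if n_homologs else []
    for j, idx in enumerate(sorted(homolog_idx)):
        src = cell[idx]
        peptides = digest_tryptic(src.sequence)
        in_bounds = [i for i, p in enumerate(peptides) if 6 <= len(p) <= 30]
        keep = int(rng.choice(in_bounds))
        serum_seq = _mutate_outside_peptide(src.sequence, keep, rng)
        serum.append(ProteinRecord(f"BT{j + 1:04d}", f"{src.gene_symbol}_BOV", "serum", serum_seq))
        truth.shared_peptides.append(peptides[keep])
    for j in range(config.n_serum_only):
        serum.append(
            ProteinRecord(f"BTX{j + 1:03d}", f"SERUM{j + 1}", "serum", _random_sequence(rng))
        )

    annotation = pd.DataFrame(
        [
            {
                "accession": r.accession,
                "gene_symbol": r.gene_symbol,
                "keywords": ";".join(sorted(r.keywords)),
            }
            for r in cell
        ]
    )
    return cell, serum, annotation, truth


def _sample_label(patient: int, condition: str) -> str:
    return f"P{patient}_{condition}"


def sample_columns(config: SimConfig) -> list[str]:
    return [
        _sample_label(p, c)
        for p in range(1, config.n_patients + 1)
        for c in config.conditions
    ]


def generate_ms_peptide_table(
    cell_db: list[ProteinRecord],
    serum_db: list[ProteinRecord],
    truth: SimTruth,
    config: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Long-format peptide intensity table (peptide, patient, condition,
    replicate, intensity) including serum-derived contaminant peptides.

    Only tryptic peptides of 6-30 residues are observable.  Intensities
    follow the log-normal paired model documented at module level;
    detection is thinned by the logistic dropout model.
    """
    if not cell_db:
        raise ValueError("empty cell database")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    noise10 = config.noise_sd * LOG10_2
    patient_sd10 = config.patient_sd * LOG10_2

    rows: list[tuple[str, int, str, int, float]] = []
    for rec in cell_db:
        peptides = [p for p in digest_tryptic(rec.sequence) if 6 <= len(p) <= 30]
        if not peptides:
            continue
        base = truth.base_log10[rec.accession]
        fc = truth.log2fc[truth.gene_of[rec.accession]]
        pep_offsets = rng.normal(0.0, config.peptide_sd, size=len(peptides))
        u_patient = rng.normal(0.0, patient_sd10, size=config.n_patients)
        for p in range(config.n_patients):
            for cond in config.conditions:
                mu = base + fc[cond] * LOG10_2 + u_patient[p]
                for rep in range(1, config.ms_replicates + 1):
                    eps = rng.normal(0.0, noise10, size=len(peptides))
                    log10_i = mu + pep_offsets + eps
                    detect_p = config.ms_dropout.detect_probability(log10_i)
                    detected = rng.random(len(peptides)) < detect_p
                    for pep, li, d in zip(peptides, log10_i, detected):
                        if d:
                            rows.append((pep, p + 1, cond, rep, float(10.0 ** li)))

    # serum contamination: shared peptides plus unique peptides of
    # serum-only proteins, at a high, condition-independent level
    serum_only = [r for r in serum_db if r.accession.startswith("BTX")]
    contaminant_peps = list(truth.shared_peptides)
    for rec in serum_only[:2]:
        peps = [p for p in digest_tryptic(rec.sequence) if 6 <= len(p) <= 30]
        contaminant_peps.extend(peps[:2])
    for pep in contaminant_peps:
        level = rng.uniform(7.0, 8.5)
        for p in range(config.n_patients):
            for cond in config.conditions:
                for rep in range(1, config.ms_replicates + 1):
                    eps = rng.normal(0.0, noise10)
                    rows.append((pep, p + 1, cond, rep, float(10.0 ** (level + eps))))

    return pd.DataFrame(
        rows, columns=["peptide", "patient", "condition", "replicate", "intensity"]
    )


def generate_array_data(
    truth: SimTruth, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level linear-intensity matrix and probe->gene map.

    Every gene in the truth gets 1-5 probes (fixed affinity offsets),
    plus ``n_below_threshold_genes`` extra genes planted well under the
    log2 = 5 detection threshold and ``n_background_genes`` null
    non-secreted genes emulating the rest of the transcriptome an array
    measures — quantile normalization is only well-behaved when regulated
    genes are a small minority of all probes.  Values are emitted on the
    linear scale (2**log2), as the processing pipeline expects pre-log data.

    For genes whose protein is in the truth, base expression is an affine
    map of the protein's base log10 abundance plus scatter, planting the
    positive protein-transcript correlation seen in real secretome data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    base10_of_gene = {
        truth.gene_of[acc]: truth.base_log10[acc] for acc in truth.base_log10
    }
    genes = [g for g in truth.gene_category if not g.startswith(("LOWG", "BGG"))]
    for i in range(config.n_below_threshold_genes):
        g = f"LOWG{i + 1}"
        genes.append(g)
        truth.gene_category.setdefault(g, INTRACELLULAR)
        truth.log2fc.setdefault(g, {c: 0.0 for c in config.conditions})
        if g not in truth.below_threshold_genes:
            truth.below_threshold_genes.append(g)
    for i in range(config.n_background_genes):
        g = f"BGG{i + 1}"
        genes.append(g)
        truth.gene_category.setdefault(g, INTRACELLULAR)
        truth.log2fc.setdefault(g, {c: 0.0 for c in config.conditions})

    cols = sample_columns(config)
    lo, hi = config.base_log2_range
    probe_rows: dict[str, np.ndarray] = {}
    probe_map_rows = []
    probe_no = 0
    p_lo, p_hi = config.base_log10_range
    for g in genes:
        below = g in truth.below_threshold_genes
        if below:
            base = rng.uniform(2.0, 4.0)
        elif g.startswith("BGG"):
            # background transcriptome spans the array's full dynamic range
            base = rng.uniform(3.0, 14.0)
        elif g in base10_of_gene:
            rel = (base10_of_gene[g] - p_lo) / (p_hi - p_lo)
            base = lo + rel * (hi - lo) + rng.normal(0.0, 0.6)
        else:
            base = rng.uniform(lo, hi)
        fc = truth.log2fc[g]
        u_patient = rng.normal(0.0, config.patient_sd, size=config.n_patients)
        n_probes = int(rng.integers(config.probes_per_gene[0], config.probes_per_gene[1] + 1))
        offsets = rng.normal(0.0, config.probe_offset_sd, size=n_probes)
        gene_signal = np.array(
            [
                base + fc[c] * (0.0 if below else 1.0) + u_patient[p]
                for p in range(config.n_patients)
                for c in config.conditions
            ]
        )
        for k in range(n_probes):
            probe_no += 1
            probe_id = f"PS{probe_no:05d}_at"
            eps = rng.normal(0.0, config.noise_sd, size=len(cols))
            probe_rows[probe_id] = 2.0 ** (gene_signal + offsets[k] + eps)
            probe_map_rows.append({"probe_id": probe_id, "gene_symbol": g})

    probe_matrix = pd.DataFrame.from_dict(probe_rows, orient="index", columns=cols)
    probe_matrix.index.name = "probe_id"
    probe_map = pd.DataFrame(probe_map_rows)
    return probe_matrix, probe_map


def generate_qpcr_table(truth: SimTruth, config: SimConfig, seed: int) -> pd.DataFrame:
    """TaqMan-style Ct table for cytokine and collagen genes plus the
    housekeeping reference.

    Ct model: ``Ct = offset_gene - (log2FC + patient effect + noise)``, so
    every planted doubling of expression lowers Ct by one cycle; the
    housekeeping gene has zero fold change in every condition.
    """
    hk = truth.housekeeping_gene
    if hk not in truth.gene_category or any(
        truth.log2fc[hk][c] != 0.0 for c in config.conditions
    ):
        raise ValueError("truth must include a null housekeeping gene")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    targets = [
        g
        for g, cat in truth.gene_category.items()
        if cat in (CYTOKINE, COLLAGEN) and g not in truth.below_threshold_genes
    ]
    rows = []
    hk_base = 20.0
    for g in targets:
        ct_base = float(rng.uniform(22.0, 30.0))
        u_patient = rng.normal(0.0, config.patient_sd, size=config.n_patients)
        for p in range(config.n_patients):
            for cond in config.conditions:
                ct = ct_base - (truth.log2fc[g][cond] + u_patient[p]) + rng.normal(
                    0.0, config.noise_sd
                )
                ct_hk = hk_base + rng.normal(0.0, config.noise_sd)
                rows.append(
                    {
                        "patient": p + 1,
                        "condition": cond,
                        "gene": g,
                        "ct": ct,
                        "ct_housekeeping": ct_hk,
                    }
                )
    return pd.DataFrame(rows)


def simulate_all(config: SimConfig, seed: int, outdir: str | Path | None = None):
    """Run every generator off one master seed; optionally write all files.

    Returns a dict with keys cell_db, serum_db, annotation, truth,
    peptide_table, probe_matrix, probe_map, qpcr_table.
    """
    cell, serum, annotation, truth = generate_protein_database(config, seed)
    peptides = generate_ms_peptide_table(cell, serum, truth, config, seed)
    probe_matrix, probe_map = generate_array_data(truth, config, seed)
    qpcr = generate_qpcr_table(truth, config, seed)
    bundle = {
        "cell_db": cell,
        "serum_db": serum,
        "annotation": annotation,
        "truth": truth,
        "peptide_table": peptides,
        "probe_matrix": probe_matrix,
        "probe_map": probe_map,
        "qpcr_table": qpcr,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(cell, out / "cell_db.fasta")
        write_fasta(serum, out / "serum_db.fasta")
        write_annotation_table(cell, out / "annotation.tsv")
        peptides.to_csv(out / "peptides.tsv", sep="\t", index=False)
        probe_matrix.to_csv(out / "probe_matrix.tsv", sep="\t")
        probe_map.to_csv(out / "probe_map.tsv", sep="\t", index=False)
        qpcr.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
        truth.to_json(out / "truth.json")
        (out / "sim_config.json").write_text(
            json.dumps({"seed": seed, **config_to_dict(config)}, indent=1, sort_keys=True)
        )
    return bundle
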