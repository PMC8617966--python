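"""The synthetic-data generator: determinism, planted truth, consistency."""

import re

import numpy as np
import pandas as pd
import pytest

from cfsecretome import SimConfig, simulate_all
from cfsecretome.config import DropoutConfig, TNFA, TGFB, CONTROL
from cfsecretome.digestion import build_shared_peptide_set, digest_tryptic
from cfsecretome.pipeline import process_arrays
from cfsecretome.records import sequences_by_accession
from cfsecretome.simulate import generate_protein_database

from conftest import small_sizes


def test_seeded_determinism_is_byte_identical(tmp_path):
    cfg = SimConfig(n_proteins=small_sizes())
    for sub in ("a", "b"):
        simulate_all(cfg, seed=9, outdir=tmp_path / sub)
    for name in (
        "cell_db.fasta",
        "serum_db.fasta",
        "annotation.tsv",
        "peptides.tsv",
        "probe_matrix.tsv",
        "probe_map.tsv",
        "qpcr_ct.tsv",
        "truth.json",
    ):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_different_seeds_differ():
    cfg = SimConfig(n_proteins=small_sizes())
    a = simulate_all(cfg, seed=1)["peptide_table"]
    b = simulate_all(cfg, seed=2)["peptide_table"]
    assert not a.equals(b)


def test_collagen_symbol_count_matches_request():
    cfg = SimConfig(n_proteins={**small_sizes(), "collagen": 30})
    _, _, annotation, _ = generate_protein_database(cfg, seed=3)
    pattern = re.compile(r"^COL\d+A\d+$")
    n_collagen = annotation["gene_symbol"].str.match(pattern).sum()
    assert n_collagen == 30
    # and no other category's symbols accidentally match the pattern
    assert (
        annotation.loc[annotation["gene_symbol"].str.match(pattern)].shape[0] == 30
    )


def test_sequences_use_canonical_alphabet(default_bundle):
    canonical = set("ACDEFGHIKLMNPQRSTVWY")
    for rec in default_bundle["cell_db"] + default_bundle["serum_db"]:
        assert set(rec.sequence) <= canonical


def test_shared_fraction_zero_gives_empty_shared_set():
    cfg = SimConfig(n_proteins=small_sizes(), shared_fraction=0.0)
    cell, serum, _, truth = generate_protein_database(cfg, seed=4)
    assert truth.shared_peptides == []
    shared = build_shared_peptide_set(
        sequences_by_accession(cell), sequences_by_accession(serum)
    )
    assert shared == set()


def test_planted_homologs_share_exactly_the_planted_peptides(default_bundle):
    cell = sequences_by_accession(default_bundle["cell_db"])
    serum = sequences_by_accession(default_bundle["serum_db"])
    shared = build_shared_peptide_set(cell, serum)
    assert set(default_bundle["truth"].shared_peptides) <= shared


def test_noiseless_peptides_identical_across_patients(noiseless_bundle):
    """With dropout off and all SDs zero, a peptide's intensity is the same
    in every patient within a condition (pairing structure degenerates)."""
    table = noiseless_bundle["peptide_table"]
    truth = noiseless_bundle["truth"]
    cell_peps = {
        p
        for rec in noiseless_bundle["cell_db"]
        for p in digest_tryptic(rec.sequence)
    } - set(truth.shared_peptides)
    own = table[table["peptide"].isin(cell_peps)]
    spread = own.groupby(["peptide", "condition"])["intensity"].nunique()
    assert (spread == 1).all()


def test_noiseless_planted_effect_is_exact(noiseless_bundle):
    """Cytokine peptides under TNF-alpha sit exactly 1.5 log2 units above
    control; collagen peptides under TGF-beta exactly 1.0."""
    table = noiseless_bundle["peptide_table"]
    truth = noiseless_bundle["truth"]
    cfg_effects = {(TNFA, "cytokine"): 1.5, (TGFB, "collagen"): 1.0}
    pep_owner = {}
    for rec in noiseless_bundle["cell_db"]:
        for p in digest_tryptic(rec.sequence):
            pep_owner.setdefault(p, rec.accession)
    for (cond, category), planted in cfg_effects.items():
        accs = {a for a, c in truth.category.items() if c == category}
        peps = {p for p, a in pep_owner.items() if a in accs} - set(truth.shared_peptides)
        sub = table[table["peptide"].isin(peps)]
        mean_log2 = sub.groupby("condition")["intensity"].apply(
            lambda s: np.log2(s).mean()
        )
        assert mean_log2[cond] - mean_log2[CONTROL] == pytest.approx(planted, abs=1e-9)


def test_noiseless_probes_differ_by_constant_offsets(noiseless_bundle):
    probes = noiseless_bundle["probe_matrix"]
    probe_map = noiseless_bundle["probe_map"]
    log2 = np.log2(probes)
    for gene, grp in probe_map.groupby("gene_symbol"):
        rows = log2.loc[grp["probe_id"]]
        if len(rows) < 2:
            continue
        offsets = rows - rows.iloc[0]
        # each probe's offset from the first probe is constant across samples
        assert float(offsets.std(axis=1).max()) == pytest.approx(0.0, abs=1e-9)


def test_below_threshold_genes_are_filtered_downstream(default_bundle):
    gene_matrix = process_arrays(
        default_bundle["probe_matrix"], default_bundle["probe_map"]
    )
    low = set(default_bundle["truth"].below_threshold_genes)
    assert low  # generator planted some
    assert low.isdisjoint(set(gene_matrix.data.index))


def test_every_probe_maps_to_exactly_one_gene(default_bundle):
    probe_map = default_bundle["probe_map"]
    assert probe_map["probe_id"].is_unique
    assert set(default_bundle["probe_matrix"].index) == set(probe_map["probe_id"])


def test_every_cell_peptide_maps_to_a_protein(default_bundle):
    """Internal consistency: every non-contaminant MS peptide occurs in at
    least one emitted cell protein."""
    all_cell_peps = {
        p for rec in default_bundle["cell_db"] for p in digest_tryptic(rec.sequence)
    }
    serum_peps = {
        p for rec in default_bundle["serum_db"] for p in digest_tryptic(rec.sequence)
    }
    observed = set(default_bundle["peptide_table"]["peptide"])
    assert observed <= all_cell_peps | serum_peps


def test_qpcr_noiseless_ct_shift_equals_planted_fold_change(noiseless_bundle):
    ct = noiseless_bundle["qpcr_table"]
    truth = noiseless_bundle["truth"]
    wide = ct.pivot_table(index="gene", columns="condition", values="ct")
    for gene in wide.index:
        for cond in (TNFA, TGFB):
            planted = truth.log2fc[gene][cond]
            # one planted doubling lowers Ct by exactly one cycle
            assert wide.loc[gene, CONTROL] - wide.loc[gene, cond] == pytest.approx(
                planted, abs=1e-9
            )
    # housekeeping Ct is condition-independent
    assert (ct["ct_housekeeping"] == 20.0).all()


def test_qpcr_housekeeping_fold_change_is_null(default_bundle):
    """Mean 2^-dCt ratio of a null gene is ~1 (housekeeping behaviour)."""
    from cfsecretome.transcriptomics import qpcr_relative_expression

    ct = default_bundle["qpcr_table"]
    truth = default_bundle["truth"]
    null_genes = [
        g
        for g in ct["gene"].unique()
        if truth.log2fc[g][TNFA] == 0.0
    ]
    expr = qpcr_relative_expression(ct[ct["gene"].isin(null_genes)])
    wide = expr.pivot_table(
        index=["gene", "patient"], columns="condition", values="relative_expression"
    )
    log_ratio = np.log2(wide[TNFA] / wide[CONTROL])
    assert abs(log_ratio.mean()) < 0.5


def test_config_validation_rejects_bad_designs():
    with pytest.raises(ValueError):
        SimConfig(n_patients=1)
    with pytest.raises(ValueError):
        SimConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        SimConfig(conditions=("TNFA", "TGFB"))
    with pytest.raises(ValueError):
        SimConfig(probes_per_gene=(0, 3))
    with pytest.raises(ValueError):
        # effect planted on a category with zero proteins
        SimConfig(n_proteins={**small_sizes(), "cytokine": 0})


def test_dropout_probability_is_monotone_in_abundance():
    d = DropoutConfig(enabled=True, midpoint_log10=5.0, scale=0.5)
    p = d.detect_probability(np.array([3.0, 5.0, 7.0]))
    assert p[0] < p[1] < p[2]
    assert p[1] == pytest.approx(0.5)
    off = DropoutConfig(enabled=False)
    assert (off.detect_probability(np.array([3.0, 9.0])) == 1.0).all()
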