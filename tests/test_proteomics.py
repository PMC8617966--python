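"""Protein quantification: exclusion rules, normalization, iBAQ, testing."""

import numpy as np
import pandas as pd
import pytest

from cfsecretome.proteomics import (
    ProteinQuantMatrix,
    compute_ibaq,
    define_extracellular_proteome,
    differential_secretion,
    normalize_log10_median,
    quantify_proteins,
)
from cfsecretome.records import ProteinRecord


def _peptide_rows(rows):
    return pd.DataFrame(rows, columns=["peptide", "patient", "condition", "intensity"])


# two proteins sharing no peptides; P2 also owns the ambiguous peptide of P1?
SEQ_A = "GGGGGGKAAAAAAR"  # peptides GGGGGGK, AAAAAAR
SEQ_B = "TTTTTTKCCCCCCR"  # peptides TTTTTTK, CCCCCCR
DB = [
    ProteinRecord("A", "GENEA", "cell", SEQ_A),
    ProteinRecord("B", "GENEB", "cell", SEQ_B),
]


def test_quantify_sums_peptides_per_protein():
    table = _peptide_rows(
        [
            ("GGGGGGK", 1, "control", 100.0),
            ("AAAAAAR", 1, "control", 300.0),
            ("TTTTTTK", 1, "control", 50.0),
        ]
    )
    matrix = quantify_proteins(table, DB, shared_set=set())
    assert matrix.raw.loc["A", "P1_control"] == 400.0
    assert matrix.raw.loc["B", "P1_control"] == 50.0


def test_shared_peptides_contribute_nothing():
    table = _peptide_rows(
        [
            ("GGGGGGK", 1, "control", 100.0),
            ("AAAAAAR", 1, "control", 1e12),  # huge serum-shared signal
        ]
    )
    matrix = quantify_proteins(table, DB, shared_set={"AAAAAAR"})
    assert matrix.raw.loc["A", "P1_control"] == 100.0


def test_ambiguous_peptides_contribute_to_neither():
    db = DB + [ProteinRecord("A2", "GENEA2", "cell", "GGGGGGKDDDDDDR")]
    table = _peptide_rows(
        [
            ("GGGGGGK", 1, "control", 500.0),  # in A and A2
            ("AAAAAAR", 1, "control", 100.0),  # unique to A
        ]
    )
    matrix = quantify_proteins(table, db, shared_set=set())
    assert matrix.raw.loc["A", "P1_control"] == 100.0
    assert "A2" not in matrix.raw.index  # no surviving peptide -> absent


def test_unmatched_peptides_are_dropped_with_warning(caplog):
    table = _peptide_rows(
        [("GGGGGGK", 1, "control", 10.0), ("WWWWWWK", 1, "control", 10.0)]
    )
    import logging

    logging.disable(logging.NOTSET)
    with caplog.at_level("WARNING", logger="cfsecretome.proteomics"):
        matrix = quantify_proteins(table, DB, shared_set=set())
    logging.disable(logging.WARNING)
    assert matrix.dropped_peptides["unmatched"] == 1
    assert any("matched no cell-database protein" in r.message for r in caplog.records)


def _matrix(raw_dict, columns):
    raw = pd.DataFrame(raw_dict, index=columns).T
    return ProteinQuantMatrix(raw=raw)


def test_extracellular_proteome_requires_every_patient():
    cols = ["P1_control", "P2_control", "P1_TNFA", "P2_TNFA"]
    m = _matrix(
        {
            "all_patients": [10.0, 20.0, 5.0, 5.0],
            "one_missing": [10.0, 0.0, 5.0, 5.0],
            "only_treated": [0.0, 0.0, 5.0, 5.0],
        },
        cols,
    )
    assert define_extracellular_proteome(m) == {"all_patients"}


def test_extracellular_proteome_needs_control_samples():
    m = _matrix({"x": [1.0, 1.0]}, ["P1_TNFA", "P2_TNFA"])
    with pytest.raises(ValueError):
        define_extracellular_proteome(m)


def test_normalization_single_sample_is_identity():
    m = _matrix({"a": [10.0], "b": [100.0], "c": [1000.0]}, ["P1_control"])
    normalize_log10_median(m)
    assert list(m.normalized["P1_control"]) == pytest.approx([1.0, 2.0, 3.0])


def test_normalization_shifts_to_global_median_of_medians():
    # per-sample log10 medians 2 and 3 -> global target 2.5 -> shifts +-0.5
    cols = ["P1_control", "P2_control"]
    m = _matrix(
        {"a": [10.0, 100.0], "b": [100.0, 1000.0], "c": [1000.0, 10000.0]}, cols
    )
    normalize_log10_median(m)
    assert m.normalized["P1_control"].median() == pytest.approx(2.5)
    assert m.normalized["P2_control"].median() == pytest.approx(2.5)
    assert list(m.normalized["P1_control"]) == pytest.approx([1.5, 2.5, 3.5])


def test_normalization_cancels_per_sample_scaling():
    """Scaling one sample's raw intensities x10 does not change the
    normalized layer (as long as the global median of per-sample medians
    is carried by another sample)."""
    cols = ["P1_control", "P2_control", "P3_control"]
    base = {
        "a": [10.0, 20.0, 40.0],
        "b": [100.0, 200.0, 400.0],
        "c": [1000.0, 900.0, 4000.0],
    }
    m1 = _matrix(base, cols)
    scaled = {k: [v[0], v[1], v[2] * 10.0] for k, v in base.items()}
    m2 = _matrix(scaled, cols)
    normalize_log10_median(m1)
    normalize_log10_median(m2)
    pd.testing.assert_frame_equal(m1.normalized, m2.normalized)


def test_normalization_keeps_zeros_missing():
    cols = ["P1_control", "P2_control"]
    m = _matrix({"a": [10.0, 0.0], "b": [100.0, 50.0], "c": [20.0, 70.0]}, cols)
    normalize_log10_median(m)
    assert np.isnan(m.normalized.loc["a", "P2_control"])


def test_ibaq_formula_and_scale_equivariance():
    cols = ["P1_control"]
    m = _matrix({"A": [1_000_000.0], "B": [300.0]}, cols)
    counts_db = [
        ProteinRecord("A", "GENEA", "cell", "GGGGGGK" * 4),  # 4 theoretical peptides
        ProteinRecord("B", "GENEB", "cell", SEQ_B),  # 2
    ]
    compute_ibaq(m, counts_db)
    assert m.ibaq.loc["A", "P1_control"] == pytest.approx(250_000.0)
    assert m.ibaq.loc["B", "P1_control"] == pytest.approx(150.0)

    m2 = _matrix({"A": [3_000_000.0], "B": [900.0]}, cols)
    compute_ibaq(m2, counts_db)
    pd.testing.assert_frame_equal(m2.ibaq, m.ibaq * 3.0)


def test_ibaq_undefined_without_theoretical_peptides():
    cols = ["P1_control"]
    m = _matrix({"S": [100.0]}, cols)
    short_db = [ProteinRecord("S", "GENES", "cell", "AK")]  # no in-bounds peptides
    compute_ibaq(m, short_db)
    assert np.isnan(m.ibaq.loc["S", "P1_control"])
    assert m.peptide_counts["S"] == 0


def test_differential_secretion_recovers_planted_direction():
    rng = np.random.default_rng(0)
    cols = [f"P{p}_{c}" for p in range(1, 5) for c in ("control", "TNFA")]
    raw = {}
    for i in range(20):
        base = rng.uniform(5, 7)
        vals = []
        for p in range(4):
            ctrl = base + rng.normal(0, 0.05)
            up = 0.6 if i < 5 else 0.0  # first 5 proteins planted up (log10)
            vals += [10.0 ** ctrl, 10.0 ** (ctrl + up)]
        raw[f"prot{i:02d}"] = vals
    m = _matrix(raw, cols)
    normalize_log10_median(m)
    results = differential_secretion(m, "TNFA")
    by_feature = {r.feature: r for r in results}
    assert all(by_feature[f"prot{i:02d}"].direction == "up" for i in range(5))
    assert all(np.isfinite(r.p) for r in results)


def test_differential_identical_matrix_has_no_hits():
    cols = [f"P{p}_{c}" for p in range(1, 5) for c in ("control", "TNFA")]
    m = _matrix({f"x{i}": [100.0 + i] * 8 for i in range(5)}, cols)
    normalize_log10_median(m)
    results = differential_secretion(m, "TNFA")
    assert all(r.direction == "ns" for r in results)


def test_median_normalization_invariant_p_values():
    """Per-sample multiplicative raw scaling leaves paired p-values unchanged."""
    rng = np.random.default_rng(5)
    cols = [f"P{p}_{c}" for p in range(1, 5) for c in ("control", "TGFB")]
    raw = {f"y{i}": 10.0 ** rng.uniform(4, 7, size=8) for i in range(12)}
    m1 = _matrix(raw, cols)
    scale = 10.0 ** rng.uniform(-1, 1, size=8)
    m2 = ProteinQuantMatrix(raw=m1.raw * scale)
    for m in (m1, m2):
        normalize_log10_median(m)
    p1 = [r.p for r in differential_secretion(m1, "TGFB")]
    p2 = [r.p for r in differential_secretion(m2, "TGFB")]
    assert p1 == pytest.approx(p2, abs=1e-9)
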