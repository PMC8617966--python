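"""Compositional fractions, category comparisons, correlation."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from cfsecretome.annotation import CategoryAssignment
from cfsecretome.composition import (
    ECM_LEVEL,
    PROTEOME_LEVEL,
    SECRETOME_LEVEL,
    category_sum_comparison,
    check_nested_consistency,
    composition_fractions,
    protein_transcript_correlation,
    spearman_correlation,
    transcript_composition,
)


def _assignment(acc, gene, loc="secreted", tags=()):
    return CategoryAssignment(acc, gene, loc, frozenset(tags))


def _ibaq_one_sample(values):
    return pd.DataFrame({"P1_control": values})


def test_fractions_simple_normalization():
    ibaq = _ibaq_one_sample({"a": 50.0, "b": 30.0, "c": 20.0})
    assignments = {
        "a": _assignment("a", "GA", tags={"cytokine"}),
        "b": _assignment("b", "GB", tags={"ECM"}),
        "c": _assignment("c", "GC", tags={"other_secreted"}),
    }
    rep = composition_fractions(ibaq, assignments, SECRETOME_LEVEL)
    assert rep.fractions == pytest.approx(
        {"cytokine": 0.5, "ECM": 0.3, "other_secreted": 0.2}
    )
    assert sum(rep.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_fraction_of_single_protein_is_one():
    ibaq = _ibaq_one_sample({"only": 123.0})
    assignments = {"only": _assignment("only", "G", tags={"cytokine"})}
    rep = composition_fractions(ibaq, assignments, SECRETOME_LEVEL)
    assert rep.fractions == {"cytokine": 1.0}


def test_zero_denominator_raises():
    ibaq = _ibaq_one_sample({"a": 0.0})
    assignments = {"a": _assignment("a", "GA", tags={"cytokine"})}
    with pytest.raises(ValueError):
        composition_fractions(ibaq, assignments, SECRETOME_LEVEL)


def test_undefined_ibaq_raises():
    ibaq = _ibaq_one_sample({"a": np.nan, "b": 1.0})
    assignments = {
        "a": _assignment("a", "GA", tags={"cytokine"}),
        "b": _assignment("b", "GB", tags={"ECM"}),
    }
    with pytest.raises(ValueError):
        composition_fractions(ibaq, assignments, SECRETOME_LEVEL)


def _nested_fixture():
    """Secretome totalling 100: fibronectin 17, collagens 6, MMPs/TIMPs 5
    (ECM = 58 with other ECM 30), cytokines 5, other secreted 37."""
    ibaq = _ibaq_one_sample(
        {"fn1": 17.0, "col": 6.0, "mmp": 5.0, "ecm": 30.0, "cyt": 5.0, "oth": 37.0}
    )
    assignments = {
        "fn1": _assignment("fn1", "FN1", tags={"ECM", "fibronectin"}),
        "col": _assignment("col", "COL1A1", tags={"ECM", "collagen"}),
        "mmp": _assignment("mmp", "TIMP1", tags={"ECM", "MMP/TIMP"}),
        "ecm": _assignment("ecm", "SPARC", tags={"ECM"}),
        "cyt": _assignment("cyt", "IL6", tags={"cytokine"}),
        "oth": _assignment("oth", "IGFBP3", tags={"other_secreted"}),
    }
    return ibaq, assignments


def test_nested_fractions_are_consistent():
    ibaq, assignments = _nested_fixture()
    secretome = composition_fractions(ibaq, assignments, SECRETOME_LEVEL)
    ecm = composition_fractions(ibaq, assignments, ECM_LEVEL)
    assert secretome.fractions["ECM"] == pytest.approx(0.58)
    # 17% of secretome with ECM at 58% -> 29% of the ECM fraction
    assert ecm.as_percent()["fibronectin"] == 29
    # collagens + MMPs/TIMPs: 11% of secretome -> 19% of ECM
    assert round(100 * (ecm.fractions["collagen"] + ecm.fractions["MMP/TIMP"])) == 19
    assert check_nested_consistency(secretome, ecm, "ECM") < 1e-9


def test_fractions_invariant_to_global_scaling():
    ibaq, assignments = _nested_fixture()
    rep1 = composition_fractions(ibaq, assignments, SECRETOME_LEVEL)
    rep2 = composition_fractions(ibaq * 7.3, assignments, SECRETOME_LEVEL)
    assert rep1.fractions == pytest.approx(rep2.fractions, abs=1e-12)


def test_proteome_level_uses_localization():
    ibaq = _ibaq_one_sample({"s": 72.0, "m": 20.0, "e": 7.0, "o": 1.0})
    assignments = {
        "s": _assignment("s", "GS", "secreted", {"other_secreted"}),
        "m": _assignment("m", "GM", "membrane"),
        "e": _assignment("e", "GE", "endoplasmic_reticulum"),
        "o": _assignment("o", "GO", "other"),
    }
    rep = composition_fractions(ibaq, assignments, PROTEOME_LEVEL)
    assert rep.fractions["secreted"] == pytest.approx(0.72)


def test_transcript_composition_linear_shares():
    cols = ["P1_control", "P1_TNFA"]
    gene_log2 = pd.DataFrame(
        {"P1_control": [np.log2(90.0), np.log2(10.0)], "P1_TNFA": [1.0, 1.0]},
        index=["cyto_gene", "ecm_gene"],
    )
    ga = {
        "cyto_gene": _assignment("cyto_gene", "cyto_gene", tags={"cytokine"}),
        "ecm_gene": _assignment("ecm_gene", "ecm_gene", tags={"ECM"}),
    }
    rep = transcript_composition(gene_log2, ga)
    assert rep.fractions["cytokine"] == pytest.approx(0.9)
    assert rep.fractions["ECM"] == pytest.approx(0.1)
    assert rep.fractions["other_secreted"] == 0.0  # empty category reported as 0


def test_category_sums_with_copied_conditions_are_ns():
    cols = ["P1_control", "P2_control", "P3_control", "P1_TNFA", "P2_TNFA", "P3_TNFA"]
    linear = pd.DataFrame(
        {c: [100.0, 50.0] for c in cols}, index=["a", "b"]
    )
    res = category_sum_comparison(linear, {"a": "cytokine", "b": "cytokine"}, "TNFA")
    assert len(res) == 1
    assert res[0].direction == "ns" and res[0].log2fc == 0.0


def test_category_sums_recover_planted_effects(default_bundle):
    """TGF-beta raises summed collagen secretion; TNF-alpha raises summed
    cytokine secretion (protein level, planted effects)."""
    from cfsecretome.pipeline import run_pipeline

    res = run_pipeline(default_bundle)
    tgfb = {r.feature: r for r in res.category_protein_diff["TGFB"]}
    tnfa = {r.feature: r for r in res.category_protein_diff["TNFA"]}
    assert tgfb["collagen"].direction == "up"
    assert tnfa["cytokine"].direction == "up"
    assert tgfb["collagen"].log2fc == pytest.approx(1.0, abs=0.5)
    assert tnfa["cytokine"].log2fc == pytest.approx(1.5, abs=0.5)


def test_spearman_monotone_extremes():
    rho, p, n = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert rho == pytest.approx(1.0)
    rho_rev, _, _ = spearman_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert rho_rev == pytest.approx(-1.0)


def test_spearman_exact_p_matches_brute_force_oracle():
    """n = 5: the two-sided p equals the fraction of the 5! rank
    arrangements with |rho| >= observed, computed from first principles."""
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.1, 1.0, 3.3, 5.0, 4.2]
    rho, p, n = spearman_correlation(x, y)

    def rank(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0] * len(v)
        for pos, i in enumerate(order):
            r[i] = pos + 1
        return r

    def rho_of(rx, ry):
        n = len(rx)
        d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
        return 1 - 6 * d2 / (n * (n**2 - 1))

    rx, ry = rank(x), rank(y)
    rho_ref = rho_of(rx, ry)
    hits = sum(
        abs(rho_of(rx, perm)) >= abs(rho_ref) - 1e-12 for perm in permutations(ry)
    )
    assert rho == pytest.approx(rho_ref, abs=1e-12)
    assert p == pytest.approx(hits / 120.0, abs=1e-12)


def test_correlation_untestable_below_three_matches():
    s1 = pd.Series([1.0, 2.0], index=["a", "b"])
    s2 = pd.Series([1.0, 2.0], index=["a", "b"])
    rho, p, n = protein_transcript_correlation(s1, s2)
    assert n == 2 and np.isnan(rho) and np.isnan(p)
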