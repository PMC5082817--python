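"""Probe preprocessing, contrast fitting, BH and signature construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import small_config
from oracles import bh_stepup

from eggstim.datatypes import ContrastSpec
from eggstim.diffexpr import (
    benjamini_hochberg,
    collapse_probes_to_genes,
    filter_probes_by_detection,
    fit_contrast,
    standardize_signature,
)
from eggstim.synthetic import generate_expression


# ---------------------------------------------------------------- BH

def test_bh_known_values():
    assert benjamini_hochberg([0.01]) == pytest.approx([0.01])
    assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_monotone_and_matches_oracle():
    rng = np.random.default_rng(42)
    for _ in range(50):
        p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 200))
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, bh_stepup(p), rtol=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


def test_bh_rejects_out_of_range_and_passes_empty():
    assert len(benjamini_hochberg([])) == 0
    with pytest.raises(ValueError):
        benjamini_hochberg([0.0, 0.5])
    with pytest.raises(ValueError):
        benjamini_hochberg([1.5])


# ---------------------------------------------------- probe handling

def _probe_matrix(n_probes=5, n_samples=10):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(8, 1, (n_probes, n_samples)),
        index=[f"P{i}" for i in range(n_probes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


def test_detection_filter_boundary_and_extremes():
    pm = _probe_matrix()
    det = pd.DataFrame(True, index=pm.index, columns=pm.columns)
    det.loc["P0"] = False                      # 0/10 -> removed
    det.loc["P1"] = [True, True] + [False] * 8  # exactly 20% -> retained
    det.loc["P2"] = [True] + [False] * 9        # 10% -> removed
    out = filter_probes_by_detection(pm, det)
    assert set(out.index) == {"P1", "P3", "P4"}
    # all-detected is the identity
    all_det = pd.DataFrame(True, index=pm.index, columns=pm.columns)
    pd.testing.assert_frame_equal(filter_probes_by_detection(pm, all_det), pm)


def test_detection_filter_rejects_nonconformal():
    pm = _probe_matrix()
    with pytest.raises(ValueError):
        filter_probes_by_detection(pm, pd.DataFrame(True, index=pm.index[:3],
                                                    columns=pm.columns))


def test_collapse_keeps_highest_mean_probe():
    pm = pd.DataFrame(
        {"S0": [5.0, 7.2, 3.0, 4.0], "S1": [5.0, 7.2, 3.0, 4.0]},
        index=["PA", "PB", "PC", "PX"],
    )
    out = collapse_probes_to_genes(pm, {"PA": "G1", "PB": "G1", "PC": "G2"})
    assert list(out.index) == ["G1", "G2"]
    assert out.loc["G1", "S0"] == 7.2  # max-mean probe wins; PX unmapped, dropped
    # tie in means -> lexicographically smallest probe id
    tie = pd.DataFrame({"S0": [1.0, 1.0]}, index=["PZ", "PA"])
    out = collapse_probes_to_genes(tie, {"PZ": "G", "PA": "G"})
    assert out.loc["G", "S0"] == tie.loc["PA", "S0"]
    assert len(out) == 1


# ------------------------------------------------------ fit_contrast

def _toy_delta_design():
    """8 subjects (4 BER with delta 1, 4 AC with delta 0), no covariate
    variation."""
    rows, data = [], {}
    for i, (grp, delta) in enumerate([("BER", 1.0)] * 4 + [("AC", 0.0)] * 4):
        subj = f"{grp}{i}"
        for stim, val in (("EW", 5.0 + delta), ("M", 5.0)):
            sid = f"{subj}_{stim}"
            rows.append({"sample_id": sid, "subject_id": subj, "group": grp,
                         "stimulation": stim, "gender": "F", "batch": "B0"})
            data[sid] = [val]
    expr = pd.DataFrame(data, index=["G1"])
    return expr, pd.DataFrame(rows)


def test_difference_of_differences_exact_means():
    expr, samples = _toy_delta_design()
    deg = fit_contrast(expr, samples,
                       ContrastSpec("difference_of_differences", "BER", "AC"))
    assert deg.loc[0, "log2FC"] == pytest.approx(1.0)


def test_within_group_matches_paired_t_test():
    rng = np.random.default_rng(8)
    rows, data = [], {}
    n = 10
    ew_vals = rng.normal(6.0, 1.0, n)
    m_vals = rng.normal(5.0, 1.0, n)
    for i in range(n):
        subj = f"BER{i}"
        for stim, val in (("EW", ew_vals[i]), ("M", m_vals[i])):
            sid = f"{subj}_{stim}"
            rows.append({"sample_id": sid, "subject_id": subj, "group": "BER",
                         "stimulation": stim, "gender": "F", "batch": "B0"})
            data[sid] = [val]
    expr = pd.DataFrame(data, index=["G1"])
    deg = fit_contrast(expr, pd.DataFrame(rows),
                       ContrastSpec("within_group_EW_vs_M", "BER"))
    t_ref = stats.ttest_rel(ew_vals, m_vals)
    assert deg.loc[0, "p_value"] == pytest.approx(t_ref.pvalue, rel=1e-10)
    assert deg.loc[0, "log2FC"] == pytest.approx((ew_vals - m_vals).mean())


def test_aliased_covariate_dropped_with_warning(caplog):
    expr, samples = _toy_delta_design()
    samples = samples.copy()
    # batch perfectly tracks group -> aliased with the contrast column
    samples["batch"] = np.where(samples["group"] == "BER", "B1", "B0")
    with caplog.at_level("WARNING"):
        deg = fit_contrast(expr, samples,
                           ContrastSpec("difference_of_differences", "BER", "AC"))
    assert "aliased" in caplog.text
    assert deg.loc[0, "log2FC"] == pytest.approx(1.0)


def test_between_group_contrast_recovers_planted_condition_difference():
    cfg = small_config(seed=13, de_log2fc=1.5)
    expr, samples, truth = generate_expression(cfg)
    deg = fit_contrast(expr, samples,
                       ContrastSpec("between_group_within_condition", "BER", "AC", "EW"))
    planted = set(truth.de_gene_ids["EWvsM@BER"])
    hits = deg[deg["gene_id"].isin(planted)]
    # planted genes are shifted only in EW samples of BER/BET, so the
    # BER-vs-AC@EW contrast sees the full effect
    assert hits["log2FC"].mean() == pytest.approx(1.5, abs=0.3)
    assert deg["fdr_p"].ge(deg["p_value"]).all()


def test_type_i_error_calibrated_on_null():
    fractions = []
    for seed in range(1, 11):
        cfg = small_config(seed=seed, de_log2fc=0.0, n_genes=2000)
        expr, samples, _ = generate_expression(cfg)
        deg = fit_contrast(expr, samples,
                           ContrastSpec("difference_of_differences", "BER", "AC"))
        fractions.append((deg["p_value"] < 0.05).mean())
    assert 0.03 <= np.mean(fractions) <= 0.07
    assert all(0.02 <= f <= 0.08 for f in fractions)


# ------------------------------------------------ signature building

def _deg_table(n, rng):
    fc = rng.normal(0, 2, n)
    return pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(n)],
        "log2FC": fc,
        "ave_expr": 8.0,
        "p_value": rng.uniform(1e-8, 1, n),
        "fdr_p": 1.0,
        "contrast_id": "toy",
    })


def test_signature_standard_size_and_truncation():
    rng = np.random.default_rng(3)
    deg = _deg_table(2000, rng)
    deg["log2FC"] = np.abs(deg["log2FC"]) + 0.01  # all up
    sig = standardize_signature(deg, "up")
    assert len(sig.gene_ids) == 200
    few = deg.head(150)
    assert len(standardize_signature(few, "up").gene_ids) == 150
    assert standardize_signature(deg, "down").gene_ids == []


def test_signature_two_stage_rule_excludes_late_p_ranks():
    rng = np.random.default_rng(4)
    deg = _deg_table(600, rng)
    deg["log2FC"] = 1.0
    deg["p_value"] = np.linspace(1e-6, 0.9, 600)
    # the gene ranked 501 by p carries the largest fold change but misses
    # the significance stage
    deg.loc[500, "log2FC"] = 50.0
    sig = standardize_signature(deg, "up")
    assert deg.loc[500, "gene_id"] not in sig.gene_ids


def test_signature_invariant_to_row_order_and_direction_rules():
    rng = np.random.default_rng(5)
    deg = _deg_table(800, rng)
    deg.loc[0, "log2FC"] = 0.0  # sign zero belongs to neither direction
    sig_a = standardize_signature(deg, "up")
    shuffled = deg.sample(frac=1.0, random_state=1).reset_index(drop=True)
    sig_b = standardize_signature(shuffled, "up")
    assert sig_a.gene_ids == sig_b.gene_ids
    assert deg.loc[0, "gene_id"] not in sig_a.gene_ids
    assert all(deg.set_index("gene_id").loc[g, "log2FC"] > 0 for g in sig_a.gene_ids)
    down = standardize_signature(deg, "down")
    assert all(deg.set_index("gene_id").loc[g, "log2FC"] < 0 for g in down.gene_ids)
    with pytest.raises(ValueError):
        standardize_signature(deg, "sideways")
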