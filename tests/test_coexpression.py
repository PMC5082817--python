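"""Network construction, TOM, module detection, eigengenes, associations."""

import numpy as np
import pandas as pd
import pytest

from conftest import module_config

from eggstim.datatypes import ModulePartition
from eggstim.coexpression import (
    detect_modules,
    eigengene_matrix,
    eigengene_subject_deltas,
    merge_modules,
    module_eigengene,
    module_trait_association,
    soft_adjacency,
    topological_overlap,
)
from eggstim.synthetic import generate_expression
from oracles import tom_triple_loop


def _expr(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


def test_soft_adjacency_known_correlations():
    x = np.array([1.0, -1.0, 1.0, -1.0])
    z = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x
    y = 0.5 * x + np.sqrt(0.75) * z       # empirical r(x, y) = 0.5 exactly
    expr = _expr([x, y, x, -x])
    a = soft_adjacency(expr, beta=7)
    assert a.iloc[0, 1] == pytest.approx(0.5 ** 7, rel=1e-12)
    assert a.iloc[0, 2] == pytest.approx(1.0)   # perfect correlation
    assert a.iloc[0, 3] == pytest.approx(1.0)   # unsigned: anti-correlation too
    assert np.all(np.diag(a) == 1.0)


def test_soft_adjacency_guards():
    expr = _expr(np.random.default_rng(0).normal(size=(4, 10)))
    with pytest.raises(ValueError):
        soft_adjacency(expr, beta=0)
    with pytest.raises(ValueError):
        soft_adjacency(expr.iloc[:, :2])
    expr.iloc[0] = 5.0  # zero variance -> removed
    assert soft_adjacency(expr).shape == (3, 3)


def test_tom_hand_example_and_identity():
    a = pd.DataFrame(np.full((3, 3), 0.5) + 0.5 * np.eye(3))
    tom = topological_overlap(a)
    # (0.25 + 0.5) / (1 + 1 - 0.5)
    assert tom.iloc[0, 1] == pytest.approx(0.5)
    eye = pd.DataFrame(np.eye(4))
    pd.testing.assert_frame_equal(topological_overlap(eye), eye)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(3)
    expr = _expr(rng.normal(size=(50, 20)))
    a = soft_adjacency(expr, beta=7)
    tom = topological_overlap(a).to_numpy()
    oracle = tom_triple_loop(a.to_numpy())
    assert np.max(np.abs(tom - oracle)) < 1e-10
    assert np.max(np.abs(tom - tom.T)) < 1e-12
    assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


def test_tom_rejects_asymmetry():
    a = pd.DataFrame(np.eye(3))
    a.iloc[0, 1] = 0.5
    with pytest.raises(ValueError):
        topological_overlap(a)


def test_detect_modules_recovers_planted_blocks():
    expr, _, truth = generate_expression(module_config(seed=4))
    tom = topological_overlap(soft_adjacency(expr))
    part = detect_modules(1.0 - tom)
    sizes = part.sizes()
    assert len(sizes) == 3
    assert min(sizes.values()) >= 50
    # labels are numbered by size: 1 is the largest
    ordered = [sizes[k] for k in sorted(sizes)]
    assert ordered == sorted(ordered, reverse=True)
    # determinism
    part2 = detect_modules(1.0 - tom)
    pd.testing.assert_series_equal(part.assignment, part2.assignment)


def test_detect_modules_min_size_larger_than_input():
    rng = np.random.default_rng(1)
    expr = _expr(rng.normal(size=(30, 12)))
    tom = topological_overlap(soft_adjacency(expr))
    part = detect_modules(1.0 - tom, min_module_size=100)
    assert part.module_labels() == []
    assert (part.assignment == 0).all()


def test_eigengene_properties():
    rng = np.random.default_rng(2)
    base = rng.normal(size=20)
    expr = _expr([base * s + rng.normal(scale=1e-6, size=20) for s in (1, 2, 0.5)])
    part = ModulePartition(pd.Series([1, 1, 1], index=expr.index))
    eig = module_eigengene(expr, part, 1)
    assert np.linalg.norm(eig) == pytest.approx(1.0)
    for g in expr.index:
        r = np.corrcoef(expr.loc[g], eig)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-4)
    # flipping every member row leaves the oriented eigengene unchanged
    flipped = expr * -1
    eig_f = module_eigengene(flipped, part, 1)
    # orientation makes mean member correlation positive in both cases
    assert np.mean([np.corrcoef(expr.loc[g], eig)[0, 1] for g in expr.index]) > 0
    assert np.mean([np.corrcoef(flipped.loc[g], eig_f)[0, 1] for g in flipped.index]) > 0
    with pytest.raises(ValueError):
        module_eigengene(expr, ModulePartition(pd.Series([1, 0, 0], index=expr.index)), 1)


def test_eigengene_tracks_planted_latent_factor():
    expr, _, truth = generate_expression(module_config(seed=6))
    part = ModulePartition(truth.module_assignment)
    for m in (1, 2, 3):
        eig = module_eigengene(expr, part, m)
        r = np.corrcoef(eig, truth.module_latents.loc[m])[0, 1]
        assert abs(r) >= 0.9


def test_eigengene_variance_share_reflects_module_correlation():
    cfg = module_config(seed=8)
    expr, _, truth = generate_expression(cfg)
    members = truth.module_assignment[truth.module_assignment == 1].index
    sub = expr.loc[members]
    z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=1)).T.to_numpy()
    s = np.linalg.svd(z, compute_uv=False)
    share = s[0] ** 2 / (s ** 2).sum()
    assert share >= cfg.module_cor - 0.1


def test_merge_modules_joins_split_factor_and_respects_cutoff():
    expr, _, truth = generate_expression(module_config(seed=5))
    # split planted module 1 into halves: their eigengenes share the factor
    members = list(truth.module_assignment[truth.module_assignment == 1].index)
    labels = pd.Series(0, index=expr.index)
    labels[members[:50]] = 1
    labels[members[50:]] = 2
    m2 = list(truth.module_assignment[truth.module_assignment == 2].index)
    labels[m2] = 3
    merged = merge_modules(expr, ModulePartition(labels), cutoff=0.29)
    sizes = merged.sizes()
    assert len(sizes) == 2  # halves merged, independent module kept
    assert max(sizes.values()) == 100
    assert min(sizes.values()) >= 50  # merging never shrinks the smallest module
    # distinct factors stay separate at the same cutoff
    clean = ModulePartition(truth.module_assignment)
    unchanged = merge_modules(expr, clean, cutoff=0.29)
    assert len(unchanged.sizes()) == 3


def test_trait_association_recovers_self_and_flags_constant():
    expr, samples, truth = generate_expression(module_config(seed=7))
    part = ModulePartition(truth.module_assignment)
    eig = eigengene_matrix(expr, part)
    traits = pd.DataFrame(
        {c: [eig.loc[1, c], 1.0] for c in eig.columns},
        index=["self", "flat"],
    )
    out = module_trait_association(eig, traits).set_index(["module", "trait"])
    hit = out.loc[(1, "self")]
    assert hit["p_value"] < 1e-20
    assert hit["slope"] == pytest.approx(1.0, abs=1e-8)
    assert out.loc[(1, "flat"), "p_value"] == 1.0
    assert out["fdr_p"].ge(out["p_value"] - 1e-12).all()


def test_planted_module_cytokine_association_is_top_hit():
    """A per-subject trait built from module 1's stimulation response is the
    strongest (module, trait) association in >= 90% of seeds."""
    hits = 0
    for seed in range(1, 21):
        expr, samples, truth = generate_expression(module_config(seed=seed))
        part = ModulePartition(truth.module_assignment)
        eig = eigengene_matrix(expr, part)
        eig_d = eigengene_subject_deltas(eig, samples)
        rng = np.random.default_rng(seed + 1000)
        lat = truth.module_latents.loc[1]
        meta = samples.set_index("sample_id")
        lat_delta = {}
        for subj, sub in meta.groupby("subject_id"):
            s = pd.Series(sub.index, index=sub["stimulation"])
            lat_delta[subj] = lat[s["EW"]] - lat[s["M"]]
        trait = pd.DataFrame(
            {s: [2.0 * lat_delta[s] + rng.normal(0, 1.0)] for s in eig_d.columns},
            index=["cytoX"],
        )
        out = module_trait_association(eig_d, trait)
        top = out.sort_values("p_value").iloc[0]
        hits += top["module"] == 1
    assert hits >= 18


def test_independent_trait_yields_uniform_pvalues():
    ps = []
    for seed in range(1, 21):
        expr, samples, truth = generate_expression(module_config(seed=seed))
        part = ModulePartition(truth.module_assignment)
        eig = eigengene_matrix(expr, part)
        rng = np.random.default_rng(seed + 2000)
        trait = pd.DataFrame(rng.normal(size=(1, eig.shape[1])),
                             index=["noise"], columns=eig.columns)
        out = module_trait_association(eig, trait)
        ps.extend(out["p_value"].tolist())
    ps = np.asarray(ps)
    assert 0.25 <= (ps < 0.5).mean() <= 0.75  # coarse uniformity check
    assert (ps < 0.001).sum() == 0
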