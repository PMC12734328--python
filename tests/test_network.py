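import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

import mapkstress as m
from mapkstress.deg import DEGSet
from mapkstress.pipeline import adjusted_rand_index


def expr_of(array, tag="logclr"):
    df = pd.DataFrame(np.asarray(array, float))
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return m.ExpressionMatrix(df, tag)


# --- gene selection --------------------------------------------------------

def test_select_coexpression_genes_union():
    def ds(genes):
        return DEGSet(pd.Series("up_in_mutant", index=genes), "dHog1",
                      "sorbitol", 0.5)
    a = ds([f"g{i}" for i in range(10)])
    b = ds([f"g{i}" for i in range(5, 15)])
    assert len(m.select_coexpression_genes([a, b])) == 15
    empty = DEGSet(pd.Series(dtype=object), "dHog1", "sorbitol", 0.5)
    with pytest.warns(UserWarning):
        assert m.select_coexpression_genes([empty]) == []


# --- k-means ---------------------------------------------------------------

def test_kmeans_trivial_cases():
    base = np.tile([1.0, -1.0, 0.5, -0.5], (6, 1))
    base[3:] *= -1
    base += np.random.default_rng(0).normal(0, 0.01, base.shape)
    expr = expr_of(base - base.mean(axis=1, keepdims=True))
    one = m.kmeans_modules(expr, 1, seed=0)
    assert len(set(one.labels)) == 1
    two = m.kmeans_modules(expr, 2, seed=0)
    assert len(set(two.labels[:3])) == 1 and len(set(two.labels[3:])) == 1
    with pytest.raises(ValueError):
        m.kmeans_modules(expr, 0, seed=0)
    with pytest.raises(ValueError):
        m.kmeans_modules(expr, 7, seed=0)


def test_kmeans_recovers_planted_blocks(block_expr):
    expr, truth = block_expr
    km = m.kmeans_modules(expr, 3, seed=0)
    assert adjusted_rand_index(km.labels, truth) >= 0.9
    km2 = m.kmeans_modules(expr, 3, seed=0)
    pd.testing.assert_series_equal(km.labels, km2.labels)


# --- soft threshold --------------------------------------------------------

def test_mean_connectivity_decreases_with_power(block_expr):
    expr, _ = block_expr
    _, diag = m.pick_soft_threshold(expr, m.NetworkParams(power_grid=(1, 3, 6, 9)))
    k = diag["mean_connectivity"].to_numpy()
    assert (np.diff(k) < 0).all()


def test_single_power_grid_returned():
    rng = np.random.default_rng(0)
    expr = expr_of(rng.normal(0, 1, (30, 10)))
    beta, diag = m.pick_soft_threshold(
        expr, m.NetworkParams(power_grid=(6,), r2_target=0.0))
    assert beta == 6 and len(diag) == 1


def test_scale_free_fit_reached_on_graded_block_structure():
    """With hub/periphery loading structure plus background genes, the
    chosen power reaches the scale-free topology fit target."""
    pm = m.PlantedModules(n_blocks=3, block_size=(150, 100, 60),
                          loading_sd=(0.5, 0.35, 0.22), loading_spread=0.6)
    cfg = m.SimulationConfig(n_genes=1000, planted_response={},
                             planted_modules=pm, seed=0)
    cm, _, truth = m.simulate_counts(cfg)
    ef = m.tmm_logclr(cm)
    genes = list(truth.module_id.index[truth.module_id >= 0]) + \
        list(truth.module_id.index[truth.module_id < 0][:200])
    expr = m.ExpressionMatrix(ef.values.loc[genes], "logclr")
    beta, diag = m.pick_soft_threshold(expr)
    assert float(diag.loc[diag["power"] == beta, "r2"].iloc[0]) >= 0.8


# --- TOM -------------------------------------------------------------------

def brute_force_tom(x, power):
    r = np.corrcoef(x)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (
                min(a[i].sum(), a[j].sum()) + 1.0 - a[i, j])
    return tom


@pytest.mark.parametrize("n_genes,power", [(4, 2), (7, 3), (10, 6)])
def test_tom_matches_triple_loop_oracle(n_genes, power):
    rng = np.random.default_rng(n_genes)
    x = rng.normal(0, 1, (n_genes, 12))
    tom = m.adjacency_and_tom(expr_of(x), power).to_numpy()
    assert np.abs(tom - brute_force_tom(x, power)).max() < 1e-10
    assert np.allclose(tom, tom.T)
    assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()


def test_tom_perfect_pair_is_one():
    x = np.array([[1.0, 2.0, 3.0, 1.5], [2.0, 4.0, 6.0, 3.0]])
    tom = m.adjacency_and_tom(expr_of(x), 6).to_numpy()
    assert tom[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_tom_independent_genes_vanishes():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, (20, 2000))
    tom = m.adjacency_and_tom(expr_of(x), 6).to_numpy()
    off = tom[~np.eye(20, dtype=bool)]
    assert off.max() < 0.05


def test_tom_zero_variance_gene_errors():
    x = np.vstack([np.ones(8), np.random.default_rng(0).normal(0, 1, (3, 8))])
    with pytest.raises(ValueError, match="g0"):
        m.adjacency_and_tom(expr_of(x), 6)


# --- module detection ------------------------------------------------------

def test_detect_modules_recovers_planted_blocks(block_expr):
    expr, truth = block_expr
    tom = m.adjacency_and_tom(expr, 6)
    assignment = m.detect_modules(tom, m.NetworkParams(), expr)
    assert len(assignment.modules) == 3
    assert adjusted_rand_index(assignment.labels, truth) >= 0.9


def test_detect_modules_single_block_and_grey():
    rng = np.random.default_rng(1)
    z = rng.normal(0, 1, 12)
    x = np.outer(np.full(40, 1.0), z) + rng.normal(0, 0.2, (40, 12))
    tom = m.adjacency_and_tom(expr_of(x), 6)
    one = m.detect_modules(tom, m.NetworkParams(min_module_size=10))
    assert len(one.modules) == 1 and (one.labels == "turquoise").all()
    small = m.detect_modules(tom, m.NetworkParams(min_module_size=100))
    assert (small.labels == "grey").all() and small.modules == []


# --- eigengenes ------------------------------------------------------------

def make_assignment(labels_dict):
    s = pd.Series(labels_dict)
    return m.ModuleAssignment(s, "tree_cut")


def test_eigengene_of_identical_profiles():
    profile = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
    x = np.tile(profile, (5, 1))
    expr = expr_of(x)
    assignment = make_assignment({f"g{i}": "blue" for i in range(5)})
    eig = m.module_eigengenes(expr, assignment)
    z = (profile - profile.mean()) / profile.std()
    expected = z / np.linalg.norm(z)
    assert np.allclose(eig.values.loc["blue"], expected, atol=1e-10)
    assert eig.variance_explained["blue"] == pytest.approx(1.0)


def test_eigengene_sign_and_order_invariance():
    rng = np.random.default_rng(3)
    x = np.outer(rng.uniform(0.5, 1.5, 6), rng.normal(0, 1, 10)) \
        + rng.normal(0, 0.1, (6, 10))
    expr = expr_of(x)
    assignment = make_assignment({f"g{i}": "blue" for i in range(6)})
    e1 = m.module_eigengenes(expr, assignment).values.loc["blue"]
    flipped = expr_of(-x)
    e2 = m.module_eigengenes(flipped, assignment).values.loc["blue"]
    assert np.allclose(e1, e2, atol=1e-10)  # orientation rule, not raw PCA sign
    perm = expr_of(x[::-1])
    e3 = m.module_eigengenes(perm, assignment).values.loc["blue"]
    assert np.allclose(e1, e3.to_numpy(), atol=1e-10)


def test_eigengene_two_gene_closed_form():
    """For two standardized genes the first PC is their normalized sum
    (or difference), from the analytic 2×2 eigen-decomposition."""
    rng = np.random.default_rng(8)
    x = rng.normal(0, 1, (2, 9))
    expr = expr_of(x)
    assignment = make_assignment({"g0": "blue", "g1": "blue"})
    eig = m.module_eigengenes(expr, assignment)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    r = np.corrcoef(z)[0, 1]
    direction = z[0] + np.sign(r) * z[1]
    expected = direction / np.linalg.norm(direction)
    got = eig.values.loc["blue"].to_numpy()
    assert min(np.abs(got - expected).max(),
               np.abs(got + expected).max()) < 1e-9
    assert eig.variance_explained["blue"] == pytest.approx((1 + abs(r)) / 2,
                                                           abs=1e-9)


def test_eigengene_constant_gene_errors():
    x = np.vstack([np.ones(6), np.arange(6.0)])
    assignment = make_assignment({"g0": "blue", "g1": "blue"})
    with pytest.raises(ValueError):
        m.module_eigengenes(expr_of(x), assignment)


# --- module–trait ----------------------------------------------------------

def betainc_pvalue(r, n):
    """Independent two-sided p via the incomplete-beta form of the t CDF."""
    df = n - 2
    t2 = r * r * df / (1.0 - r * r)
    return float(betainc(df / 2.0, 0.5, df / (df + t2)))


@pytest.mark.parametrize("r", [0.05, 0.2, 0.5, 0.6, 0.7, -0.73, 0.78, 0.9, -0.99])
def test_corr_pvalue_matches_incomplete_beta_oracle(r):
    mine = m.corr_pvalue(r, 18)
    assert mine == pytest.approx(betainc_pvalue(r, 18), rel=1e-9)


def test_corr_pvalue_edge_cases():
    assert m.corr_pvalue(0.0, 18) == pytest.approx(1.0)
    assert m.corr_pvalue(1.0, 18) == 0.0
    assert m.corr_pvalue(0.5, 18) == pytest.approx(0.0346, abs=5e-5)


def test_module_trait_correlations():
    trait = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0], float)
    eigv = pd.DataFrame([(trait - trait.mean()) / np.linalg.norm(trait - trait.mean())],
                        index=["blue"], columns=[f"s{j}" for j in range(10)])
    eig = m.EigengeneMatrix(eigv, pd.Series({"blue": 1.0}))
    traits = pd.DataFrame({"stress": trait, "flat": np.ones(10)},
                          index=eigv.columns)
    mt = m.module_trait(eig, traits)
    assert mt.r.loc["blue", "stress"] == pytest.approx(1.0)
    assert mt.p.loc["blue", "stress"] < 1e-12
    assert np.isnan(mt.r.loc["blue", "flat"])  # constant trait: missing


def test_module_trait_orthogonal_gives_p_one():
    e = np.array([1.0, -1.0, 1.0, -1.0])
    trait = np.array([1.0, 1.0, 0.0, 0.0])
    eig = m.EigengeneMatrix(
        pd.DataFrame([e / np.linalg.norm(e)], index=["blue"],
                     columns=[f"s{j}" for j in range(4)]),
        pd.Series({"blue": 1.0}))
    traits = pd.DataFrame({"t": trait}, index=[f"s{j}" for j in range(4)])
    mt = m.module_trait(eig, traits)
    assert mt.r.loc["blue", "t"] == pytest.approx(0.0, abs=1e-12)
    assert mt.p.loc["blue", "t"] == pytest.approx(1.0)


def test_printed_module_trait_pairs_within_factor_two():
    """The study's module–trait (r, p) pairs at n = 18 agree with the
    Student-t transform within a factor of 2 (their r values are rounded)."""
    for r, p_printed in [(0.78, 1.5e-4), (-0.73, 5.5e-4),
                         (0.7, 1.1e-3), (0.6, 5.6e-3)]:
        mine = m.corr_pvalue(r, 18)
        assert 0.5 < mine / p_printed < 2.0


# --- export ----------------------------------------------------------------

def test_export_network_thresholds():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (6, 15))
    tom = m.adjacency_and_tom(expr_of(x), 2)
    assignment = make_assignment({f"g{i}": "blue" for i in range(6)})
    all_edges, nodes = m.export_network(tom, assignment, 0.0)
    assert len(all_edges) == 15  # 6·5/2
    none_edges, _ = m.export_network(tom, assignment, 1.0)
    assert len(none_edges) == 0
    thr = float(np.sort(tom.to_numpy()[np.triu_indices(6, 1)])[-4])
    four, _ = m.export_network(tom, assignment, thr)
    assert len(four) == 4
    assert set(nodes.columns) == {"gene_id", "module"}
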