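"""Shared-gene-excluded correlations, thresholded networks, coupling tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arscore import (
    GeneratorConfig,
    all_pairs,
    build_network,
    compare_coupling,
    corr_pair_excluding_shared,
    generate,
    standardize_genewise,
)
from arscore.containers import GeneSetCollection
from arscore.correlation_network import PathwayCorrelation
from arscore.errors import ContractError, NotEvaluableError
from arscore.pathway_scores import activity_matrix, rank_matrix


def brute_force_pair_rho(genes_a, genes_b, matrix, min_genes=5):
    """Independent oracle: rebuild residual sets and rank-correlate from scratch."""
    shared = set(genes_a) & set(genes_b)
    res_a = [g for g in genes_a if g not in shared and g in matrix.index]
    res_b = [g for g in genes_b if g not in shared and g in matrix.index]
    assert len(res_a) >= min_genes and len(res_b) >= min_genes
    prof_a, prof_b = [], []
    for sample in matrix.columns:
        col = matrix[sample].rank()
        n = col.notna().sum()
        prof_a.append(col.loc[res_a].mean() / n)
        prof_b.append(col.loc[res_b].mean() / n)
    return stats.spearmanr(prof_a, prof_b).statistic


def monotone_profile_matrix(decreasing: bool = False) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Disjoint sets whose AR profiles are exactly monotone in each other.

    Filler genes keep fixed values at half-integers 0.5..9.5 in every sample;
    set A genes sit at the sample index j (+ tiny offsets) so their mean rank
    strictly increases with j, and set B genes at j (or 10 - j) likewise.
    """
    samples = list(range(1, 10))
    rows = {}
    for i in range(6):
        rows[f"a{i}"] = [j + 0.01 * i for j in samples]
        b_base = [(10 - j) if decreasing else j for j in samples]
        rows[f"b{i}"] = [v + 0.3 + 0.01 * i for v in b_base]
    for i in range(10):
        rows[f"noise{i}"] = [i + 0.5] * len(samples)
    mat = pd.DataFrame(rows, index=[f"s{j}" for j in samples]).T
    sets = GeneSetCollection(
        {"A": [f"a{i}" for i in range(6)], "B": [f"b{i}" for i in range(6)]}
    )
    return mat, sets


class TestPairCorrelation:
    def test_monotone_increasing_profiles_give_rho_one(self):
        mat, sets = monotone_profile_matrix()
        rho = corr_pair_excluding_shared(sets["A"], sets["B"], mat)
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_profiles_give_rho_minus_one(self):
        mat, sets = monotone_profile_matrix(decreasing=True)
        rho = corr_pair_excluding_shared(sets["A"], sets["B"], mat)
        assert rho == pytest.approx(-1.0)

    def test_subset_with_empty_residual_is_not_evaluable(self):
        mat, _ = monotone_profile_matrix()
        inner = [f"a{i}" for i in range(6)]
        outer = inner + ["noise0", "noise1"]
        with pytest.raises(NotEvaluableError, match="residual"):
            corr_pair_excluding_shared(inner, outer, mat)

    def test_symmetric_in_arguments(self):
        mat, sets = monotone_profile_matrix()
        r1 = corr_pair_excluding_shared(sets["A"], sets["B"], mat)
        r2 = corr_pair_excluding_shared(sets["B"], sets["A"], mat)
        assert r1 == pytest.approx(r2)

    def test_matches_brute_force_oracle_on_small_instance(self):
        """6 pathways, 10 samples, 40 genes, with overlaps: every pair equals
        an independent from-scratch recomputation."""
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(40)]
        mat = pd.DataFrame(
            rng.normal(size=(40, 10)), index=genes, columns=[f"s{j}" for j in range(10)]
        )
        sets = {}
        for k in range(6):
            members = list(rng.choice(genes, size=8, replace=False))
            sets[f"P{k}"] = members
        coll = GeneSetCollection(sets)
        result = all_pairs(coll, mat, min_genes=2)
        for a, b in combinations(coll.names, 2):
            expected = brute_force_pair_rho(coll[a], coll[b], mat, min_genes=2)
            assert result.matrix.at[a, b] == pytest.approx(expected, abs=1e-12)

    def test_exclusion_noop_for_disjoint_pairs(self, default_dataset):
        """For disjoint pairs, rho with exclusion equals the naive profile rho."""
        mat = standardize_genewise(default_dataset.expression).matrix
        sets = default_dataset.sets
        overlapping = {frozenset(p) for p in default_dataset.truth.overlap}
        with_excl = all_pairs(sets, mat, exclude_shared=True)
        without = all_pairs(sets, mat, exclude_shared=False)
        for a, b in combinations(sets.names, 2):
            if frozenset((a, b)) in overlapping:
                continue
            assert with_excl.matrix.at[a, b] == pytest.approx(without.matrix.at[a, b], abs=1e-12)

    def test_exclusion_matters_for_overlapping_pairs(self, default_dataset):
        mat = standardize_genewise(default_dataset.expression).matrix
        sets = default_dataset.sets
        with_excl = all_pairs(sets, mat, exclude_shared=True)
        without = all_pairs(sets, mat, exclude_shared=False)
        (a, b) = next(iter(default_dataset.truth.overlap))
        assert with_excl.matrix.at[a, b] != pytest.approx(without.matrix.at[a, b], abs=1e-9)


class TestAllPairs:
    @pytest.mark.parametrize("k,expected", [(2, 1), (5, 10)])
    def test_pair_count(self, k, expected):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10 * k)]
        mat = pd.DataFrame(rng.normal(size=(10 * k, 8)), index=genes)
        coll = GeneSetCollection(
            {f"P{i}": genes[10 * i : 10 * (i + 1)] for i in range(k)}
        )
        result = all_pairs(coll, mat)
        assert result.n_pairs == expected

    def test_matrix_is_symmetric_with_unit_diagonal(self, default_dataset):
        mat = standardize_genewise(default_dataset.expression).matrix
        result = all_pairs(default_dataset.sets, mat)
        arr = result.matrix.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 1.0)
        finite = arr[~np.isnan(arr)]
        assert (finite >= -1 - 1e-12).all() and (finite <= 1 + 1e-12).all()


class TestBuildNetwork:
    def make_corr(self, rho):
        df = pd.DataFrame(
            [[1.0, rho], [rho, 1.0]], index=["P1", "P2"], columns=["P1", "P2"]
        )
        return PathwayCorrelation(df, n_samples=10, n_pairs=1, exclude_shared=True)

    def test_all_below_tau_keeps_isolated_nodes(self):
        net = build_network(self.make_corr(0.5), tau=0.75)
        assert net.edges == []
        assert set(net.nodes) == {"P1", "P2"}

    def test_single_positive_edge(self):
        net = build_network(self.make_corr(0.8), tau=0.75)
        assert net.edges == [("P1", "P2", 0.8, "positive")]

    def test_exact_tau_is_not_an_edge(self):
        net = build_network(self.make_corr(0.75), tau=0.75)
        assert net.edges == []

    def test_negative_edge_sign(self):
        net = build_network(self.make_corr(-0.9), tau=0.75)
        assert net.edges[0][3] == "negative"


class TestCompareCoupling:
    def test_identical_matrices_give_t_zero(self):
        rng = np.random.default_rng(2)
        names = [f"P{i}" for i in range(10)]
        arr = rng.uniform(-1, 1, size=(10, 10))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        corr = PathwayCorrelation(
            pd.DataFrame(arr, index=names, columns=names), 20, 45, True
        )
        res = compare_coupling(corr, corr)
        assert res.t == 0.0 and res.p == 1.0

    def test_abs_mode_ignores_sign_flips(self):
        rng = np.random.default_rng(3)
        names = [f"P{i}" for i in range(8)]
        arr = rng.uniform(0.1, 0.9, size=(8, 8))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        pos = PathwayCorrelation(pd.DataFrame(arr, index=names, columns=names), 20, 28, True)
        neg = PathwayCorrelation(pd.DataFrame(-arr, index=names, columns=names), 20, 28, True)
        res = compare_coupling(pos, neg, mode="abs")
        assert res.t == 0.0

    def test_attenuated_coupling_detected(self):
        """Condition B's coupling attenuated by half: paired t > 0, small p."""
        base = GeneratorConfig(
            n_genes=1200,
            n_pathways=24,
            n_samples={"a": 60, "b": 60},
            gamma={"a": 0.8, "b": 0.4},
            rho_within=0.5,
            delta=0.0,
            n_overlap_pairs=0,
            seed=10,
        )
        data = generate(base)
        corr = {
            cond: all_pairs(
                data.sets, standardize_genewise(data.condition_matrix(cond)).matrix
            )
            for cond in ("a", "b")
        }
        res = compare_coupling(corr["a"], corr["b"])
        assert res.n_pairs >= 200
        assert res.t > 0
        assert res.p < 0.01

    def test_too_few_common_pairs_is_contract_error(self):
        names = ["P1", "P2"]
        df = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=names, columns=names)
        corr = PathwayCorrelation(df, 10, 1, True)
        with pytest.raises(ContractError):
            compare_coupling(corr, corr)

    def test_coupling_monotone_in_gamma(self):
        """Median |rho| over truly coupled pairs rises with gamma."""
        medians = []
        for gamma in (0.0, 0.3, 0.6, 0.9):
            cfg = GeneratorConfig(
                n_genes=900,
                n_pathways=15,
                n_samples={"only": 80},
                gamma=gamma,
                rho_within=0.5,
                delta=0.0,
                n_overlap_pairs=0,
                seed=123,
            )
            data = generate(cfg)
            mat = standardize_genewise(data.expression).matrix
            corr = all_pairs(data.sets, mat)
            coupled = [corr.matrix.at[a, b] for a, b in data.truth.coupled_pairs]
            medians.append(np.median(np.abs(coupled)))
        assert medians == sorted(medians)


class TestArEsProfileShapes:
    def test_ar_unimodal_es_bimodal_on_exchangeable_noise(self):
        """Pooled over pathways and samples of pure-noise data, AR-scores look
        normal while ES-scores split into a positive and a negative lobe."""
        cfg = GeneratorConfig(
            n_genes=600,
            n_pathways=12,
            n_samples={"only": 40},
            rho_within=0.0,
            gamma=0.0,
            delta=0.0,
            n_overlap_pairs=0,
            seed=5,
        )
        data = generate(cfg)
        mat = standardize_genewise(data.expression).matrix
        ar = activity_matrix(mat, data.sets).to_numpy().ravel()
        es = activity_matrix(mat, data.sets, score_type="es").to_numpy().ravel()

        def bimodality_coefficient(x):
            n = len(x)
            g1 = stats.skew(x)
            g2 = stats.kurtosis(x)  # excess
            return (g1**2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))

        assert abs(stats.skew(ar)) < 0.5
        assert bimodality_coefficient(ar) < 0.5
        assert bimodality_coefficient(es) > 0.555  # uniform-threshold heuristic
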