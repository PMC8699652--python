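"""Wavelength selectors: planted-signal recovery, oracles, contracts."""

import numpy as np
import pytest

from conftest import planted_signal
from oilblend import (
    CARSConfig,
    cars_retention_schedule,
    cars_select,
    overlap_counts,
    pca_loading_select,
    spa_select,
    vip_select,
)
from oilblend.exceptions import ParameterError, SelectionError
from oilblend.select import SelectionResult, _spa_chain


class TestPCALoadingSelect:
    def test_planted_variance_columns_found(self):
        rng = np.random.default_rng(0)
        n, p = 60, 100
        X = 1e-4 * rng.standard_normal((n, p))  # near-constant background
        hot = np.arange(0, 100, 10)
        X[:, hot] += rng.standard_normal((n, hot.size))
        result = pca_loading_select(X, k=10)
        np.testing.assert_array_equal(result.selected, hot)

    def test_k_equals_p_selects_all(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 15))
        result = pca_loading_select(X, k=15)
        np.testing.assert_array_equal(result.selected, np.arange(15))

    def test_contract_sorted_unique_of_length_k(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 40))
        result = pca_loading_select(X, k=12, n_pcs=3)
        assert result.n_selected == 12
        assert np.all(np.diff(result.selected) > 0)

    def test_infeasible_k_rejected(self):
        X = np.random.default_rng(3).standard_normal((10, 5))
        with pytest.raises(ParameterError):
            pca_loading_select(X, k=6)


class TestVIPSelect:
    def test_planted_signal_recall_at_threshold_one(self):
        X, y, informative = planted_signal(100)
        result = vip_select(X, y, threshold=1.0, seed=0)
        recall = len(set(informative) & set(result.selected)) / len(informative)
        assert recall >= 0.9

    def test_uncorrelated_response_still_valid_contract(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 60))
        y = rng.standard_normal(40)
        result = vip_select(X, y, seed=0)
        assert result.n_selected >= 1
        assert np.all((result.selected >= 0) & (result.selected < 60))

    def test_top_k_rule_returns_exactly_k(self):
        X, y, _ = planted_signal(101)
        result = vip_select(X, y, k=90, seed=0)
        assert result.n_selected == 90


class TestSPA:
    def test_chain_matches_gram_schmidt_oracle(self):
        """The SPA chain must equal brute-force Gram-Schmidt projection:
        at each step, the column with maximal residual norm after
        projecting off the span of the chosen columns."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((5, 4))
            Xc = X - X.mean(axis=0)
            start = int(np.argmax(np.einsum("ij,ij->j", Xc, Xc)))
            chain = _spa_chain(Xc, start, 4)
            # oracle: explicit orthonormal basis, full reprojection each step
            oracle = [start]
            for _ in range(3):
                basis = np.linalg.qr(Xc[:, oracle])[0]
                resid = Xc - basis @ (basis.T @ Xc)
                norms = np.einsum("ij,ij->j", resid, resid)
                norms[oracle] = -1
                oracle.append(int(np.argmax(norms)))
            assert chain == oracle

    def test_orthogonal_design_first_addition_is_max_norm(self):
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.standard_normal((20, 6)))
        scales = np.array([1.0, 3.0, 2.0, 0.5, 2.5, 1.5])
        Xc = Q * scales
        chain = _spa_chain(Xc, start=3, length=2)
        assert chain == [3, 1]  # column 1 has the largest norm among the rest

    def test_duplicated_column_never_selected_after_twin(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 6))
        X[:, 4] = X[:, 1]
        Xc = X - X.mean(axis=0)
        chain = _spa_chain(Xc, start=1, length=6)
        assert 4 not in chain

    def test_selected_prefix_scores_best(self):
        X, y, _ = planted_signal(8, n=40, p=25)
        result = spa_select(X, y, k_min=2, k_max=8, seed=0)
        assert 2 <= result.n_selected <= 8
        assert result.diagnostics["best_rmse"] == min(
            min(v) for v in result.diagnostics["chain_rmse"].values())

    def test_infeasible_range_rejected(self):
        X, y, _ = planted_signal(9, n=20, p=10)
        with pytest.raises(ParameterError):
            spa_select(X, y, k_min=5, k_max=3)


class TestCARS:
    def test_retention_schedule_endpoints(self):
        for p, n_runs in [(2151, 50), (200, 50), (50, 10)]:
            sched = cars_retention_schedule(p, n_runs)
            assert sched[0] == p
            assert sched[-1] == 2
            assert np.all(np.diff(sched) <= 0)

    def test_returned_subset_is_rmsecv_argmin(self):
        X, y, _ = planted_signal(10)
        result = cars_select(X, y, CARSConfig(n_runs=30, seed=0))
        path = result.diagnostics["rmsecv_path"]
        assert result.diagnostics["best_run"] == int(np.argmin(path))
        assert len(result.diagnostics["subset_sizes"]) == len(path)

    def test_same_seed_reproduces_selection(self):
        X, y, _ = planted_signal(11)
        cfg = CARSConfig(n_runs=25, seed=3)
        a = cars_select(X, y, cfg)
        b = cars_select(X, y, cfg)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_planted_signal_median_recall(self):
        recalls = []
        for seed in range(10):
            X, y, informative = planted_signal(200 + seed)
            result = cars_select(X, y, CARSConfig(seed=seed))
            recalls.append(
                len(set(informative) & set(result.selected)) / len(informative))
        assert np.median(recalls) >= 0.8

    def test_noiseless_planted_signal_full_recall(self):
        """Deterministic limit: with exact linear structure both CARS and
        VIP recover every informative wavelength."""
        X, y, informative = planted_signal(55, noise_sd=0.0)
        cars = cars_select(X, y, CARSConfig(seed=0))
        vip = vip_select(X, y, threshold=1.0, seed=0)
        assert set(informative).issubset(set(cars.selected))
        assert set(informative).issubset(set(vip.selected))


class TestOverlapCounts:
    def _mk(self, algorithm, idx, p=50):
        return SelectionResult(algorithm=algorithm,
                               selected=np.sort(np.unique(idx)),
                               n_wavelengths=p)

    def test_single_set_counts_itself(self):
        counts = overlap_counts([self._mk("pca", [1, 4, 9])])
        assert counts == {("pca",): 3}

    def test_disjoint_sets_have_empty_intersections(self):
        counts = overlap_counts([self._mk("pca", [0, 1]),
                                 self._mk("vip", [2, 3]),
                                 self._mk("spa", [4]),
                                 self._mk("cars", [5, 6, 7])])
        for combo, c in counts.items():
            expected = {("pca",): 2, ("vip",): 2, ("spa",): 1, ("cars",): 3}
            assert c == expected.get(combo, 0)

    def test_matches_brute_force_venn_oracle(self):
        rng = np.random.default_rng(12)
        sets = {alg: set(rng.choice(40, size=rng.integers(5, 20),
                                    replace=False).tolist())
                for alg in ("pca", "vip", "spa", "cars")}
        results = [self._mk(alg, sorted(s), p=40) for alg, s in sets.items()]
        counts = overlap_counts(results)
        for idx in range(40):  # every element lands in exactly one region
            members = tuple(sorted(a for a, s in sets.items() if idx in s))
            if members:
                assert counts[members] >= 1
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ParameterError):
            overlap_counts([self._mk("pca", [1], p=50),
                            self._mk("vip", [1], p=60)])
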