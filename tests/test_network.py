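"""Adjacency construction, scale-free diagnostic, consensus, module
detection and permutation validation."""

import numpy as np
import pandas as pd
import pytest

import coexdisrupt as cd
from coexdisrupt.containers import DegenerateInputError, ExpressionMatrix

from conftest import random_adjacency


def _expr(values, samples=None):
    values = np.asarray(values, dtype=float)
    probes = [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestBuildAdjacency:
    def test_soft_threshold_arithmetic(self, rng):
        # plant a pair with correlation 0.9 and check a_ij = 0.9 ** 10
        n = 2000
        z = rng.normal(size=n)
        x = np.vstack([z, 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n)])
        adj = cd.build_adjacency(_expr(x), beta=10)
        observed_corr = np.corrcoef(x)[0, 1]
        assert adj.weights[0, 1] == pytest.approx(np.abs(observed_corr) ** 10)
        assert adj.weights[0, 1] == pytest.approx(0.9**10, abs=0.05)

    def test_unsigned_network_treats_sign_symmetrically(self, rng):
        z = rng.normal(size=50)
        x = np.vstack([z, -z + 0.1 * rng.normal(size=50), z + 0.1 * rng.normal(size=50)])
        adj = cd.build_adjacency(_expr(x), beta=6)
        corr = np.corrcoef(x)
        assert corr[0, 1] < 0 < corr[0, 2]
        assert adj.weights[0, 1] == pytest.approx(np.abs(corr[0, 1]) ** 6)

    def test_affine_profiles_fully_connected(self):
        x0 = np.array([1.0, 2.0, 5.0, 3.0])
        adj = cd.build_adjacency(_expr(np.vstack([x0, 2 * x0 + 1])), beta=10)
        assert adj.weights[0, 1] == pytest.approx(1.0)

    def test_constant_transcripts_disconnected(self, rng):
        x = np.vstack([np.full(6, 3.0), rng.normal(size=(3, 6))])
        adj = cd.build_adjacency(_expr(x), beta=10)
        assert (adj.weights[0] == 0).all()

    def test_monotone_in_beta_except_perfect_correlation(self, rng):
        x = rng.normal(size=(6, 20))
        x[5] = 3 * x[4] - 1  # |corr| = 1 pair
        a_lo = cd.build_adjacency(_expr(x), beta=6).weights
        a_hi = cd.build_adjacency(_expr(x), beta=10).weights
        iu = np.triu_indices(6, k=1)
        assert (a_hi[iu] <= a_lo[iu] + 1e-12).all()
        assert a_hi[4, 5] == pytest.approx(a_lo[4, 5]) == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cd.build_adjacency(_expr(np.ones((2, 2))))


class TestScaleFreeFit:
    def test_exact_power_law_bins_fit_perfectly(self, monkeypatch):
        # craft connectivities whose binned frequencies follow freq ~ k^-1
        # by checking the regression against a least-squares oracle instead
        k = np.array([1.0] * 100 + [2.0] * 50 + [4.0] * 25 + [8.0] * 12 + [16.0] * 6)
        # fabricate an adjacency whose row sums equal k via a star-free trick:
        # use a diagonal-block structure is overkill; call the internal
        # regression through a tiny fake network object
        class Fake:
            def connectivity(self):
                return k

        fit = cd.scale_free_fit(Fake(), n_bins=30)
        assert fit == pytest.approx(1.0, abs=0.01)

    def test_uniform_connectivity_degenerate(self):
        class Fake:
            def connectivity(self):
                return np.full(10, 3.0)

        with pytest.raises(DegenerateInputError):
            cd.scale_free_fit(Fake())

    def test_matches_polyfit_oracle(self, rng):
        adj = random_adjacency(rng, 40)
        k = adj.connectivity()
        fit = cd.scale_free_fit(adj, n_bins=5)
        # independent oracle: rebuild the binned regression by hand
        edges = np.linspace(k.min(), k.max(), 6)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 4)
        pts = []
        for b in range(5):
            m = which == b
            if m.sum():
                pts.append((np.log10(k[m].mean()), np.log10(m.sum() / len(k))))
        x = np.array([p[0] for p in pts]); y = np.array([p[1] for p in pts])
        slope, intercept = np.polyfit(x, y, 1)
        r2 = 1 - ((y - slope * x - intercept) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        expected = r2 if slope < 0 else -r2
        assert fit == pytest.approx(expected, abs=1e-12)


class TestConsensus:
    def test_mean_of_identical_inputs_is_identity(self, rng):
        adj = random_adjacency(rng, 8)
        out = cd.consensus_adjacency([adj, adj])
        assert np.allclose(out.weights, adj.weights)

    def test_two_point_mean_and_permutation_invariance(self, rng):
        a = random_adjacency(rng, 6)
        b = random_adjacency(rng, 6)
        ab = cd.consensus_adjacency([a, b])
        ba = cd.consensus_adjacency([b, a])
        assert np.allclose(ab.weights, (a.weights + b.weights) / 2)
        assert np.allclose(ab.weights, ba.weights)
        assert (ab.weights >= np.minimum(a.weights, b.weights) - 1e-12).all()
        assert (ab.weights <= np.maximum(a.weights, b.weights) + 1e-12).all()

    def test_mismatched_beta_rejected(self, rng):
        a = random_adjacency(rng, 5)
        b = random_adjacency(rng, 5)
        b.beta = 2.0
        with pytest.raises(ValueError):
            cd.consensus_adjacency([a, b])


class TestDetectModules:
    @staticmethod
    def _two_block(within=0.9, between=0.01, size=20):
        n = 2 * size
        w = np.full((n, n), between)
        w[:size, :size] = within
        w[size:, size:] = within
        np.fill_diagonal(w, 0.0)
        ids = pd.Index([f"P{i}" for i in range(n)])
        return cd.AdjacencyNetwork(w, ids, beta=1.0)

    def test_two_planted_blocks_recovered_exactly(self, rng):
        adj = self._two_block()
        expr = _expr(rng.normal(size=(40, 10)))
        part = cd.detect_modules(adj, expr, min_module_size=10, merge_cut=0.05)
        labels = part.assignment.to_numpy()
        assert len(part.labels) == 2
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_uniform_adjacency_yields_all_grey(self, rng):
        n = 30
        w = np.full((n, n), 0.4)
        np.fill_diagonal(w, 0.0)
        adj = cd.AdjacencyNetwork(w, pd.Index([f"P{i}" for i in range(n)]), 1.0)
        part = cd.detect_modules(adj, _expr(rng.normal(size=(n, 8))),
                                 min_module_size=5)
        assert part.labels == []
        assert (part.assignment == cd.GREY).all()

    def test_min_module_size_respected(self, small_bundle):
        adj = cd.build_adjacency(small_bundle.expr_high, 10)
        part = cd.detect_modules(adj, small_bundle.expr_high, min_module_size=15)
        assert all(size >= 15 for size in part.sizes().values())

    def test_order_invariance_up_to_labels(self, small_bundle, rng):
        expr = small_bundle.expr_high
        adj = cd.build_adjacency(expr, 10)
        part1 = cd.detect_modules(adj, expr, min_module_size=15)
        perm = rng.permutation(len(expr.transcript_ids))
        ids = expr.transcript_ids[perm]
        expr2 = expr.subset_transcripts(ids)
        adj2 = cd.build_adjacency(expr2, 10)
        part2 = cd.detect_modules(adj2, expr2, min_module_size=15)
        from sklearn.metrics import adjusted_rand_score

        common = expr.transcript_ids
        ari = adjusted_rand_score(
            part1.assignment.loc[common], part2.assignment.loc[common]
        )
        assert ari == pytest.approx(1.0)

    def test_truth_recovery_on_synthetic_bundle(self):
        from sklearn.metrics import adjusted_rand_score

        bundle = cd.simulate_expression_pair(
            n_modules=3, module_sizes=(30, 30, 30), n_samples_per_condition=40,
            loading=0.7, disruption_fraction=0.0, seed=21,
        )
        adj_h = cd.build_adjacency(bundle.expr_high, 10)
        adj_l = cd.build_adjacency(bundle.expr_low, 10)
        consensus = cd.consensus_adjacency([adj_h, adj_l])
        combined = ExpressionMatrix(
            pd.concat([bundle.expr_high.values, bundle.expr_low.values], axis=1)
        )
        part = cd.detect_modules(consensus, combined, min_module_size=30)
        ari = adjusted_rand_score(bundle.truth_partition, part.assignment)
        assert ari >= 0.8


class TestModuleEigengene:
    def test_rank_one_module_reproduces_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        expr = _expr(np.tile(profile, (4, 1)))
        eig = cd.module_eigengene(expr, expr.transcript_ids)
        corr = np.corrcoef(eig, profile)[0, 1]
        assert corr == pytest.approx(1.0)

    def test_sign_oriented_towards_members(self, rng):
        x = rng.normal(size=(6, 12))
        expr = _expr(x)
        eig = cd.module_eigengene(expr, expr.transcript_ids)
        mean_cor = np.mean([np.corrcoef(eig, row)[0, 1] for row in x])
        assert mean_cor >= 0
        flipped = cd.module_eigengene(_expr(-x), expr.transcript_ids)
        assert np.allclose(np.abs(flipped.to_numpy()), np.abs(eig.to_numpy()))

    def test_matches_svd_oracle(self, rng):
        x = rng.normal(size=(5, 6))
        expr = _expr(x)
        eig = cd.module_eigengene(expr, expr.transcript_ids).to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        oracle = vt[0]
        agreement = min(np.abs(eig - oracle).max(), np.abs(eig + oracle).max())
        assert agreement < 1e-10

    def test_constant_members_rejected(self):
        expr = _expr(np.ones((3, 5)))
        with pytest.raises(ValueError):
            cd.module_eigengene(expr, expr.transcript_ids)


class TestValidateModules:
    def test_planted_dense_block_maximally_significant(self, rng):
        n, size = 60, 12
        w = rng.uniform(0, 0.05, size=(n, n))
        w = (w + w.T) / 2
        w[:size, :size] = 0.9
        np.fill_diagonal(w, 0.0)
        ids = pd.Index([f"P{i}" for i in range(n)])
        adj = cd.AdjacencyNetwork(w, ids, 1.0)
        labels = pd.Series(["m1"] * size + [cd.GREY] * (n - size), index=ids)
        p = cd.validate_modules(adj, cd.ModulePartition(labels), n_perm=200, seed=3)
        assert p["m1"] == pytest.approx(1 / 201)

    def test_random_subset_of_homogeneous_network_null_calibrated(self, rng):
        n = 80
        w = rng.uniform(0.2, 0.4, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        ids = pd.Index([f"P{i}" for i in range(n)])
        adj = cd.AdjacencyNetwork(w, ids, 1.0)
        ps = []
        for seed in range(20):
            members = np.random.default_rng(seed).choice(n, 15, replace=False)
            labels = pd.Series(cd.GREY, index=ids)
            labels.iloc[members] = "m1"
            p = cd.validate_modules(adj, cd.ModulePartition(labels),
                                    n_perm=200, seed=seed)
            ps.append(p["m1"])
        assert 0.3 <= np.median(ps) <= 0.7

    def test_observed_mean_adjacency_hand_arithmetic(self):
        w = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]])
        ids = pd.Index(["a", "b", "c"])
        adj = cd.AdjacencyNetwork(w, ids, 1.0)
        from coexdisrupt.network import _mean_within_adjacency

        # 3 ordered pairs x 2 = sum 2.4 over 6 ordered entries = 0.4
        assert _mean_within_adjacency(w, np.arange(3)) == pytest.approx(
            (0.2 + 0.4 + 0.6) / 3
        )
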