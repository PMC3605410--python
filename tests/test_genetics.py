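"""AMOVA, classical MDS, founder-origin HMM (vs path enumeration) and
allelic-imbalance scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import coexdisrupt as cd
from coexdisrupt.containers import GenotypeSet
from coexdisrupt.genetics import fisher_table_test


def _genos(dosages, groups):
    dosages = np.asarray(dosages)
    samples = [f"S{j}" for j in range(dosages.shape[0])]
    markers = [f"M{m}" for m in range(dosages.shape[1])]
    return GenotypeSet(
        pd.DataFrame(dosages, index=samples, columns=markers),
        pd.Series(groups, index=samples),
    )


class TestAmova:
    def test_manhattan_worked_example(self):
        g = _genos([[0, 1, 2], [2, 1, 0], [0, 1, 2], [2, 1, 0]],
                   ["High", "High", "Low", "Low"])
        d = cd.manhattan_distances(g)
        assert d[0, 1] == pytest.approx(4.0)
        assert d[0, 2] == pytest.approx(0.0)

    def test_fixed_alternative_alleles_maximally_significant(self):
        high = np.tile([0, 0, 0, 0, 0, 0], (6, 1))
        low = np.tile([2, 2, 2, 2, 2, 2], (6, 1))
        g = _genos(np.vstack([high, low]), ["High"] * 6 + ["Low"] * 6)
        res = cd.amova(g, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_null_calibrated_without_group_shift(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dos = rng.integers(0, 3, size=(24, 60))
            g = _genos(dos, ["High"] * 12 + ["Low"] * 12)
            res = cd.amova(g, n_perm=199, seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections <= 2  # p > 0.05 in >= 90% of seeds

    def test_f_invariant_to_within_group_relabeling(self, rng):
        dos = rng.integers(0, 3, size=(10, 30))
        g1 = _genos(dos, ["High"] * 5 + ["Low"] * 5)
        shuffled = np.vstack([dos[[3, 1, 4, 0, 2]], dos[[7, 9, 5, 8, 6]]])
        g2 = _genos(shuffled, ["High"] * 5 + ["Low"] * 5)
        a = cd.amova(g1, n_perm=99, seed=0)
        b = cd.amova(g2, n_perm=99, seed=0)
        assert a.f_statistic == pytest.approx(b.f_statistic)

    def test_triangle_inequality_spot_check(self, rng):
        dos = rng.integers(0, 3, size=(6, 25))
        d = cd.manhattan_distances(_genos(dos, ["High"] * 3 + ["Low"] * 3))
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_tiny_group_rejected(self):
        g = _genos([[0, 1], [1, 2], [2, 0]], ["High", "Low", "Low"])
        with pytest.raises(ValueError):
            cd.amova(g, n_perm=99)


class TestMds:
    def test_all_zero_distances_collapse_to_origin(self):
        out = cd.mds_embed(np.zeros((4, 4)), k=2)
        assert np.allclose(out, 0.0)

    def test_recovers_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0], [0.0, 4.0]])
        d = squareform(pdist(pts))
        coords = cd.mds_embed(d, k=2)
        assert np.allclose(squareform(pdist(coords)), d, atol=1e-8)

    def test_collinear_points_are_one_dimensional(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(pts))
        coords = cd.mds_embed(d, k=1)
        assert np.allclose(squareform(pdist(coords)), d, atol=1e-8)
        with pytest.raises(ValueError):
            cd.mds_embed(d, k=2)  # only one positive eigenvalue


def hmm_posterior_by_enumeration(dosages, panel, error_rate, switch_prob):
    """Sum over every founder path (brute force) on a tiny marker set."""
    n_founders, n_markers = panel.shape
    stay = 1 - switch_prob
    switch = switch_prob / (n_founders - 1)
    post = np.zeros((n_markers, n_founders))
    total = 0.0
    for path in itertools.product(range(n_founders), repeat=n_markers):
        prob = 1.0 / n_founders
        for m, state in enumerate(path):
            emit = (1 - error_rate) if panel[state, m] == dosages[m] else error_rate
            prob *= emit
            if m > 0:
                prob *= stay if path[m] == path[m - 1] else switch
        total += prob
        for m, state in enumerate(path):
            post[m, state] += prob
    return post / total


class TestFounderOrigin:
    def test_single_founder_posterior_is_one(self):
        panel = pd.DataFrame([[0, 2, 0, 2]], index=["F0"],
                             columns=[f"M{m}" for m in range(4)])
        g = _genos([[0, 2, 0, 2], [0, 0, 0, 2]], ["High", "Low"])
        post = cd.infer_founder_origin(g, panel)
        assert np.allclose(post.probabilities, 1.0)

    def test_posteriors_sum_to_one(self):
        b = cd.simulate_genotypes(n_founders=3, n_markers=60, n_intervals=6,
                                  n_samples_per_group=5, ploidy=1, seed=2)
        post = cd.infer_founder_origin(b.genotypes, b.founder_panel,
                                       interval_bounds=b.interval_bounds)
        assert np.allclose(post.probabilities.sum(axis=2), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n_markers", [4, 6, 8])
    def test_matches_path_enumeration(self, n_markers, rng):
        panel_alleles = rng.integers(0, 2, size=(3, n_markers))
        panel = pd.DataFrame(2 * panel_alleles, index=["F0", "F1", "F2"],
                             columns=[f"M{m}" for m in range(n_markers)])
        dosages = 2 * rng.integers(0, 2, size=(2, n_markers))
        g = _genos(dosages, ["High", "Low"])
        post = cd.infer_founder_origin(g, panel, error_rate=0.05,
                                       switch_prob=0.1)
        for s in range(2):
            oracle = hmm_posterior_by_enumeration(
                dosages[s], panel.to_numpy(), 0.05, 0.1
            )
            assert np.allclose(post.probabilities[s], oracle, atol=1e-10)

    def test_two_founder_mosaic_accuracy(self):
        b = cd.simulate_genotypes(
            n_founders=2, n_markers=500, n_intervals=25,
            n_samples_per_group=10, recomb_prob=0.02,
            n_shifted_intervals=0, ploidy=1, seed=13,
        )
        post = cd.infer_founder_origin(
            b.genotypes, b.founder_panel, error_rate=0.01,
            switch_prob=0.02, interval_bounds=b.interval_bounds,
        )
        accuracy = (post.argmax == b.truth_origin[:, :, 0]).mean()
        assert accuracy >= 0.95

    def test_diploid_mode_recovers_homozygous_truth(self):
        b = cd.simulate_genotypes(
            n_founders=2, n_markers=200, n_intervals=10,
            n_samples_per_group=5, recomb_prob=0.02,
            n_shifted_intervals=0, ploidy=1, seed=3,
        )
        post = cd.infer_founder_origin(
            b.genotypes, b.founder_panel, error_rate=0.01,
            switch_prob=0.02, interval_bounds=b.interval_bounds, diploid=True,
        )
        accuracy = (post.argmax == b.truth_origin[:, :, 0]).mean()
        assert accuracy >= 0.9

    def test_mismatched_markers_rejected(self):
        panel = pd.DataFrame([[0, 2]], index=["F0"], columns=["MA", "MB"])
        g = _genos([[0, 2]], ["High"])
        with pytest.raises(ValueError):
            cd.infer_founder_origin(g, panel)


class TestFisherTable:
    def test_disjoint_two_by_two_enumeration(self):
        # all mass on the diagonal: p = 2 / C(6,3) = 0.1
        p = fisher_table_test(np.array([[3, 0], [0, 3]]))
        assert p == pytest.approx(0.1)

    def test_independent_table_uninformative(self):
        p = fisher_table_test(np.array([[5, 5], [5, 5]]))
        assert p == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_exact_on_2x2(self):
        table = np.array([[8, 2], [3, 7]])
        exact = fisher_table_test(table)
        # force the Monte-Carlo path by adding an empty-free third column
        # and removing it is not possible; instead call the MC machinery
        # on the same 2x2 via the internal ordering test
        from coexdisrupt.genetics import _log_table_prob

        rng = np.random.default_rng(0)
        row, col = table.sum(1), table.sum(0)
        pool = np.repeat([0, 1], col)
        obs = _log_table_prob(table)
        hits = 0
        n_mc = 20000
        for _ in range(n_mc):
            rng.shuffle(pool)
            sim = np.stack([np.bincount(pool[:row[0]], minlength=2),
                            np.bincount(pool[row[0]:], minlength=2)])
            hits += _log_table_prob(sim) <= obs + 1e-9
        mc = (1 + hits) / (n_mc + 1)
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert abs(mc - exact) <= 3 * se

    def test_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_table_test(np.zeros((2, 3), dtype=int))


class TestImbalanceScan:
    @staticmethod
    def _scan(shift, seed=0, n=50):
        b = cd.simulate_genotypes(
            n_founders=4, n_markers=200, n_intervals=10,
            n_samples_per_group=n, shift_strength=shift,
            n_shifted_intervals=2, ploidy=1, seed=seed,
        )
        post = cd.infer_founder_origin(
            b.genotypes, b.founder_panel, interval_bounds=b.interval_bounds
        )
        scan = cd.allele_imbalance_test(post, b.genotypes.group, seed=seed)
        return b, scan

    def test_shifted_intervals_flagged_and_others_not(self):
        flagged_hits, false_flags, n_seeds = 0, 0, 5
        for seed in range(n_seeds):
            b, scan = self._scan(shift=0.8, seed=seed)
            shifted = sorted(b.shifted_intervals)
            flagged_hits += scan.loc[shifted, "flagged"].all()
            others = scan.drop(index=shifted)
            false_flags += others["flagged"].sum() / len(others)
        assert flagged_hits >= 4  # >= 80% of seeds on this reduced run
        assert false_flags / n_seeds <= 0.1

    def test_identical_distributions_give_p_one(self):
        # two groups with identical founder argmax composition
        probs = np.zeros((8, 1, 2))
        probs[:4, 0, 0] = 1.0
        probs[:4, 0, 1] = 0.0
        probs[4:, 0, 0] = 1.0
        probs[4:, 0, 1] = 0.0
        post = cd.FounderOriginPosterior(
            probabilities=probs,
            sample_ids=pd.Index([f"S{j}" for j in range(8)]),
            founder_names=pd.Index(["F0", "F1"]),
            interval_bounds=[(0, 1)],
        )
        groups = pd.Series(["High"] * 4 + ["Low"] * 4, index=post.sample_ids)
        scan = cd.allele_imbalance_test(post, groups)
        assert scan.loc[0, "p"] == pytest.approx(1.0)

    def test_lowering_fdr_threshold_never_adds_flags(self):
        b, scan_10 = self._scan(shift=0.8, seed=1, n=30)
        post = cd.infer_founder_origin(
            b.genotypes, b.founder_panel, interval_bounds=b.interval_bounds
        )
        scan_05 = cd.allele_imbalance_test(
            post, b.genotypes.group, fdr_threshold=0.05, seed=1
        )
        strict = set(scan_05.index[scan_05["flagged"]])
        loose = set(scan_10.index[scan_10["flagged"]])
        assert strict <= loose
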