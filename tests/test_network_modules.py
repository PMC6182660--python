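"""Co-expression network, modules, eigengenes, subgroups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import plasmasig as ps
from plasmasig.network_modules import _first_pc

from conftest import make_matrix


def tom_oracle(a):
    """Direct-summation implementation of the TOM definition."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def block_matrix(rng, n_blocks=3, block_size=50, within_r=0.8, n_samples=60):
    """Planted correlation blocks via a shared factor per block."""
    load = np.sqrt(within_r)
    noise = np.sqrt(1 - within_r)
    rows, truth = [], []
    for b in range(n_blocks):
        factor = rng.normal(0, 1, n_samples)
        for _ in range(block_size):
            rows.append(load * factor + noise * rng.normal(0, 1, n_samples))
            truth.append(b)
    return make_matrix(np.array(rows)), truth


class TestTopologicalOverlap:
    def test_empty_adjacency(self):
        a = np.zeros((4, 4))
        tom = ps.topological_overlap(a)
        assert np.all(np.diag(tom) == 1.0)
        off = tom[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)

    def test_complete_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = ps.topological_overlap(a)
        # TOM_12 = (1 + 1) / (2 + 1 - 1) = 1
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.uniform(0, 1, (6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            np.testing.assert_allclose(ps.topological_overlap(a),
                                       tom_oracle(a), atol=1e-12)

    def test_output_bounds_and_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = ps.topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.all(np.diag(tom) == 1.0)

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ps.ValidationError):
            ps.topological_overlap(a)


class TestAdjacencyInvariances:
    def test_sample_relabelling_invariant(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (12, 20))
        mat = make_matrix(vals)
        perm = rng.permutation(20)
        permuted = ps.ExpressionMatrix(mat.probe_ids,
                                       [mat.sample_ids[j] for j in perm],
                                       vals[:, perm])
        np.testing.assert_allclose(ps.adjacency_matrix(mat, 6),
                                   ps.adjacency_matrix(permuted, 6),
                                   atol=1e-12)

    def test_unsigned_sign_flip_invariant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (12, 20))
        flipped = vals.copy()
        flipped[::2] *= -1.0
        np.testing.assert_allclose(
            ps.adjacency_matrix(make_matrix(vals), 6),
            ps.adjacency_matrix(make_matrix(flipped), 6), atol=1e-12)


class TestPickSoftThreshold:
    def test_table_covers_candidates_and_includes_12(self):
        rng = np.random.default_rng(4)
        mat, _ = block_matrix(rng, n_blocks=2, block_size=20, n_samples=30)
        config = ps.NetworkConfig()
        table, chosen = ps.pick_soft_threshold(mat, config)
        assert len(table) == len(config.power_candidates)
        assert 12 in set(table["power"])

    def test_scale_free_structure_reaches_r2(self):
        # hub-like loadings give a heavy-tailed connectivity distribution
        rng = np.random.default_rng(5)
        n, m = 300, 50
        loadings = (np.arange(1, n + 1) / n) ** 2.0
        factor = rng.normal(0, 1, m)
        vals = (loadings[:, None] * factor[None, :]
                + np.sqrt(1 - loadings[:, None] ** 2)
                * rng.normal(0, 1, (n, m)))
        table, chosen = ps.pick_soft_threshold(make_matrix(vals),
                                               ps.NetworkConfig())
        assert table["scale_free_r2"].max() > 0.8
        assert chosen is not None

    def test_too_small_input_rejected(self, tiny_matrix):
        with pytest.raises(ps.ValidationError):
            ps.pick_soft_threshold(tiny_matrix, ps.NetworkConfig())


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        mat, truth = block_matrix(rng)
        adj = ps.adjacency_matrix(mat, 12)
        assignment = ps.detect_modules(1.0 - ps.topological_overlap(adj),
                                       ps.NetworkConfig(),
                                       probe_ids=mat.probe_ids, matrix=mat)
        labels = [assignment.labels[p] for p in mat.probe_ids]
        assert len(assignment.module_sizes) == 3
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_pure_noise_mostly_grey(self):
        rng = np.random.default_rng(7)
        mat = make_matrix(rng.normal(0, 1, (120, 40)))
        adj = ps.adjacency_matrix(mat, 12)
        assignment = ps.detect_modules(1.0 - ps.topological_overlap(adj),
                                       ps.NetworkConfig(),
                                       probe_ids=mat.probe_ids)
        grey = sum(1 for v in assignment.labels.values() if v == "grey")
        assert grey / mat.n_probes > 0.5

    def test_small_block_goes_grey(self):
        rng = np.random.default_rng(8)
        mat, truth = block_matrix(rng, n_blocks=1, block_size=10,
                                  n_samples=40)
        noise = make_matrix(rng.normal(0, 1, (60, 40)), probe_prefix="N")
        combined = ps.ExpressionMatrix(
            mat.probe_ids + noise.probe_ids, mat.sample_ids,
            np.vstack([mat.values, noise.values]))
        adj = ps.adjacency_matrix(combined, 12)
        assignment = ps.detect_modules(1.0 - ps.topological_overlap(adj),
                                       ps.NetworkConfig(min_module_size=30),
                                       probe_ids=combined.probe_ids)
        assert all(assignment.labels[p] == "grey" for p in mat.probe_ids)

    def test_fewer_probes_than_min_size_all_grey(self):
        d = np.zeros((5, 5))
        assignment = ps.detect_modules(d, ps.NetworkConfig(min_module_size=30))
        assert set(assignment.labels.values()) == {"grey"}


class TestModuleEigengenes:
    def test_identical_profiles_perfect_correlation(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        mat = make_matrix(np.tile(profile, (4, 1))
                          + np.random.default_rng(0).normal(0, 1e-6, (4, 5)))
        assignment = ps.ModuleAssignment(
            {p: "turquoise" for p in mat.probe_ids},
            module_sizes={"turquoise": 4})
        eig = ps.module_eigengenes(mat, assignment)
        r = np.corrcoef(eig["turquoise"], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(9)
        mat = make_matrix(rng.normal(0, 1, (10, 15)))
        pc = _first_pc(mat)
        x = mat.values
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(x)
        oracle = vt[0]
        assert (np.allclose(pc, oracle, atol=1e-8)
                or np.allclose(pc, -oracle, atol=1e-8))

    def test_sign_convention(self):
        rng = np.random.default_rng(10)
        for seed in range(10):
            mat = make_matrix(np.random.default_rng(seed).normal(0, 1, (8, 12)))
            pc = _first_pc(mat)
            x = mat.values
            x = ((x - x.mean(axis=1, keepdims=True))
                 / x.std(axis=1, keepdims=True))
            assert np.corrcoef(pc, x.mean(axis=0))[0, 1] >= 0

    def test_first_pc_explains_most_variance(self):
        rng = np.random.default_rng(11)
        mat = make_matrix(rng.normal(0, 1, (12, 20)))
        pc = _first_pc(mat)
        x = mat.values
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        var_pc = ((x @ pc) ** 2).sum()
        for _ in range(50):
            v = rng.normal(0, 1, 20)
            v /= np.linalg.norm(v)
            assert var_pc >= ((x @ v) ** 2).sum() - 1e-9

    def test_constant_module_rejected(self):
        mat = make_matrix(np.ones((3, 5)))
        assignment = ps.ModuleAssignment(
            {p: "blue" for p in mat.probe_ids}, module_sizes={"blue": 3})
        with pytest.raises(ps.ValidationError):
            ps.module_eigengenes(mat, assignment)


class TestModuleTraitCorrelation:
    def test_trait_equals_eigengene(self):
        rng = np.random.default_rng(12)
        eig = pd.DataFrame({"turquoise": rng.normal(0, 1, 30)},
                           index=[f"s{i}" for i in range(30)])
        traits = pd.DataFrame({"self": eig["turquoise"]}, index=eig.index)
        out = ps.module_trait_correlation(eig, traits)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] < 1e-20

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(13)
        estimates = []
        for _ in range(30):
            z = rng.normal(0, 1, 74)
            trait = 0.7 * z + np.sqrt(1 - 0.49) * rng.normal(0, 1, 74)
            eig = pd.DataFrame({"m": z}, index=[f"s{i}" for i in range(74)])
            traits = pd.DataFrame({"t": trait}, index=eig.index)
            estimates.append(ps.module_trait_correlation(eig, traits
                                                         ).loc[0, "r"])
        assert abs(np.mean(estimates) - 0.7) < 0.15

    def test_constant_trait_excluded_with_warning(self):
        eig = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        traits = pd.DataFrame({"flat": [1.0, 1.0, 1.0]}, index=eig.index)
        with pytest.warns(UserWarning, match="flat"):
            out = ps.module_trait_correlation(eig, traits)
        assert out.empty

    def test_pairwise_deletion(self):
        eig = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]},
                           index=list("abcd"))
        traits = pd.DataFrame({"t": [1.0, 2.0, np.nan, 4.0]},
                              index=eig.index)
        out = ps.module_trait_correlation(eig, traits)
        assert out.loc[0, "n"] == 3


class TestSubgroupClustering:
    def test_k_one_single_group(self, tiny_matrix):
        out = ps.subgroup_clustering(tiny_matrix, 1)
        assert set(out.labels.values()) == {1}

    def test_duplicated_participants_cluster_together(self):
        rng = np.random.default_rng(14)
        base = rng.normal(0, 1, (30, 3))
        vals = np.hstack([base, base])  # samples 0-2 duplicated as 3-5
        mat = make_matrix(vals)
        out = ps.subgroup_clustering(mat, 3)
        for j in range(3):
            assert out.labels[f"S{j}"] == out.labels[f"S{j + 3}"]

    def test_k_too_large_rejected(self, tiny_matrix):
        with pytest.raises(ps.ValidationError):
            ps.subgroup_clustering(tiny_matrix, 5)

    def test_trial_subgroups_recovered(self, trial_study):
        m = ps.select_high_mad(ps.filter_low_intensity(trial_study.matrix),
                               1500)
        module_probes = [p for probes in
                         trial_study.truth.module_probes.values()
                         for p in probes]
        sub = ps.subgroup_clustering(m.subset_probes(module_probes), 4)
        truth = [trial_study.truth.subgroup[s[:-3]] for s in m.sample_ids]
        got = [sub.labels[s] for s in m.sample_ids]
        assert adjusted_rand_score(truth, got) >= 0.8


class TestSubgroupClinicalComparison:
    def _build(self, rng, shift=0.0, n=15):
        endpoints, records = [], []
        for g in (1, 2):
            for arm in ("treated", "placebo"):
                for i in range(n):
                    pid = f"{arm}{g}_{i}"
                    slope = rng.normal(-0.1 + (shift * 0.05 if
                                               (g == 2 and arm == "treated")
                                               else 0.0), 0.05)
                    endpoints.append(ps.EndpointRecord(
                        participant_id=pid, arm=arm,
                        pct_change_by_visit={3.0: rng.normal(0, 1)},
                        decline_slope=float(slope),
                        baseline_auc=0.5))
                    records.append(ps.SampleRecord(
                        f"{pid}_m0", pid, "TRIAL", arm, 0.0,
                        float(rng.normal(12 + (2.0 * shift if g == 2 else 0),
                                         1.0))))
        labels = {f"{arm}{g}_{i}_m0": g for g in (1, 2)
                  for arm in ("treated", "placebo") for i in range(n)}
        sub = ps.SubgroupAssignment(labels, k=2)
        return sub, endpoints, ps.SampleTable(records)

    def test_planted_benefit_detected(self):
        rng = np.random.default_rng(15)
        hits_t = hits_ks = 0
        reps = 40
        for _ in range(reps):
            sub, eps, samples = self._build(rng, shift=1.5)
            out = ps.subgroup_clinical_comparison(sub, eps, samples)
            tt = out["t_tests"]
            row = tt[(tt.metric == "decline_slope")
                     & (tt.arm_a == "treated") & (tt.arm_b == "treated")
                     & (tt.subgroup_a != tt.subgroup_b)]
            hits_t += bool((row["p_value"] < 0.05).any())
            ks = out["ks_age"]
            krow = ks[(ks.arm_a == ks.arm_b) & (ks.subgroup_a != ks.subgroup_b)]
            hits_ks += bool((krow["p_value"] < 0.05).any())
        assert hits_t / reps >= 0.9
        assert hits_ks / reps >= 0.9

    def test_null_p_values_not_inflated(self):
        rng = np.random.default_rng(16)
        pvals = []
        for _ in range(60):
            sub, eps, samples = self._build(rng, shift=0.0)
            out = ps.subgroup_clinical_comparison(sub, eps, samples)
            tt = out["t_tests"]
            row = tt[(tt.metric == "decline_slope")
                     & (tt.arm_a == "treated") & (tt.arm_b == "treated")]
            pvals.extend(row["p_value"].tolist())
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_subgroup_descriptive_only(self):
        rng = np.random.default_rng(17)
        sub, eps, samples = self._build(rng, n=5)
        # shrink subgroup 2 to one member
        keep = {e.participant_id for e in eps
                if not (e.participant_id.endswith(("_1", "_2", "_3", "_4"))
                        and "2_" in e.participant_id)}
        eps = [e for e in eps if e.participant_id in keep]
        out = ps.subgroup_clinical_comparison(sub, eps, samples)
        tt = out["t_tests"]
        assert not ((tt.subgroup_a == 2) & (tt.subgroup_b == 2)).any()
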