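import itertools

import numpy as np
import pandas as pd
import pytest

import luckydoor as ld
from luckydoor.group_stats import (
    cluster_ttest,
    demographic_comparison,
    fdr_across_maps,
    neurobehavioral_family,
    neurobehavioral_model,
    permutation_cluster_map,
    within_group_spearman,
)
from luckydoor.montage import PARIETAL_CLUSTER


def null_scalars(rng, n1, n2, montage):
    vals = rng.standard_normal((n1 + n2, len(montage.ch_names)))
    scal = pd.DataFrame(vals, index=[f"s{i:03d}" for i in range(n1 + n2)],
                        columns=montage.ch_names)
    contrast = pd.Series([True] * n1 + [False] * n2, index=scal.index)
    return scal, contrast


class TestPermutationClusterMap:
    def test_detected_cluster_contains_injected_channels(self, montage):
        rng = np.random.default_rng(0)
        scal, contrast = null_scalars(rng, 20, 36, montage)
        scal.loc[contrast, list(PARIETAL_CLUSTER)] += 2.0
        res = permutation_cluster_map(scal, contrast, montage, n_perm=500, rng=rng)
        sig = [cl for cl in res.clusters if cl.pvalue < 0.05]
        assert sig and any(set(PARIETAL_CLUSTER) <= set(cl.channels) for cl in sig)

    def test_label_shuffle_before_testing_preserves_null(self, montage):
        # exchangeability: pre-permuting labels on null data changes nothing
        rng = np.random.default_rng(1)
        scal, contrast = null_scalars(rng, 15, 15, montage)
        shuffled = pd.Series(
            rng.permutation(contrast.to_numpy()), index=contrast.index
        )
        a = permutation_cluster_map(scal, contrast, montage, n_perm=300, rng=5)
        b = permutation_cluster_map(scal, shuffled, montage, n_perm=300, rng=5)
        assert abs(a.map_pvalue - b.map_pvalue) < 0.5  # both draws from the same null
        assert (a.map_pvalue < 0.05) == pytest.approx(b.map_pvalue < 0.05, abs=1)

    def test_nan_subjects_excluded_per_electrode(self, montage):
        rng = np.random.default_rng(2)
        scal, contrast = null_scalars(rng, 12, 12, montage)
        scal.iloc[0, 0] = np.nan
        res = permutation_cluster_map(scal, contrast, montage, n_perm=100, rng=rng)
        assert res.dfs[0] == 21  # one subject lost on that electrode
        assert res.dfs[1] == 22

    def test_zero_variance_electrode_excluded(self, montage):
        rng = np.random.default_rng(3)
        scal, contrast = null_scalars(rng, 10, 10, montage)
        scal.iloc[:, 5] = 1.0
        res = permutation_cluster_map(scal, contrast, montage, n_perm=100, rng=rng)
        assert np.isnan(res.tvals[5])

    def test_too_few_subjects_rejected(self, montage):
        rng = np.random.default_rng(4)
        scal, contrast = null_scalars(rng, 1, 10, montage)
        with pytest.raises(ValueError):
            permutation_cluster_map(scal, contrast, montage, n_perm=10, rng=rng)

    def test_clusters_are_adjacency_connected(self, montage):
        rng = np.random.default_rng(5)
        scal, contrast = null_scalars(rng, 20, 20, montage)
        scal.loc[contrast, ["Pz", "P3", "P4", "POz", "O1", "O2"]] += 2.5
        res = permutation_cluster_map(scal, contrast, montage, n_perm=200, rng=rng)
        for cl in res.clusters:
            chans = set(cl.channels)
            for ch in chans:
                if len(chans) > 1:
                    assert montage.neighbors(ch) & chans


def bh_oracle(pvals, q):
    """Brute-force BH step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestFdr:
    def test_all_small_pvalues_rejected(self):
        reject, _ = fdr_across_maps([0.01] * 9, q=0.05)
        assert reject.all()

    def test_single_pvalue_identity(self):
        reject, p_adj = fdr_across_maps([0.04], q=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_only_smallest_survives_sparse_family(self):
        p = [0.001, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        reject, _ = fdr_across_maps(p, q=0.05)
        assert reject[0] and not reject[1:].any()

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for m in range(1, 7):
            for _ in range(200):
                p = rng.uniform(size=m)
                reject, _ = fdr_across_maps(p, q=0.05)
                np.testing.assert_array_equal(reject, bh_oracle(p, 0.05))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_across_maps([0.5, 1.2])


class TestClusterTtest:
    def test_identical_means_give_zero_d(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = cluster_ttest(x, x.copy())
        assert res["t"] == 0 and res["cohen_d"] == 0 and res["p"] == pytest.approx(1.0)

    def test_unit_d_by_definition(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1, 1, 2000)
        y = rng.normal(0, 1, 2000)
        res = cluster_ttest(x, y)
        assert res["cohen_d"] == pytest.approx(1.0, abs=0.08)
        assert res["df"] == 3998

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            cluster_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_d_sampling_distribution(self):
        # n=28/28 with true d=0.75: estimates concentrate around truth
        rng = np.random.default_rng(8)
        ds = [cluster_ttest(rng.normal(0.75, 1, 28), rng.normal(0, 1, 28))["cohen_d"]
              for _ in range(300)]
        within = np.mean(np.abs(np.array(ds) - 0.75) < 0.56)  # ~2 SE(d)
        assert within >= 0.93


def interaction_cohort(rng, coupling_other=0.3, coupling_direct=0.0, n=(27, 21, 27)):
    cov = ld.generate_covariates(n, rng=rng)
    alpha = pd.Series(rng.normal(0, 1, len(cov)), index=cov["subject_id"])
    direct = (cov["group"] == "directly_exposed").to_numpy()
    coupling = np.where(direct, coupling_direct, coupling_other)
    y = coupling * alpha.to_numpy() + rng.normal(0, 0.3, len(cov))
    metrics = pd.DataFrame({"subject_id": cov["subject_id"], "win_stay_expt": y})
    return metrics, cov, alpha


class TestNeurobehavioral:
    def test_interaction_recovered_when_coupling_differs(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(25):
            metrics, cov, alpha = interaction_cohort(rng)
            res = neurobehavioral_model(metrics, cov, alpha)
            term = res.term("group[direct]:neural")
            hits += (term["pvalue"] < 0.05) and (term["beta"] < 0)
        assert hits >= 20  # negative: direct group lacks the positive coupling

    def test_null_coupling_interaction_calibrated(self):
        rng = np.random.default_rng(10)
        rej = 0
        n_rep = 40
        for _ in range(n_rep):
            metrics, cov, alpha = interaction_cohort(rng, coupling_other=0.0)
            res = neurobehavioral_model(metrics, cov, alpha)
            rej += res.term("group[direct]:neural")["pvalue"] < 0.05
        assert rej / n_rep < 0.175  # nominal 5% plus Monte-Carlo slack

    def test_duplicate_neural_column_rejected(self):
        rng = np.random.default_rng(11)
        metrics, cov, alpha = interaction_cohort(rng)
        cov = cov.copy()
        cov["gad7"] = alpha.to_numpy()  # z-scored gad7 duplicates z-scored neural
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            neurobehavioral_model(metrics, cov, alpha)

    def test_family_fdr_columns(self):
        rng = np.random.default_rng(12)
        metrics, cov, alpha = interaction_cohort(rng)
        table = {(e, p): alpha + rng.normal(0, 0.1, len(alpha))
                 for e in ("Pz", "P3") for p in ("choice", "immediate_reward")}
        fam = neurobehavioral_family(metrics, cov, table)
        assert len(fam) == 4
        assert {"interaction_p", "interaction_p_fdr", "significant_fdr"} <= set(fam.columns)
        assert (fam["interaction_p_fdr"] >= fam["interaction_p"] - 1e-12).all()


class TestSpearman:
    def test_perfect_monotone(self):
        cov = ld.generate_covariates((5, 5, 5), rng=13)
        other = cov[cov["group"] != "directly_exposed"]
        x = pd.Series(np.arange(len(other), dtype=float), index=other["subject_id"])
        metrics = pd.DataFrame({"subject_id": other["subject_id"],
                                "win_stay_expt": np.arange(len(other)) ** 2})
        res = within_group_spearman(metrics, x, cov,
                                    ("indirectly_exposed", "non_exposed"))
        assert res["rho"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        cov = ld.generate_covariates((5, 5, 5), rng=14)
        other = cov[cov["group"] != "directly_exposed"]
        x = pd.Series(np.arange(len(other), dtype=float), index=other["subject_id"])
        metrics = pd.DataFrame({"subject_id": other["subject_id"],
                                "win_stay_expt": -np.arange(len(other), dtype=float)})
        res = within_group_spearman(metrics, x, cov,
                                    ("indirectly_exposed", "non_exposed"))
        assert res["rho"] == pytest.approx(-1.0)

    def test_constant_input_reports_nan(self):
        cov = ld.generate_covariates((5, 5, 5), rng=15)
        sub = cov[cov["group"] == "directly_exposed"]
        x = pd.Series(np.ones(len(sub)), index=sub["subject_id"])
        metrics = pd.DataFrame({"subject_id": sub["subject_id"],
                                "win_stay_expt": np.arange(len(sub), dtype=float)})
        res = within_group_spearman(metrics, x, cov, "directly_exposed")
        assert np.isnan(res["rho"])

    def test_null_pairs_calibrated(self):
        rng = np.random.default_rng(16)
        cov = ld.generate_covariates((10, 10, 10), rng=17)
        sub = cov[cov["group"] != "directly_exposed"]
        rhos, rej = [], 0
        for _ in range(100):
            x = pd.Series(rng.normal(size=len(sub)), index=sub["subject_id"])
            metrics = pd.DataFrame({"subject_id": sub["subject_id"],
                                    "win_stay_expt": rng.normal(size=len(sub))})
            res = within_group_spearman(metrics, x, cov,
                                        ("indirectly_exposed", "non_exposed"))
            rhos.append(res["rho"])
            rej += res["p"] < 0.05
        assert abs(np.mean(rhos)) < 0.05
        assert rej / 100 <= 0.12


class TestDemographics:
    def test_chi2_matches_hand_computation(self):
        # 2x2 table (20,10 / 10,20): Yates-corrected chi2 = 4*(|5|-0.5)^2/15 = 5.4
        cov = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "group": ["directly_exposed"] * 30 + ["non_exposed"] * 30,
                "gender": ["male"] * 20 + ["female"] * 10 + ["male"] * 10 + ["female"] * 20,
            }
        )
        res = demographic_comparison(cov, categorical=("gender",), numeric=())
        row = res[res["variable"] == "gender"].iloc[0]
        assert row["statistic"] == pytest.approx(5.4)

    def test_separated_samples_hit_minimal_p(self):
        cov = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "group": ["directly_exposed"] * 5 + ["non_exposed"] * 5,
                "age": [30, 31, 32, 33, 34, 20, 21, 22, 23, 24],
            }
        )
        res = demographic_comparison(cov, categorical=(), numeric=("age",))
        # fully separated rank-sum: |z| = sqrt(12 * n1 * n2 / (N(N+1))) * mean rank gap
        from scipy.stats import ranksums
        z_exact, p_exact = ranksums([30, 31, 32, 33, 34], [20, 21, 22, 23, 24])
        assert res.iloc[0]["pvalue"] == pytest.approx(p_exact)

    def test_identical_distributions_unstarred(self):
        rng = np.random.default_rng(18)
        cov = ld.generate_covariates((30, 20, 30),
                                     effect_config=None, rng=19)
        cov["gad7"] = rng.normal(10, 3, len(cov)).round()  # same in both sides
        res = demographic_comparison(cov, categorical=(), numeric=("gad7",))
        assert res.iloc[0]["stars"] == ""
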