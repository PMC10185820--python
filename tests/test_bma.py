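import numpy as np
import pytest

from gutmr.bma import (
    BmaConfig,
    ExposureMatrix,
    ModelPosterior,
    build_exposure_matrix,
    enumerate_models,
    mip_mace,
    model_posterior,
    run_bma,
    run_bma_iterative,
    snp_diagnostics,
)
from gutmr.harmonize import HarmonizedInstrument, HarmonizedSet
from gutmr.synthetic_data import SyntheticScenario, simulate_multi_exposure


def hset_from(label, rsids, gammas, Gammas, se_Gamma=0.03):
    out = HarmonizedSet(label, "disease")
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    for i, (r, g, G) in enumerate(zip(rsids, gammas, Gammas)):
        a1, a2 = pairs[i % 4]
        out.instruments.append(HarmonizedInstrument(
            rsid=r, gamma=g, se_gamma=0.01, Gamma_out=G, se_Gamma=se_Gamma,
            effect_allele=a1, other_allele=a2,
        ))
    return out


def toy_matrix(seed=0, j=40, k=4, theta=(0.7, 0, 0, 0), cor=0.0):
    scenario = SyntheticScenario(
        j_instruments=j, k_exposures=k, exposure_cor=cor, seed=seed,
    )
    _, _, mat = simulate_multi_exposure(scenario, list(theta))
    return mat


class TestBuildExposureMatrix:
    def test_disjoint_sets_give_complementary_zero_blocks(self):
        a = hset_from("a", ["rs1", "rs2", "rs3"], [0.05] * 3, [0.02] * 3)
        b = hset_from("b", ["rs4", "rs5", "rs6"], [0.06] * 3, [0.01] * 3)
        mat = build_exposure_matrix({"a": a, "b": b})
        assert mat.X.shape == (6, 2)
        assert np.count_nonzero(mat.X) == 6  # one nonzero per row

    def test_identical_sets_have_no_zeros(self):
        rsids = ["rs1", "rs2", "rs3"]
        a = hset_from("a", rsids, [0.05] * 3, [0.02] * 3)
        b = hset_from("b", rsids, [0.06] * 3, [0.02] * 3)
        mat = build_exposure_matrix({"a": a, "b": b})
        assert np.count_nonzero(mat.X) == 6

    def test_study_scale_dimensions(self):
        # four exposures, 41-instrument union: the multivariable design shape
        mat = toy_matrix(j=41, k=4)
        assert mat.X.shape == (41, 4) and mat.y.shape == (41,)

    def test_single_exposure_rejected(self):
        a = hset_from("a", ["rs1"], [0.05], [0.02])
        with pytest.raises(ValueError):
            build_exposure_matrix({"a": a})


class TestEnumerateModels:
    def test_two_exposures_give_three_models(self):
        models = enumerate_models(2, BmaConfig())
        assert sorted(m for m, _ in models) == [(0,), (0, 1), (1,)]

    def test_priors_sum_to_one(self):
        for k in (2, 3, 4, 6):
            models = enumerate_models(k, BmaConfig(prior_inclusion=0.3))
            assert sum(p for _, p in models) == pytest.approx(1.0)

    def test_four_exposures_give_fifteen_models(self):
        assert len(enumerate_models(4, BmaConfig())) == 15

    def test_enumeration_capped(self):
        with pytest.raises(ValueError):
            enumerate_models(21, BmaConfig())


class TestModelPosterior:
    def test_true_singleton_model_wins(self):
        mat = toy_matrix(seed=1)
        summary = run_bma(mat, BmaConfig(seed=1), with_permutation=False)
        best = max(summary.models, key=lambda m: m.pp)
        assert best.subset == (0,)

    def test_pps_sum_to_one(self):
        mat = toy_matrix(seed=2)
        summary = run_bma(mat, BmaConfig(seed=2), with_permutation=False)
        assert sum(m.pp for m in summary.models) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_exposure_splits_inclusion_mass(self):
        mat = toy_matrix(seed=3, k=3, theta=(0.7, 0, 0))
        dup = ExposureMatrix(
            snp_ids=list(mat.snp_ids),
            exposure_labels=mat.exposure_labels + ["copy"],
            X=np.column_stack([mat.X, mat.X[:, 0]]),
            y=mat.y, se_y=mat.se_y,
        )
        base = run_bma(mat, BmaConfig(seed=3), with_permutation=False)
        split = run_bma(dup, BmaConfig(seed=3), with_permutation=False)
        assert split.mip[0] < base.mip[0]
        assert split.mip[3] < base.mip[0]
        # joint inclusion (either copy) stays comparable to the original
        joint = sum(m.pp for m in split.models if 0 in m.subset or 3 in m.subset)
        assert joint == pytest.approx(base.mip[0], abs=0.2)

    def test_vanishing_prior_sd_lets_the_prior_dominate(self):
        mat = toy_matrix(seed=4)
        cfg = BmaConfig(prior_inclusion=0.25, prior_sd=1e-8)
        models = enumerate_models(4, cfg)
        summary = run_bma(mat, cfg, with_permutation=False)
        prior = {m: p for m, p in models}
        for mp in summary.models:
            assert mp.pp == pytest.approx(prior[mp.subset], rel=1e-3)

    def test_scale_invariance_of_pps_and_ranks(self):
        mat = toy_matrix(seed=5)
        scaled = ExposureMatrix(
            snp_ids=list(mat.snp_ids), exposure_labels=list(mat.exposure_labels),
            X=mat.X, y=3.0 * mat.y, se_y=3.0 * mat.se_y,
        )
        a = run_bma(mat, BmaConfig(seed=5), with_permutation=False)
        b = run_bma(scaled, BmaConfig(seed=5), with_permutation=False)
        # prior_sd is held fixed, so PPs shift slightly, but ranking is stable
        assert list(a.rank_by_mip) == list(b.rank_by_mip)


class TestMipMace:
    def test_single_certain_model(self):
        models = [ModelPosterior((0,), 1.0, (0.42,))]
        mip, mace, rank = mip_mace(models, 3)
        assert mip.tolist() == [1.0, 0.0, 0.0]
        assert mace[0] == pytest.approx(0.42)
        assert rank[0] == 1

    def test_hand_summed_toy_pps(self):
        models = [
            ModelPosterior((0,), 0.5, (0.4,)),
            ModelPosterior((1,), 0.3, (0.2,)),
            ModelPosterior((0, 1), 0.2, (0.5, 0.1)),
        ]
        mip, mace, rank = mip_mace(models, 2)
        assert mip.tolist() == pytest.approx([0.7, 0.5])
        assert mace.tolist() == pytest.approx([0.5 * 0.4 + 0.2 * 0.5,
                                               0.3 * 0.2 + 0.2 * 0.1])
        assert rank.tolist() == [1, 2]

    def test_mip_equals_sum_over_containing_models(self):
        mat = toy_matrix(seed=6, cor=0.3)
        summary = run_bma(mat, BmaConfig(seed=6), with_permutation=False)
        for k in range(4):
            direct = sum(m.pp for m in summary.models if k in m.subset)
            assert summary.mip[k] == pytest.approx(direct, abs=1e-12)

    def test_ranks_are_a_permutation(self):
        mat = toy_matrix(seed=7)
        summary = run_bma(mat, BmaConfig(seed=7), with_permutation=False)
        assert sorted(summary.rank_by_mip) == [1, 2, 3, 4]


class TestSnpDiagnostics:
    def test_perfect_fit_gives_zero_q(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.03, 0.08, size=(12, 2))
        theta = np.array([0.5, 0.0])
        mat = ExposureMatrix(
            snp_ids=[f"rs{i}" for i in range(12)], exposure_labels=["a", "b"],
            X=X, y=X @ theta, se_y=np.full(12, 0.03),
        )
        cfg = BmaConfig(prior_sd=50.0)  # negligible shrinkage
        logpp, est = model_posterior(mat, (0,), cfg)
        q, _ = snp_diagnostics(mat, [ModelPosterior((0,), 1.0, tuple(est))], cfg)
        assert np.all(q < 1e-3)

    def test_four_sigma_residual_exceeds_q_threshold(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0.03, 0.08, size=(12, 2))
        y = X @ np.array([0.5, 0.0])
        se_y = np.full(12, 0.03)
        y[5] += 4 * se_y[5]
        mat = ExposureMatrix(
            snp_ids=[f"rs{i}" for i in range(12)], exposure_labels=["a", "b"],
            X=X, y=y, se_y=se_y,
        )
        cfg = BmaConfig(prior_sd=50.0)
        _, est = model_posterior(mat, (0,), cfg)
        q, _ = snp_diagnostics(mat, [ModelPosterior((0,), 1.0, tuple(est))], cfg)
        assert q[5] > 10
        assert np.argmax(q) == 5

    def test_rerun_after_removal_reports_all_q_below_threshold(self):
        mat = toy_matrix(seed=10)
        bumped = mat.y.copy()
        bumped[7] += 8 * mat.se_y[7]
        mat = ExposureMatrix(mat.snp_ids, mat.exposure_labels, mat.X, bumped,
                             mat.se_y)
        cfg = BmaConfig(seed=10)
        iters = run_bma_iterative(mat, cfg, with_permutation=False)
        final = iters[-1]
        best = [m for m in final.models if m.pp >= cfg.pp_threshold]
        q, _ = snp_diagnostics(
            iters[0].models and _final_matrix(mat, iters), best, cfg
        )
        assert np.all(q <= cfg.q_threshold)


def _final_matrix(mat, iters):
    removed = set()
    for s in iters:
        removed |= set(s.excluded_snps)
    return mat.drop_snps(removed)


class TestPermutationPvalues:
    def test_granularity_is_multiples_of_one_over_101(self):
        mat = toy_matrix(seed=11, j=20)
        cfg = BmaConfig(seed=11, n_perm=100)
        summary = run_bma(mat, cfg)
        for p in summary.perm_pval:
            assert (p * 101) == pytest.approx(round(p * 101), abs=1e-9)
            assert p >= 1 / 101

    def test_dominant_exposure_attains_minimum_p(self):
        mat = toy_matrix(seed=12)
        cfg = BmaConfig(seed=12, n_perm=100)
        summary = run_bma(mat, cfg)
        assert summary.perm_pval[0] == pytest.approx(1 / 101)

    def test_null_exposure_p_is_roughly_uniform(self):
        # all-null design: average permutation p over scenario repeats ~ 0.5
        ps = []
        for seed in range(40):
            mat = toy_matrix(seed=70_000 + seed, j=20, theta=(0, 0, 0, 0))
            cfg = BmaConfig(seed=seed, n_perm=50)
            summary = run_bma(mat, cfg)
            ps.extend(summary.perm_pval)
        assert 0.4 <= float(np.mean(ps)) <= 0.6


class TestIterativeLoop:
    def test_clean_data_converges_in_one_iteration(self):
        mat = toy_matrix(seed=13)
        iters = run_bma_iterative(mat, BmaConfig(seed=13), with_permutation=False)
        assert len(iters) == 1
        assert iters[0].excluded_snps == []

    def test_planted_outlier_removed_in_exactly_two_iterations(self):
        mat = toy_matrix(seed=15)
        bumped = mat.y.copy()
        bumped[3] += 8 * mat.se_y[3]
        mat2 = ExposureMatrix(mat.snp_ids, mat.exposure_labels, mat.X, bumped,
                              mat.se_y)
        iters = run_bma_iterative(mat2, BmaConfig(seed=15), with_permutation=False)
        assert len(iters) == 2
        assert mat.snp_ids[3] in iters[0].excluded_snps
        assert iters[1].n_snps == mat.n_snps - len(iters[0].excluded_snps)

    def test_ranking_recovery_under_correlated_exposures(self):
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            mat = toy_matrix(seed=80_000 + seed, j=41, cor=0.3)
            summary = run_bma(mat, BmaConfig(seed=seed), with_permutation=False)
            wins += summary.rank_by_mip[0] == 1
        assert wins >= int(0.8 * n_rep)
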