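"""AR(1) likelihood, group models, LR tests, permutation thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from leafqtl.efd import efd_reconstruct
from leafqtl.errors import PipelineError
from leafqtl.popgen import GenotypeMatrix
from leafqtl.scan import (
    ARCovParams,
    MarkerSkippedError,
    ShapePhenotype,
    ar1_loglik,
    fit_group_model,
    genome_scan,
    lr_test,
    permutation_threshold,
    snp_heritability,
)
from leafqtl.simulate import _ar1_noise, default_base_shape


def make_phenotypes(n, noise_sd=0.02, rho=0.0, rng=None, k=70, deme="high",
                    transform=None):
    """Phenotypes around the default ovate mean with AR(1) landmark noise."""
    rng = rng or np.random.default_rng(0)
    base = efd_reconstruct(default_base_shape(k), k).points
    out = []
    for i in range(n):
        pts = base.copy() if transform is None else transform(i, base.copy())
        if noise_sd > 0:
            pts[:, 0] += _ar1_noise(rng, k, noise_sd, rho)
            pts[:, 1] += _ar1_noise(rng, k, noise_sd, rho)
        out.append(
            ShapePhenotype(
                line_id=f"L{i:04d}", deme=deme,
                z=np.concatenate([pts[:, 0], pts[:, 1]]),
            )
        )
    return out


def make_gmatrix(calls: np.ndarray, line_ids) -> GenotypeMatrix:
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    if calls.shape[0] != len(line_ids):
        calls = calls.T
    m = calls.shape[1]
    markers = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "id": [f"M{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "neutrality": ["intergenic"] * m,
            "annotation": [""] * m,
        }
    )
    return GenotypeMatrix(line_ids, calls, markers)


class TestAR1Loglik:
    def test_standard_normal_at_mode(self):
        assert ar1_loglik([0.0, 0.0], 1.0, 0.0) == pytest.approx(
            -np.log(2 * np.pi), abs=1e-10
        )

    def test_independent_unit_residuals(self):
        assert ar1_loglik([1.0, 1.0], 1.0, 0.0) == pytest.approx(
            -np.log(2 * np.pi) - 1.0, abs=1e-10
        )

    def test_correlated_case_dense_oracle_value(self):
        # dense 2x2 covariance oracle: -ln(2pi) + 0.1438 - 0.6667
        assert ar1_loglik([1.0, 1.0], 1.0, 0.5) == pytest.approx(-2.3607, abs=1e-4)

    @pytest.mark.parametrize("k", [2, 5, 12])
    @pytest.mark.parametrize("rho", [-0.8, 0.0, 0.3, 0.9])
    @pytest.mark.parametrize("sigma2", [0.5, 2.0])
    def test_matches_dense_mvn_density(self, k, rho, sigma2):
        rng = np.random.default_rng(k * 100 + int(rho * 10) + int(sigma2))
        e = rng.standard_normal(k)
        cov = sigma2 * rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        oracle = sps.multivariate_normal(mean=np.zeros(k), cov=cov).logpdf(e)
        assert ar1_loglik(e, sigma2, rho) == pytest.approx(oracle, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ar1_loglik([1.0, 1.0], 1.0, 1.0)
        with pytest.raises(ValueError):
            ar1_loglik([1.0, 1.0], 0.0, 0.5)
        with pytest.raises(ValueError):
            ar1_loglik([1.0], 1.0, 0.5)

    def test_cov_params_validated(self):
        with pytest.raises(ValueError):
            ARCovParams(sigma2_x=1.0, rho_x=1.2, sigma2_y=1.0, rho_y=0.0)


class TestFitGroupModel:
    def test_iid_noise_gives_near_zero_rho(self):
        phen = make_phenotypes(60, noise_sd=0.01, rho=0.0,
                               rng=np.random.default_rng(7))
        fit = fit_group_model(phen, {p.line_id: "all" for p in phen}, 4,
                              min_group_size=1)
        assert abs(fit.cov.rho_x) < 0.1
        assert abs(fit.cov.rho_y) < 0.1
        assert fit.converged

    def test_planted_autocorrelation_recovered(self):
        phen = make_phenotypes(100, noise_sd=0.02, rho=0.7,
                               rng=np.random.default_rng(3))
        fit = fit_group_model(phen, {p.line_id: "all" for p in phen}, 4,
                              min_group_size=1)
        assert fit.cov.rho_x == pytest.approx(0.7, abs=0.1)
        assert fit.cov.rho_y == pytest.approx(0.7, abs=0.1)

    def test_identical_groups_have_equal_likelihoods(self):
        phen = make_phenotypes(30, rng=np.random.default_rng(11))
        doubled = phen + [
            ShapePhenotype(line_id=f"B{p.line_id}", deme=p.deme, z=p.z.copy())
            for p in phen
        ]
        null = fit_group_model(doubled, {p.line_id: "all" for p in doubled}, 4,
                               min_group_size=1)
        split = fit_group_model(
            doubled,
            {p.line_id: p.line_id.startswith("B") for p in doubled},
            4, min_group_size=1,
        )
        assert split.loglik == pytest.approx(null.loglik, abs=1e-6)

    def test_small_group_rejected(self):
        phen = make_phenotypes(10)
        grouping = {p.line_id: (0 if i < 8 else 1) for i, p in enumerate(phen)}
        with pytest.raises(ValueError, match="min_group_size"):
            fit_group_model(phen, grouping, 4, min_group_size=5)

    def test_zero_residuals_degenerate(self):
        from leafqtl.errors import DegenerateDataError

        k = 70
        base = efd_reconstruct(default_base_shape(k), k).points
        # phenotypes exactly on the order-4 mean curve: residuals vanish
        from leafqtl.efd import fit_ef_curve

        _, fitted = fit_ef_curve(base, 4)
        phen = [
            ShapePhenotype(line_id=f"L{i}", deme="h",
                           z=np.concatenate([fitted[:, 0], fitted[:, 1]]))
            for i in range(6)
        ]
        with pytest.raises(DegenerateDataError):
            fit_group_model(phen, {p.line_id: "a" for p in phen}, 4,
                            min_group_size=1)


class TestLRTest:
    def test_label_renaming_invariance(self):
        rng = np.random.default_rng(21)
        phen = make_phenotypes(60, rng=rng)
        calls = np.array([0] * 30 + [2] * 30)
        lr1, _ = lr_test(phen, calls, 4)
        lr2, _ = lr_test(phen, 2 - calls, 4)
        assert lr1 == pytest.approx(lr2, abs=1e-9)

    def test_null_lr_small_relative_to_parameter_count(self):
        # homogeneous sample, arbitrary labels: LR stays well below twice the
        # number of extra mean parameters (18 for two genotype groups, order 4)
        lrs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            phen = make_phenotypes(60, rng=rng)
            calls = rng.permutation(np.array([0] * 30 + [2] * 30))
            lr, _ = lr_test(phen, calls, 4)
            lrs.append(lr)
        assert np.median(lrs) < 2 * 18

    def test_null_lr_tracks_chisq_envelope(self):
        # under H0 the LR distribution tracks chi-square with
        # df = 4*order*(J-1) + 2 (a sanity envelope, not an inference rule;
        # finite samples inflate the statistic by a few percent, hence the
        # explicit 10% slack on the upper-tail check)
        lrs = []
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            phen = make_phenotypes(40, rng=rng, noise_sd=0.03)
            calls = rng.permutation(np.array([0] * 20 + [2] * 20))
            lr, _ = lr_test(phen, calls, 4)
            lrs.append(lr)
        df = 4 * 4 * (2 - 1) + 2
        assert np.quantile(lrs, 0.9) <= 1.1 * sps.chi2.ppf(0.9, df)
        assert np.median(lrs) >= 0.5 * sps.chi2.ppf(0.5, df)

    def test_planted_width_effect_detected(self):
        rng = np.random.default_rng(31)
        calls = rng.binomial(2, 0.4, size=150)

        def widen(i, pts):
            pts[:, 0] *= 1.0 + 0.10 * calls[i] / 2.0
            return pts

        phen = make_phenotypes(150, noise_sd=0.02, rho=0.5, rng=rng,
                               transform=widen)
        lr, fit = lr_test(phen, calls, 4)
        assert lr > 100  # overwhelming signal vs permutation scale (~25)
        assert set(fit.means) == {0, 1, 2}

    def test_single_group_skipped(self):
        phen = make_phenotypes(20)
        with pytest.raises(MarkerSkippedError):
            lr_test(phen, np.zeros(20, dtype=int), 4)

    def test_missing_genotypes_dropped(self):
        rng = np.random.default_rng(5)
        phen = make_phenotypes(40, rng=rng)
        calls = np.array([0] * 18 + [2] * 18 + [-1] * 4)
        lr_missing, _ = lr_test(phen, calls, 4)
        lr_subset, _ = lr_test(phen[:36], calls[:36], 4)
        assert lr_missing == pytest.approx(lr_subset, abs=1e-9)


class TestGenomeScan:
    def test_duplicated_markers_get_identical_lr(self):
        rng = np.random.default_rng(41)
        phen = make_phenotypes(50, rng=rng)
        col = rng.binomial(2, 0.4, size=50)
        g = make_gmatrix(np.column_stack([col, col, rng.binomial(1, 0.5, 50)]),
                         [p.line_id for p in phen])
        res = genome_scan(phen, g, 4)
        t = res.table.set_index("marker")
        assert t.loc["M0", "lr"] == t.loc["M1", "lr"]

    def test_untestable_markers_recorded_not_lost(self):
        rng = np.random.default_rng(43)
        phen = make_phenotypes(30, rng=rng)
        g = make_gmatrix(
            np.column_stack(
                [np.zeros(30, dtype=int), rng.binomial(1, 0.5, 30)]
            ),
            [p.line_id for p in phen],
        )
        res = genome_scan(phen, g, 4)
        t = res.table.set_index("marker")
        assert bool(t.loc["M0", "skipped"])
        assert not bool(t.loc["M1", "skipped"])

    def test_all_markers_untestable_is_pipeline_error(self):
        phen = make_phenotypes(20)
        g = make_gmatrix(np.zeros((20, 3), dtype=int), [p.line_id for p in phen])
        with pytest.raises(PipelineError):
            genome_scan(phen, g, 4)


class TestPermutationThreshold:
    def _setup(self, seed=51, n=50, m=10):
        rng = np.random.default_rng(seed)
        phen = make_phenotypes(n, rng=rng)
        calls = rng.binomial(2, 0.4, size=(n, m))
        g = make_gmatrix(calls, [p.line_id for p in phen])
        return phen, g

    def test_deterministic_given_seed(self):
        phen, g = self._setup()
        t1 = permutation_threshold(phen, g, "intercross", n_perm=30, seed=9)
        t2 = permutation_threshold(phen, g, "intercross", n_perm=30, seed=9)
        assert t1 == t2

    def test_threshold_monotone_in_alpha(self):
        phen, g = self._setup()
        kwargs = dict(n_perm=50, seed=2)
        t01 = permutation_threshold(phen, g, "intercross", alpha=0.01, **kwargs)
        t05 = permutation_threshold(phen, g, "intercross", alpha=0.05, **kwargs)
        t_all = permutation_threshold(phen, g, "intercross", alpha=1.0, **kwargs)
        assert t01 >= t05 >= t_all

    def test_zero_permutations_rejected(self):
        phen, g = self._setup()
        with pytest.raises(ValueError):
            permutation_threshold(phen, g, "intercross", n_perm=0)

    def test_per_marker_variant_returns_mapping(self):
        phen, g = self._setup(m=4)
        out = permutation_threshold(phen, g, "intercross", n_perm=20, seed=3,
                                    per_marker=True)
        assert set(out) <= set(g.markers["id"])
        assert all(v >= 0 for v in out.values())


class TestSNPHeritability:
    def test_equal_group_means_give_zero(self):
        y = np.array([1.0, 2.0, 1.0, 2.0])
        g = np.array([0, 0, 2, 2])
        assert snp_heritability(y, g) == pytest.approx(0.0)

    def test_fully_determined_trait_gives_one(self):
        g = np.array([0, 0, 1, 1, 2, 2])
        assert snp_heritability(g.astype(float), g) == pytest.approx(1.0)

    def test_additive_biallelic_closed_form(self):
        rng = np.random.default_rng(5)
        n, p, a = 2000, 0.3, 0.5
        g = rng.binomial(2, p, n)
        y = a * g + rng.normal(0, 1, n)
        var_g = 2 * p * (1 - p) * a**2
        oracle = var_g / (var_g + 1.0)
        assert snp_heritability(y, g) == pytest.approx(oracle, abs=0.02)

    def test_constant_trait_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert snp_heritability(np.ones(10), np.array([0] * 5 + [2] * 5)) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            snp_heritability(np.arange(4, dtype=float), np.zeros(4, dtype=int))
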