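"""Segregation typing, HWE exact test, marker filters, FST/QST, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from leafqtl.errors import AliasedTermError, UndefinedStatisticError
from leafqtl.popgen import (
    FilterConfig,
    MarkerRecord,
    VarianceComponents,
    classify_segregation,
    deme_variance_components,
    filter_markers,
    hwe_exact_pvalue,
    nm_from_fst,
    qst,
    shape_anova,
    weir_cockerham_fst,
)


def make_record(genotypes, depths=None, **kw) -> MarkerRecord:
    g = np.asarray(genotypes, dtype=np.int8)
    defaults = dict(chrom="1", pos=100, id="M1", ref="A", alt="G",
                    neutrality="intergenic")
    defaults.update(kw)
    return MarkerRecord(
        genotypes=g,
        depths=None if depths is None else np.asarray(depths),
        **defaults,
    )


class TestClassifySegregation:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"hom_ref": 50, "het": 50, "hom_alt": 0}, "testcross"),
            ({"hom_ref": 30, "het": 50, "hom_alt": 20}, "intercross"),
            ({"hom_ref": 100, "het": 0, "hom_alt": 0}, "monomorphic"),
            ({"hom_ref": 0, "het": 100, "hom_alt": 0}, "monomorphic"),
            ({"hom_ref": 40, "het": 0, "hom_alt": 60}, "intercross"),
        ],
    )
    def test_genotype_class_rules(self, counts, expected):
        assert classify_segregation(counts) == expected


def hwe_enumeration_oracle(n_aa, n_ab, n_bb) -> float:
    """Brute-force exact test: enumerate all heterozygote counts with the
    observed allele counts, exact probabilities via math.comb."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    for het in range(na % 2, min(na, 2 * n - na) + 1, 2):
        hom_a = (na - het) // 2
        hom_b = n - het - hom_a
        if hom_a < 0 or hom_b < 0:
            continue
        probs[het] = (
            math.comb(n, hom_a) * math.comb(n - hom_a, het) * 2**het
            / math.comb(2 * n, na)
        )
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))


class TestHWEExact:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_pvalue(100, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(2, 0, 2), (5, 2, 5), (20, 10, 5), (1, 7, 1), (0, 3, 8)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_extreme_het_excess_tiny_pvalue(self):
        assert hwe_exact_pvalue(0, 100, 0) < 1e-6

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    def test_pvalue_in_unit_interval(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_pvalue(a, b, c)
        assert 0.0 < p <= 1.0


class TestFilterMarkers:
    def _good_depths(self, n, d=20):
        return np.full(n, d)

    def test_boundary_depth_exactly_twelve_rejected(self):
        rec = make_record([0] * 50 + [1] * 30 + [2] * 20,
                          depths=self._good_depths(100, 12))
        kept, tally = filter_markers([rec])
        assert kept == [] and tally["depth"] == 1

    def test_boundary_maf_exactly_five_percent_rejected(self):
        # 10 het among 100 diploids, rest hom_ref: alt frequency exactly 0.05
        rec = make_record([1] * 10 + [0] * 90, depths=self._good_depths(100))
        kept, tally = filter_markers([rec])
        assert kept == [] and tally["maf"] == 1

    def test_clean_marker_retained(self):
        rng = np.random.default_rng(1)
        g = rng.choice([0, 1, 2], size=100, p=[0.49, 0.42, 0.09])
        g[:9] = -1  # 9% missing
        rec = make_record(g, depths=self._good_depths(100))
        kept, tally = filter_markers([rec])
        assert len(kept) == 1 and tally["retained"] == 1

    def test_het_excess_filter_spares_hwe_intercross(self):
        # HWE proportions at p=0.5: 25/50/25 — a literal observed-het cap
        # would reject every such intercross SNP; the excess rule keeps it
        g = [0] * 25 + [1] * 50 + [2] * 25
        rec = make_record(g, depths=self._good_depths(100))
        kept, _ = filter_markers([rec])
        assert len(kept) == 1
        kept_lit, tally_lit = filter_markers(
            [rec], FilterConfig(het_filter="observed")
        )
        assert kept_lit == [] and tally_lit["heterozygosity"] == 1

    def test_order_independent(self, rng):
        recs = []
        for j in range(30):
            g = rng.choice([-1, 0, 1, 2], size=80, p=[0.05, 0.45, 0.35, 0.15])
            recs.append(make_record(g, depths=rng.poisson(20, 80), id=f"M{j}"))
        kept1, _ = filter_markers(recs)
        perm = rng.permutation(len(recs))
        kept2, _ = filter_markers([recs[i] for i in perm])
        assert {r.id for r in kept1} == {r.id for r in kept2}

    def test_missing_depths_require_disabled_depth_rule(self):
        rec = make_record([0] * 25 + [1] * 50 + [2] * 25)  # HWE-consistent
        with pytest.raises(ValueError, match="depth"):
            filter_markers([rec])
        kept, _ = filter_markers([rec], FilterConfig(min_depth_exclusive=None))
        assert len(kept) == 1


def wc_theta_oracle(calls_mat, demes) -> float:
    """Independent FST oracle via the nested mean-squares (ANOVA) route."""
    labels = np.unique(demes)
    num = den = 0.0
    for j in range(calls_mat.shape[1]):
        ns, ps, hs = [], [], []
        for lab in labels:
            sub = calls_mat[(demes == lab) & (calls_mat[:, j] >= 0), j]
            ns.append(len(sub))
            ps.append(np.mean(sub) / 2.0)
            hs.append(np.mean(sub == 1))
        ns, ps, hs = map(np.asarray, (ns, ps, hs))
        r = len(labels)
        n_tot = ns.sum()
        pbar = np.sum(ns * ps) / n_tot
        if pbar <= 0 or pbar >= 1:
            continue
        msp = 2 * np.sum(ns * (ps - pbar) ** 2) / (r - 1)
        msi = np.sum(2 * ns * ps * (1 - ps) - ns * hs / 2.0) / (n_tot - r)
        msg = np.sum(ns * hs / 2.0) / n_tot
        nc = (n_tot - np.sum(ns**2) / n_tot) / (r - 1)
        s_a = (msp - msi) / (2 * nc)
        s_b = (msi - msg) / 2.0
        s_c = msg
        num += s_a
        den += s_a + s_b + s_c
    return num / den


class TestWeirCockerhamFst:
    def test_identical_demes_give_zero(self, rng):
        calls = rng.choice([0, 1, 2], size=(50, 30), p=[0.4, 0.4, 0.2])
        stacked = np.vstack([calls, calls])
        demes = np.array(["a"] * 50 + ["b"] * 50)
        theta = weir_cockerham_fst(
            [make_record(stacked[:, j], id=f"M{j}") for j in range(30)], demes
        )
        assert theta <= 1e-12

    def test_fixed_opposite_alleles_give_one(self):
        calls = np.vstack([np.zeros((40, 10), dtype=int),
                           np.full((40, 10), 2, dtype=int)])
        demes = np.array(["a"] * 40 + ["b"] * 40)
        recs = [make_record(calls[:, j], id=f"M{j}") for j in range(10)]
        assert weir_cockerham_fst(recs, demes) == pytest.approx(1.0, abs=1e-9)

    def test_matches_mean_squares_oracle(self, rng):
        calls = rng.choice([0, 1, 2], size=(60, 20))
        calls[rng.random(calls.shape) < 0.05] = -1
        demes = np.array(["a"] * 25 + ["b"] * 20 + ["c"] * 15)
        recs = [make_record(calls[:, j], id=f"M{j}") for j in range(20)]
        assert weir_cockerham_fst(recs, demes) == pytest.approx(
            wc_theta_oracle(calls, demes), abs=1e-10
        )

    def test_all_monomorphic_undefined(self):
        recs = [make_record(np.zeros(20, dtype=int))]
        with pytest.raises(UndefinedStatisticError):
            weir_cockerham_fst(recs, np.array(["a"] * 10 + ["b"] * 10))


class TestNmFromFst:
    def test_study_scale_value(self):
        assert nm_from_fst(0.007484551) == pytest.approx(33.152, abs=5e-4)

    @pytest.mark.parametrize("fst, nm", [(0.25, 0.75), (0.2, 1.0)])
    def test_closed_form(self, fst, nm):
        assert nm_from_fst(fst) == pytest.approx(nm)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            nm_from_fst(bad)


class TestVarianceComponentsAndQst:
    def test_pure_between_deme_signal(self):
        comp = deme_variance_components(
            np.array([0.0, 0, 0, 0, 1, 1, 1, 1]),
            np.array(["a"] * 4 + ["b"] * 4),
        )
        assert comp.sigma2_GW == pytest.approx(0.0)
        assert comp.sigma2_GB > 0

    def test_null_between_component_near_zero(self):
        rng = np.random.default_rng(19)
        y = rng.normal(0, 1, 400)
        demes = np.array(["a"] * 200 + ["b"] * 200)
        comp = deme_variance_components(y, demes)
        # SE of the between-component under the null is ~ sigma2*sqrt(2)/n0
        assert comp.sigma2_GB <= 2.0 * math.sqrt(2) / 200 * 1.5

    def test_balanced_offsets_match_moment_expectations(self):
        # deme means +/-delta: E[MS_between] = v + n*2*delta^2, so the
        # between-component estimates 2*delta^2 under the r-1 denominator
        rng = np.random.default_rng(7)
        delta, v, n = 0.5, 1.0, 4000
        y = np.concatenate(
            [rng.normal(-delta, math.sqrt(v), n), rng.normal(delta, math.sqrt(v), n)]
        )
        comp = deme_variance_components(y, np.array(["a"] * n + ["b"] * n))
        assert comp.sigma2_GW == pytest.approx(v, rel=0.05)
        assert comp.sigma2_GB == pytest.approx(2 * delta**2, rel=0.1)

    def test_underfilled_deme_rejected(self):
        with pytest.raises(ValueError):
            deme_variance_components(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))

    @pytest.mark.parametrize(
        "gb, gw, expected", [(0.0, 1.0, 0.0), (1.0, 1.0, 1 / 3), (1.0, 0.0, 1.0)]
    )
    def test_qst_closed_forms(self, gb, gw, expected):
        assert qst(VarianceComponents(gb, gw)) == pytest.approx(expected)

    def test_qst_undefined_for_zero_components(self):
        with pytest.raises(UndefinedStatisticError):
            qst(VarianceComponents(0.0, 0.0))

    def test_qst_increasing_in_between_component(self):
        vals = [qst(VarianceComponents(gb, 1.0)) for gb in (0.1, 0.5, 1.0, 5.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def _balanced_frame(rng, n_geno=10, n_pos=3, reps=2):
    rows = []
    for alt in ("high", "low"):
        for g in range(n_geno):
            for p in range(n_pos):
                for b in range(reps):
                    rows.append(
                        {
                            "altitude": alt,
                            "genotype": f"g{g}",
                            "position": f"p{p}",
                            "block": f"B{b + 1}",
                        }
                    )
    df = pd.DataFrame(rows)
    alt_eff = df["altitude"].map({"high": 0.5, "low": -0.5})
    gen_eff = df["genotype"].str[1:].astype(int) * 0.1
    pos_eff = df["position"].map({"p0": -0.3, "p1": 0.0, "p2": 0.3})
    df["y"] = alt_eff + gen_eff + pos_eff + rng.normal(0, 0.5, len(df))
    return df


def anova_projection_oracle(df, response):
    """Sequential SS via explicit projection matrices (independent route)."""
    y = df[response].to_numpy(dtype=float)

    def dummies(*cols):
        keys = df[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(keys).to_numpy(dtype=float)

    blocks = [
        dummies("altitude"),
        dummies("altitude", "genotype"),
        dummies("position"),
        dummies("block"),
        dummies("altitude", "position"),
        dummies("altitude", "genotype", "position"),
    ]
    design = np.ones((len(y), 1))
    proj_prev = design @ np.linalg.pinv(design)
    out = []
    for b in blocks:
        design = np.hstack([design, b])
        # rank-deficient dummy design: discard numerically-zero singular values
        proj = design @ np.linalg.pinv(design, rcond=1e-10)
        ss = float(y @ (proj - proj_prev) @ y)
        df_t = int(round(np.trace(proj - proj_prev)))
        out.append((ss, df_t))
        proj_prev = proj
    rss = float(y @ (np.eye(len(y)) - proj_prev) @ y)
    df_res = len(y) - int(round(np.trace(proj_prev)))
    ms_res = rss / df_res
    return [(ss / d) / ms_res for ss, d in out], df_res


class TestShapeAnova:
    def test_pure_altitude_signal(self):
        df = _balanced_frame(np.random.default_rng(0))
        df["y"] = (df["altitude"] == "high").astype(float)
        tab = shape_anova(df, "y")
        assert tab.loc["altitude", "sum_sq"] > 0
        assert tab.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        for term in tab.index:
            if term not in ("altitude", "residual"):
                assert tab.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_projection_matrix_oracle(self):
        df = _balanced_frame(np.random.default_rng(23))
        tab = shape_anova(df, "y")
        oracle_f, oracle_df_res = anova_projection_oracle(df, "y")
        f_vals = tab["F"].to_numpy()[:-1]
        assert np.abs(f_vals - oracle_f).max() < 1e-8
        assert int(tab.loc["residual", "df"]) == oracle_df_res

    def test_permuted_response_has_uniform_pvalues(self):
        rng = np.random.default_rng(99)
        df = _balanced_frame(rng)
        pvals = []
        for _ in range(120):
            df2 = df.assign(y=rng.permutation(df["y"].to_numpy()))
            tab = shape_anova(df2, "y")
            pvals.append(tab.loc["altitude", "p"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_aliased_term_named(self):
        df = _balanced_frame(np.random.default_rng(1))
        df["block"] = df["altitude"].map({"high": "B1", "low": "B2"})
        with pytest.raises(AliasedTermError, match="block"):
            shape_anova(df, "y")

    def test_single_level_factor_rejected(self):
        df = _balanced_frame(np.random.default_rng(1))
        df["position"] = "p0"
        with pytest.raises(ValueError, match="position"):
            shape_anova(df, "y")
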