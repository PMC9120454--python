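"""Gram ratios, correlations, model selection, rank tests and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gutbench import (
    CommunitySpec,
    DissimilarityMatrix,
    correlate_with_reference,
    fdr_adjust,
    fit_ols,
    gram_ratio,
    make_community,
    pairwise_clade_tests,
    permanova,
    profile_from_reference,
    top_down_select,
    wilcoxon_rank_sum,
)

from conftest import make_profile


def design_frame(rng, n=12):
    return pd.DataFrame(
        {
            "gram_indicator": (np.arange(n) < n // 3).astype(float),
            "genome_length": rng.uniform(2e6, 6e6, n),
            "gc_content": rng.uniform(0.3, 0.6, n),
        }
    )


class TestGramRatio:
    def test_expected_ratio_of_even_12_species_mix(self, even12_community):
        res = gram_ratio(profile_from_reference(even12_community), even12_community)
        assert res.expected_ratio == pytest.approx(0.5)
        assert res.observed_ratio == pytest.approx(0.5)

    def test_observed_ratio_is_abundance_quotient(self, even12_community):
        taxa = sorted(even12_community.entries, key=lambda t: t.key)
        pos = [t for t in taxa if even12_community.annotation(t).gram == "positive"]
        neg = [t for t in taxa if even12_community.annotation(t).gram == "negative"]
        entries = {t: 46.95 / len(pos) for t in pos}
        entries.update({t: 53.05 / len(neg) for t in neg})
        prof = make_profile({}, sample_id="bl")
        prof.entries = entries
        res = gram_ratio(prof, even12_community)
        assert res.observed_ratio == pytest.approx(0.885, abs=0.0005)

    def test_all_positive_profile_flagged_undefined(self, even12_community):
        taxa = [t for t in even12_community.entries if even12_community.annotation(t).gram == "positive"]
        prof = make_profile({}, sample_id="p")
        prof.entries = {t: 100.0 / len(taxa) for t in taxa}
        assert gram_ratio(prof, even12_community).observed_ratio is None


class TestCorrelation:
    def test_exact_agreement_gives_r_one_per_group(self, even12_community):
        # even community: zero variance in abundances, r undefined -> omitted
        res = correlate_with_reference(profile_from_reference(even12_community), even12_community)
        assert res == []
        staggered = make_community(CommunitySpec(distribution="lognormal", seed=3))
        res = correlate_with_reference(profile_from_reference(staggered), staggered)
        assert all(c.r == pytest.approx(1.0) for c in res)

    def test_affine_transform_preserves_r(self):
        staggered = make_community(CommunitySpec(distribution="lognormal", seed=5))
        prof = profile_from_reference(staggered)
        prof.entries = {t: 0.5 * a + 3.0 for t, a in prof.entries.items()}
        res = correlate_with_reference(prof, staggered)
        assert all(c.r == pytest.approx(1.0) for c in res)

    def test_four_point_hand_formula(self, even12_community):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        pos = [t for t in sorted(even12_community.entries, key=lambda t: t.key)
               if even12_community.annotation(t).gram == "positive"]
        prof = make_profile({}, sample_id="p")
        prof.entries = dict(zip(pos, y))
        ref_entries = dict(even12_community.entries)
        for t, xv in zip(pos, x):
            ref_entries[t] = xv
        even12_community.entries = {
            t: 100 * a / sum(ref_entries.values()) for t, a in ref_entries.items()
        }
        res = correlate_with_reference(prof, even12_community)
        (grp,) = [c for c in res if c.group == "gram_positive"]
        assert grp.n == 4
        assert grp.r == pytest.approx(r_hand)


class TestOls:
    def test_noiseless_gram_effect_recovered_exactly(self):
        rng = np.random.default_rng(0)
        d = design_frame(rng)
        y = 2.0 * d["gram_indicator"] + 1.0
        fit = fit_ols(y, d)
        assert fit.coefficients["gram_indicator"] == pytest.approx(2.0)
        assert abs(fit.coefficients["genome_length"]) < 1e-9
        assert fit.p_values["gram_indicator"] < 1e-8

    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(1)
        d = design_frame(rng)
        fit = fit_ols(np.full(12, 5.0), d)
        for term in d.columns:
            assert abs(fit.coefficients[term]) < 1e-9

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(2)
        d = design_frame(rng, n=3)
        with pytest.raises(ValueError, match="under-determined"):
            fit_ols([1.0, 2.0, 3.0], d)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(3)
        d = design_frame(rng)
        d["dup"] = d["gram_indicator"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_ols(rng.normal(size=12), d)


class TestTopDownSelection:
    def test_planted_gram_only_effect_selects_gram(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d = design_frame(rng)
            sd = 1.0
            y = 3.0 * sd * d["gram_indicator"] + rng.normal(0, sd, 12)
            fit = top_down_select(y, d, alpha=0.05)
            if fit.retained_terms == ["gram_indicator"]:
                hits += 1
        # exact recovery is capped near (1-alpha)^2 x power ~ 0.88: each noise
        # covariate is falsely retained with ~alpha probability
        assert hits >= 40

    def test_never_retains_insignificant_terms(self):
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            d = design_frame(rng)
            y = rng.normal(0, 1, 12)
            fit = top_down_select(y, d, alpha=0.05)
            for term in fit.retained_terms:
                assert fit.p_values[term] < 0.05

    def test_all_strong_effects_retained_with_empty_trace(self):
        rng = np.random.default_rng(9)
        n = 40
        d = pd.DataFrame(
            {
                "gram_indicator": (np.arange(n) < n // 2).astype(float),
                "genome_length": rng.uniform(2e6, 6e6, n),
                "gc_content": rng.uniform(0.3, 0.6, n),
            }
        )
        y = (
            5 * d["gram_indicator"]
            + 1e-5 * d["genome_length"]
            + 50 * d["gc_content"]
            + rng.normal(0, 0.5, n)
        )
        fit = top_down_select(y, d, alpha=0.05)
        assert sorted(fit.retained_terms) == sorted(d.columns)
        assert fit.elimination_trace == []


def enumeration_rank_sum_p(x, y):
    """Oracle: full enumeration of rank-sum assignments (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, n = len(x), len(pooled)
    mean_w = nx * (n + 1) / 2
    w_obs = ranks[:nx].sum()
    dev = abs(w_obs - mean_w)
    hits = total = 0
    for combo in itertools.combinations(range(n), nx):
        total += 1
        if abs(ranks[list(combo)].sum() - mean_w) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_separated_triples_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2], [2, 1, 2], mode="exact")
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (5, 4), (2, 6)])
    def test_exact_p_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(5):
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(enumeration_rank_sum_p(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(0.5, 1, size=10)
            _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
            _, p_approx = wilcoxon_rank_sum(x, y, mode="normal_approx")
            assert abs(p_exact - p_approx) < 0.01

    def test_auto_switches_on_ties_and_size(self):
        # ties force the approximation in auto mode; no crash, sane p
        _, p = wilcoxon_rank_sum([1, 1, 2], [1, 2, 2], mode="auto")
        assert 0 < p <= 1


class TestFdr:
    def test_hand_step_up(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_equal_values_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        assert fdr_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = np.sort(rng.uniform(size=15))
            adj = np.array(fdr_adjust(p))
            assert np.all(np.diff(adj) >= -1e-12)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0)


class TestPairwiseCladeTests:
    def _profiles(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        profiles, groups = [], {}
        for g in ("kapa", "nextera", "qiagen"):
            for i in range(4):
                sid = f"{g}{i}"
                entries = {"Clade a": 30.0, "Clade b": 30.0, "Clade c": 40.0}
                entries = {k: v + rng.normal(0, 0.5) for k, v in entries.items()}
                if g == "kapa" and shift:
                    entries["Clade a"] += shift
                total = sum(entries.values())
                profiles.append(make_profile({k: 100 * v / total for k, v in entries.items()}, sample_id=sid))
                groups[sid] = g
        return profiles, groups

    def test_three_groups_give_three_pairs_per_clade(self):
        profiles, groups = self._profiles()
        table = pairwise_clade_tests(profiles, groups).rows
        assert set(table["clade"]) == {"Clade a", "Clade b", "Clade c"}
        assert len(table) == 9
        assert table["p_adjusted"].ge(table["p_raw"] - 1e-12).all()

    def test_identical_groups_nothing_significant(self):
        profiles, groups = [], {}
        for g in ("a", "b"):
            for i in range(3):
                sid = f"{g}{i}"
                profiles.append(make_profile({"Clade a": 60.0, "Clade b": 40.0}, sample_id=sid))
                groups[sid] = g
        table = pairwise_clade_tests(profiles, groups).rows
        assert (table["p_raw"] > 0.99).all()

    def test_planted_shift_attains_minimum_adjusted_p(self):
        profiles, groups = self._profiles(shift=20.0, seed=1)
        table = pairwise_clade_tests(profiles, groups).rows
        best = table.loc[table["p_adjusted"].idxmin()]
        assert best["clade"] == "Clade a"
        assert "kapa" in (best["group_a"], best["group_b"])


def brute_force_permanova_f(d, labels):
    """Oracle: explicit projection-matrix pseudo-F for one factor."""
    n = len(labels)
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    levels = sorted(set(labels))
    x = np.column_stack([np.ones(n)] + [[1.0 if l == lv else 0.0 for l in labels] for lv in levels[1:]])
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_model = np.trace(h @ g @ h)
    ss_total = np.trace(g)
    ss_res = ss_total - ss_model
    df_model = len(levels) - 1
    df_res = n - len(levels)
    return (ss_model / df_model) / (ss_res / df_res), ss_model / ss_total


class TestPermanova:
    def _random_dm(self, rng, n):
        x = rng.uniform(0.05, 1.0, (n, n))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        return DissimilarityMatrix([f"s{i}" for i in range(n)], m)

    def test_f_matches_projection_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = 8
            dm = self._random_dm(rng, n)
            labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
            fac = pd.DataFrame({"sample_id": dm.sample_ids, "grp": labels})
            res = permanova(dm, fac, "grp", n_permutations=99, seed=trial)
            f_oracle, r2_oracle = brute_force_permanova_f(dm.values, labels)
            assert res.terms[0].f == pytest.approx(f_oracle, abs=1e-9)
            assert res.terms[0].r2 == pytest.approx(r2_oracle, abs=1e-9)

    def test_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        dm = self._random_dm(rng, 9)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        fac = pd.DataFrame({"sample_id": dm.sample_ids, "grp": labels})
        res = permanova(dm, fac, "grp", n_permutations=99, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values, ids=dm.sample_ids),
            grouping=labels,
            permutations=99,
        )
        assert res.terms[0].f == pytest.approx(float(sk["test statistic"]), abs=1e-9)

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(5)
        dm = self._random_dm(rng, 12)
        fac = pd.DataFrame(
            {
                "sample_id": dm.sample_ids,
                "time": ["t10", "t15", "t20"] * 4,
                "kit": ["k", "k", "n", "n", "q", "q"] * 2,
            }
        )
        res = permanova(dm, fac, "time + kit + time:kit", n_permutations=99, seed=1)
        total_r2 = sum(t.r2 for t in res.terms) + res.residual_r2
        assert total_r2 == pytest.approx(1.0, abs=1e-9)
        assert [t.name for t in res.terms] == ["time", "kit", "time:kit"]

    def test_invariant_under_consistent_sample_reordering(self):
        rng = np.random.default_rng(6)
        dm = self._random_dm(rng, 8)
        labels = ["a", "b"] * 4
        fac = pd.DataFrame({"sample_id": dm.sample_ids, "grp": labels})
        res1 = permanova(dm, fac, "grp", n_permutations=199, seed=9)
        perm = rng.permutation(8)
        dm2 = DissimilarityMatrix(
            [dm.sample_ids[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        res2 = permanova(dm2, fac, "grp", n_permutations=199, seed=9)
        assert res2.terms[0].f == pytest.approx(res1.terms[0].f, abs=1e-9)
        assert res2.terms[0].r2 == pytest.approx(res1.terms[0].r2, abs=1e-9)

    def test_clear_group_structure_gets_floor_scale_p(self):
        ids = [f"s{i}" for i in range(6)]
        m = np.full((6, 6), 0.9)
        m[:3, :3] = 0.01
        m[3:, 3:] = 0.01
        np.fill_diagonal(m, 0)
        dm = DissimilarityMatrix(ids, m)
        fac = pd.DataFrame({"sample_id": ids, "grp": ["a"] * 3 + ["b"] * 3})
        res = permanova(dm, fac, "grp", n_permutations=999, seed=2)
        # only group-preserving permutations (prob 1/10) can reach F*
        assert res.terms[0].r2 > 0.99
        assert res.terms[0].p <= 0.15
        assert res.terms[0].p >= 1 / 1000

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(7)
        dm = self._random_dm(rng, 4)
        fac = pd.DataFrame({"sample_id": dm.sample_ids, "grp": ["a"] * 4})
        with pytest.raises(ValueError, match="single level"):
            permanova(dm, fac, "grp", n_permutations=99)

    def test_overparameterised_formula_rejected(self):
        rng = np.random.default_rng(8)
        dm = self._random_dm(rng, 4)
        fac = pd.DataFrame(
            {"sample_id": dm.sample_ids, "grp": ["a", "b", "c", "d"]}
        )
        with pytest.raises(ValueError, match="residual"):
            permanova(dm, fac, "grp", n_permutations=99)
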