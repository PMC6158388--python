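"""Class summaries, genetic-effect estimators, ANOVA and Tukey letters."""

import itertools

import numpy as np
import pytest
from scipy import stats

from capskit.core import FattyAcidProfile, PopulationLine
from capskit.popgen import (
    EpistasisConventionWarning,
    anova_oneway,
    chi_square_segregation,
    class_table_from_means,
    cld_from_data,
    compact_letter_display,
    default_f2_class_tables,
    genetic_effects,
    marginal_allele_contrast,
    summarize_by_genotype,
    tukey_pairwise,
)
from capskit import synth

#: two-site F2 oleic-acid class means (%), transcribed trial summaries
NANJING = {
    "AABB": (16, 63.1, 2.0), "AABb": (28, 66.8, 1.0), "AaBB": (30, 66.9, 1.6),
    "AAbb": (15, 69.8, 2.4), "aaBB": (15, 69.5, 1.8), "AaBb": (58, 73.7, 2.0),
    "aaBb": (27, 77.6, 1.8), "Aabb": (29, 78.1, 2.3), "aabb": (14, 84.9, 1.5),
}
WUHAN = {
    "AABB": (15, 63.3, 1.9), "AABb": (26, 67.1, 1.7), "AaBB": (26, 67.0, 1.9),
    "AAbb": (12, 70.0, 2.0), "aaBB": (13, 70.3, 1.9), "AaBb": (60, 74.2, 2.0),
    "aaBb": (30, 78.2, 1.9), "Aabb": (27, 79.0, 2.2), "aabb": (15, 85.1, 1.4),
}


def _line(i, g1, g2, c18_1):
    return PopulationLine(
        f"L{i}", "F2", "Nanjing", g1, g2,
        FattyAcidProfile(3.5, 1.8, c18_1, max(0.5, 92 - c18_1), 2.0, 40.0),
    )


class TestSummarize:
    def test_mean_and_sample_sd(self):
        pop = [_line(i, "aa", "bb", v) for i, v in enumerate([10, 20, 30])]
        table = summarize_by_genotype(pop, "c18_1")
        assert table.classes["aabb"] == (3, 20.0, 10.0)

    def test_unknown_genotypes_excluded_and_counted(self):
        pop = [_line(0, "aa", "bb", 85.0), _line(1, "unknown", "bb", 70.0)]
        table = summarize_by_genotype(pop, "c18_1")
        assert table.n_excluded == 1
        assert set(table.classes) == {"aabb"}

    def test_simulated_f2_has_nine_classes(self):
        pop = synth.simulate_population(synth.PopulationConfig(n_lines=247, seed=1))
        assert len(summarize_by_genotype(pop, "c18_1").classes) == 9

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_genotype([], "c18_1")

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="trait"):
            summarize_by_genotype([_line(0, "aa", "bb", 85.0)], "c20_1")


class TestGeneticEffects:
    def _effects(self, means):
        table = class_table_from_means(means, "c18_1")
        with pytest.warns(EpistasisConventionWarning):
            return genetic_effects(table)

    def test_reproduces_published_additive_and_dominance(self):
        e_nj = self._effects(NANJING)
        assert round(e_nj.a1, 2) == 5.38
        assert round(e_nj.d1, 2) == 0.95
        assert round(e_nj.d2, 2) == 0.65
        e_wh = self._effects(WUHAN)
        assert round(e_wh.a1, 2) == 5.53
        assert round(e_wh.d1, 2) == 1.07
        assert round(e_wh.d2, 2) == 0.72

    def test_formula_literal_a2_and_epistasis(self):
        # these are the stated-formula values; they are known to differ
        # from some published summaries of the same class means
        e = self._effects(NANJING)
        assert round(e.a2, 2) == 5.55
        assert round(e.i, 2) == -3.47

    def test_all_equal_means_give_zero_effects(self):
        means = {g: (10, 70.0, 1.0) for g in NANJING}
        e = self._effects(means)
        assert (e.a1, e.a2, e.d1, e.d2, e.i) == (0, 0, 0, 0, 0)

    def test_location_shift_invariance(self):
        e0 = self._effects(NANJING)
        shifted = {g: (n, m + 7.3, s) for g, (n, m, s) in NANJING.items()}
        e1 = self._effects(shifted)
        for attr in ("a1", "a2", "d1", "d2", "i"):
            assert getattr(e1, attr) == pytest.approx(getattr(e0, attr))

    def test_class_order_invariance(self):
        reordered = dict(reversed(list(NANJING.items())))
        assert self._effects(reordered) == self._effects(NANJING)

    def test_missing_class_listed_in_error(self):
        partial = {g: v for g, v in NANJING.items() if g != "aaBb"}
        with pytest.raises(ValueError, match="aaBb"):
            genetic_effects(class_table_from_means(partial, "c18_1"))

    def test_bc1_table_refused(self):
        bc1 = {g: (50, 65.0, 2.0) for g in ("AABB", "AABb", "AaBB", "AaBb")}
        with pytest.raises(ValueError, match="9 F2 genotype classes"):
            genetic_effects(class_table_from_means(bc1, "c18_1"))

    def test_packaged_tables_match_transcription(self):
        tables = default_f2_class_tables()
        nj = tables[("F2-1", "Nanjing")]
        assert {g: (s.n, s.mean, s.sd) for g, s in nj.classes.items()} == NANJING

    def test_recovers_simulation_truth_within_three_se(self):
        truth = np.array([5.38, 5.55, 0.95, 0.65])
        reps = []
        for seed in range(60):
            pop = synth.simulate_population(
                synth.PopulationConfig(n_lines=300, seed=20_000 + seed)
            )
            with pytest.warns(EpistasisConventionWarning):
                e = genetic_effects(summarize_by_genotype(pop, "c18_1"))
            reps.append([e.a1, e.a2, e.d1, e.d2])
        mean = np.mean(reps, axis=0)
        se = np.std(reps, axis=0, ddof=1) / np.sqrt(len(reps))
        assert (np.abs(mean - truth) < 3 * se + 1e-12).all()


class TestContrast:
    def test_matches_unweighted_marginal_difference(self):
        pop = []
        for g, (n, m, _) in NANJING.items():
            pop.extend(
                _line(f"{g}{k}", g[:2], g[2:], m) for k in range(3)
            )
        res = marginal_allele_contrast(pop, 1, "AA", "aa", n_boot=100, seed=0)
        assert round(res.difference, 2) == 10.77

    def test_identical_classes_give_zero_with_covering_ci(self):
        pop = [
            _line(f"{g1}{g2}{k}", g1, g2, 70.0 + 0.1 * k)
            for g1 in ("AA", "Aa", "aa")
            for g2 in ("BB", "Bb", "bb")
            for k in range(5)
        ]
        res = marginal_allele_contrast(pop, 2, "BB", "bb", n_boot=200, seed=1)
        assert res.difference == pytest.approx(0.0, abs=1e-9)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_recovers_planted_contrast(self):
        pop = synth.simulate_population(
            synth.PopulationConfig(n_lines=400, seed=3)
        )
        res = marginal_allele_contrast(pop, 1, "AA", "aa", n_boot=500, seed=2)
        assert res.ci_low <= 2 * 5.38 <= res.ci_high

    def test_reproducible_under_seed(self):
        pop = synth.simulate_population(synth.PopulationConfig(n_lines=200, seed=4))
        a = marginal_allele_contrast(pop, 1, "AA", "aa", n_boot=300, seed=9)
        b = marginal_allele_contrast(pop, 1, "AA", "aa", n_boot=300, seed=9)
        assert a == b


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        assert anova_oneway([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0)

    def test_separated_groups_highly_significant(self):
        g1 = [63 - 2, 63 + 2] * 7
        g2 = [85 - 2, 85 + 2] * 7
        f, p = anova_oneway([g1, g2])
        assert p < 1e-6

    def test_agrees_with_closed_form(self):
        rng = np.random.default_rng(0)
        groups = [list(rng.normal(m, 1, 8)) for m in (0, 0.5, 1.0)]
        f, p = anova_oneway(groups)
        f_ref, p_ref = stats.f_oneway(*groups)
        assert (f, p) == pytest.approx((f_ref, p_ref))

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            _, p = anova_oneway(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestLetters:
    def test_three_separated_classes(self):
        groups = {
            "lo": [1, 1.1, 0.9, 1.0] * 3,
            "mid": [5, 5.1, 4.9, 5.0] * 3,
            "hi": [9, 9.1, 8.9, 9.0] * 3,
        }
        assert cld_from_data(groups) == {"lo": "a", "mid": "b", "hi": "c"}

    def test_equal_classes_share_one_letter(self):
        groups = {k: [1.0, 1.1, 0.9] for k in "xyz"}
        assert set(cld_from_data(groups).values()) == {"a"}

    def test_letters_encode_pairwise_decisions(self):
        """Sharing a letter must coincide exactly with 'not significantly
        different' under Tukey HSD."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            k = int(rng.integers(3, 6))
            groups = {
                f"g{j}": list(rng.normal(rng.uniform(0, 4), 1, 8))
                for j in range(k)
            }
            decisions = tukey_pairwise(groups, alpha=0.05)
            letters = cld_from_data(groups, alpha=0.05)
            for a, b in itertools.combinations(groups, 2):
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != decisions[frozenset((a, b))]

    def test_tukey_matches_studentized_range_brute_force(self):
        """statsmodels' decisions equal direct Tukey-Kramer comparisons
        built from the studentized-range distribution."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            k = int(rng.integers(3, 6))
            groups = {
                f"g{j}": rng.normal(rng.uniform(0, 3), 1, int(rng.integers(5, 12)))
                for j in range(k)
            }
            ns = {g: len(v) for g, v in groups.items()}
            means = {g: np.mean(v) for g, v in groups.items()}
            df = sum(ns.values()) - k
            mse = sum(
                np.sum((np.asarray(v) - means[g]) ** 2)
                for g, v in groups.items()
            ) / df
            q_crit = stats.studentized_range.ppf(0.95, k, df)
            decisions = tukey_pairwise(groups, alpha=0.05)
            for a, b in itertools.combinations(groups, 2):
                se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
                reject = abs(means[a] - means[b]) / se > q_crit
                assert decisions[frozenset((a, b))] == reject


class TestSegregation:
    def test_perfect_ratio(self):
        stat, p = chi_square_segregation([25, 50, 25], [1, 2, 1])
        assert (stat, p) == (0.0, 1.0)

    def test_observed_class_counts_run_through(self):
        stat, p = chi_square_segregation([16, 58, 14], [1, 2, 1])
        assert stat > 0 and 0 < p <= 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_square_segregation([0, 0, 0], [1, 2, 1])

    def test_large_f2_not_rejected(self):
        failures = 0
        for seed in range(30):
            pop = synth.simulate_population(
                synth.PopulationConfig(n_lines=10_000, seed=30_000 + seed)
            )
            counts = {"AA": 0, "Aa": 0, "aa": 0}
            for ln in pop:
                counts[ln.genotype_locus1] += 1
            _, p = chi_square_segregation(
                [counts["AA"], counts["Aa"], counts["aa"]], [1, 2, 1]
            )
            failures += p < 0.01
        assert failures <= 1
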