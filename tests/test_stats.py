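import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from mpalkit.io import ClinicalRecord
from mpalkit.stats import (
    fisher_exact_2x2,
    km_logrank,
    mann_whitney,
    matched_therapy_analysis,
    mutation_enrichment,
    wald_log_or,
)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by explicit enumeration of all margin-fixed tables."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestFisherExact:
    def test_matched_therapy_cr_table(self):
        # 13/18 vs 2/9 complete-remission contingency
        assert fisher_exact_2x2([[13, 5], [2, 7]]) == pytest.approx(0.037, abs=5e-4)

    def test_symmetric_two_by_two(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_zero_margin_returns_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            table = rng.integers(0, 12, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_enumeration_oracle(table.tolist()), rel=1e-9
            )

    def test_invariant_under_transposition(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            t = rng.integers(1, 15, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))
            swapped = t[::-1, ::-1]
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped))


class TestWaldLogOr:
    def test_runx1_phenotype_table(self):
        # 6/13 myeloid-B vs 2/18 myeloid-T carriers
        res = wald_log_or([[6, 7], [2, 16]])
        assert res.p_value == pytest.approx(0.039, abs=5e-4)
        assert not res.haldane_applied

    def test_notch1_zero_cell_haldane(self):
        # 9/18 myeloid-T vs 0/13 myeloid-B carriers
        res = wald_log_or([[9, 9], [0, 13]])
        assert res.p_value == pytest.approx(0.029, abs=5e-4)
        assert res.haldane_applied

    def test_balanced_table_null(self):
        res = wald_log_or([[5, 5], [5, 5]])
        assert res.log_odds_ratio == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_row_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wald_log_or([[0, 0], [3, 4]])

    def test_ci_excludes_null_iff_significant(self):
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(100):
            t = rng.integers(1, 25, size=(2, 2))
            res = wald_log_or(t)
            excludes = res.ci_low > 0 or res.ci_high < 0
            assert excludes == (res.p_value < 0.05)
            checked += 1
        assert checked == 100

    def test_mutation_enrichment_builds_correct_tables(self):
        group_b = {f"B{i}" for i in range(13)}
        group_t = {f"T{i}" for i in range(18)}
        carriers = {"RUNX1": {f"B{i}" for i in range(6)} | {"T0", "T1"}}
        res = mutation_enrichment(carriers, group_b, group_t)
        assert res[0].label == "RUNX1"
        assert res[0].table == ((6, 7), (2, 16))
        assert res[0].p_value == pytest.approx(0.039, abs=5e-4)


class TestMannWhitney:
    def test_identical_samples_exact_p_one(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_exact_branch_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_exact_branch_with_ties_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pooled = rng.integers(0, 4, size=8).astype(float)  # heavy ties
            x, y = pooled[:4], pooled[4:]
            u_obs, p = mann_whitney(x, y)
            ranks = sps.rankdata(pooled)
            mu = 4 * 4 / 2
            devs = []
            for idx in itertools.permutations(range(8), 4):
                u = ranks[list(idx)].sum() - 4 * 5 / 2
                devs.append(abs(u - mu))
            obs = abs(u_obs - mu)
            oracle = np.mean([d >= obs - 1e-12 for d in devs])
            assert p == pytest.approx(oracle, rel=1e-9)

    def test_large_sample_asymptotic_reasonable(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1, 1, 40)
        _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestKmLogrank:
    def test_no_censoring_equals_empirical_survival(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [True] * 10
        groups = ["a"] * 5 + ["b"] * 5
        res = km_logrank(times, events, groups)
        curve = res.km_curves["a"].set_index("time")["survival"]
        for t, expected in [(1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)]:
            assert curve.loc[t] == pytest.approx(expected)

    def test_identical_groups_null(self):
        times = [3, 6, 9, 12, 15] * 2
        events = [True, False, True, True, False] * 2
        res = km_logrank(times, events, ["a"] * 5 + ["b"] * 5)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_five_subject_worked_example(self):
        # product-limit by hand: deaths at 1, 2 and 4; censoring at 3 and 5
        # S(1)=4/5; S(2)=4/5*3/4=3/5; S(4)=3/5*1/2=3/10
        times = [1, 2, 3, 4, 5, 2, 4, 6, 8, 10]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        res = km_logrank(times, [bool(e) for e in events], ["a"] * 5 + ["b"] * 5)
        curve = res.km_curves["a"].set_index("time")["survival"]
        assert curve.loc[1] == pytest.approx(0.8)
        assert curve.loc[2] == pytest.approx(0.6)
        assert curve.loc[4] == pytest.approx(0.3)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [True, True], ["a", "a"])


def _clin(sample, lineage_label, therapy, cr, surv=None, event=None):
    return ClinicalRecord(
        sample_id=sample, phenotype="myeloid_B", blast_percent=80.0,
        therapy=therapy, cr_achieved=cr, survival_time=surv, event=event,
    )


class TestMatchedTherapy:
    def _paper_fixture(self):
        """27 evaluable patients mirroring the printed contingency table:
        18 matched (13 CR) and 9 unmatched (2 CR)."""
        clinical, labels = [], {}
        k = 0
        for cr_count, total, matched in ((13, 18, True), (2, 9, False)):
            for i in range(total):
                s = f"P{k}"
                k += 1
                labels[s] = "ALL_like"
                therapy = "ALL_directed" if matched else "AML_directed"
                clinical.append(_clin(s, "ALL_like", therapy, i < cr_count))
        return clinical, labels

    def test_printed_cr_comparison_reproduced(self):
        clinical, labels = self._paper_fixture()
        res = matched_therapy_analysis(clinical, labels)
        assert res.cr_table == ((13, 5), (2, 7))
        assert res.cr_fisher_p == pytest.approx(0.037, abs=5e-4)

    def test_all_matched_is_degenerate(self):
        clinical, labels = self._paper_fixture()
        clinical = [c for c in clinical if c.therapy == "ALL_directed"]
        res = matched_therapy_analysis(clinical, labels)
        assert res.degenerate

    def test_no_evaluable_patients_rejected(self):
        clinical = [_clin("P0", "ALL_like", "none", None)]
        with pytest.raises(ValueError, match="evaluable"):
            matched_therapy_analysis(clinical, {"P0": "ALL_like"})

    def test_permutation_null_type_i_controlled(self):
        """Permuting the matched/unmatched assignment kills the association;
        the (conservative, discrete) Fisher test rejects at most ~alpha."""
        clinical, labels = self._paper_fixture()
        rng = np.random.default_rng(6)
        cr_flags = [c.cr_achieved for c in clinical]
        rejections = 0
        reps = 200
        for _ in range(reps):
            perm = rng.permutation(len(cr_flags))
            for c, i in zip(clinical, perm):
                c.cr_achieved = cr_flags[i]
            res = matched_therapy_analysis(clinical, labels)
            rejections += res.cr_fisher_p < 0.05
        assert rejections / reps <= 0.05 + 0.03
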