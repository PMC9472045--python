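"""Agreement, signed-rank timing, learning-effect, and demographic stats."""

import datetime as dt
import itertools
import random

import numpy as np
import pytest
from scipy import stats as sps

from natkit.stats import (
    FIVE_CLASS_LABELS,
    binarize_labels,
    cohen_kappa,
    demographic_summary,
    filter_undetermined,
    learning_effect,
    paired_timing_test,
    percent,
)
from natkit.model import Education, EthnicGroup, MaritalStatus, Sex

from conftest import make_chart, make_patient


class TestBinarize:
    def test_normal_maps_to_cn_everything_else_ci(self):
        labels = list(FIVE_CLASS_LABELS)
        assert binarize_labels(labels) == ["CN", "CI", "CI", "CI", "CI"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            binarize_labels(["normal", "who knows"])

    def test_elementwise_on_random_vectors(self):
        rng = random.Random(1)
        vec = [rng.choice(FIVE_CLASS_LABELS) for _ in range(200)]
        out = binarize_labels(vec)
        assert out == ["CN" if v == "normal" else "CI" for v in vec]


class TestFilterUndetermined:
    def test_identity_when_none_undetermined(self):
        pairs = [("CN", "CI"), ("CI", "CI")]
        kept, excluded = filter_undetermined(pairs)
        assert kept == pairs and excluded == 0

    def test_all_undetermined_empties_and_counts(self):
        pairs = [("undetermined", "CN")] * 4
        kept, excluded = filter_undetermined(pairs)
        assert kept == [] and excluded == 4

    def test_only_tool_side_is_filtered(self):
        pairs = [("CN", "undetermined"), ("undetermined", "CN")]
        kept, excluded = filter_undetermined(pairs)
        assert kept == [("CN", "undetermined")] and excluded == 1


class TestCohenKappa:
    def test_perfect_agreement_kappa_one(self):
        labels = ["CN", "CI", "CN", "CI", "CN"]
        result, table = cohen_kappa(labels, labels)
        assert result.kappa == pytest.approx(1.0)
        assert result.po == 1.0
        assert table.n == 5

    def test_degenerate_single_category_undefined(self):
        result, _ = cohen_kappa(["CI"] * 6, ["CI"] * 6)
        assert result.kappa is None
        assert result.pe == pytest.approx(1.0)
        assert not result.defined

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohen_kappa(["CN"], ["CN", "CI"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([], [])

    def test_formula_from_contingency_table(self):
        # hand-checkable 2x2: diag 40+30 of 100, rows (50,50), cols (60,40)
        a = ["CN"] * 50 + ["CI"] * 50
        b = ["CN"] * 40 + ["CI"] * 10 + ["CN"] * 20 + ["CI"] * 30
        result, table = cohen_kappa(a, b)
        po = 0.7
        pe = 0.5 * 0.6 + 0.5 * 0.4
        assert result.po == pytest.approx(po)
        assert result.pe == pytest.approx(pe)
        assert result.kappa == pytest.approx((po - pe) / (1 - pe))
        assert table.as_array().sum() == 100

    def test_matches_sklearn_on_random_vectors(self):
        """Independent cross-check against scikit-learn's implementation."""
        from sklearn.metrics import cohen_kappa_score

        rng = random.Random(99)
        for _ in range(200):
            n = rng.randrange(2, 50)
            cats = ["CN", "CI", "undetermined"][: rng.choice([2, 3])]
            a = [rng.choice(cats) for _ in range(n)]
            b = [rng.choice(cats) for _ in range(n)]
            result, _ = cohen_kappa(a, b)
            if result.kappa is None:
                assert len(set(a)) == 1 and set(a) == set(b)
                continue
            expected = cohen_kappa_score(a, b)
            assert result.kappa == pytest.approx(expected, abs=1e-12)

    def test_symmetric_under_rater_swap(self):
        rng = random.Random(4)
        a = [rng.choice("xyz") for _ in range(60)]
        b = [rng.choice("xyz") for _ in range(60)]
        r1, _ = cohen_kappa(a, b)
        r2, _ = cohen_kappa(b, a)
        assert r1.kappa == pytest.approx(r2.kappa)


def enumeration_signed_rank_p(diffs):
    """Independent oracle: full 2^n sign enumeration of the null."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    n_total = 2 ** n
    ge = sum(1 for w in ws if w >= w_obs - 1e-12)
    le = sum(1 for w in ws if w <= w_obs + 1e-12)
    return min(1.0, 2 * min(ge, le) / n_total)


class TestPairedTiming:
    def test_identical_vectors_undefined(self):
        res = paired_timing_test([3, 4, 5], [3, 4, 5])
        assert res.p_value is None and res.method == "undefined"
        assert res.n_zero_dropped == 3

    def test_reversed_sequence_matches_full_enumeration(self):
        a = [3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        b = a[::-1]
        res = paired_timing_test(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            enumeration_signed_rank_p(np.array(a) - np.array(b))
        )

    @pytest.mark.parametrize("trial", range(20))
    def test_exact_p_equals_enumeration_small_n(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 13))
        # integer-valued differences force ties and exercise midranks
        a = rng.integers(1, 8, size=n).astype(float)
        b = rng.integers(1, 8, size=n).astype(float)
        if np.all(a == b):
            a[0] += 1
        res = paired_timing_test(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            enumeration_signed_rank_p(a - b), abs=1e-12
        )

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(10, 1, size=60)
        b = rng.normal(9, 1, size=60)
        res = paired_timing_test(a, b)
        assert res.method == "normal_approx"
        # cross-check against scipy's implementation of the same test
        expected = sps.wilcoxon(a, b, correction=True,
                                method="approx").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-6)

    def test_ratio_summaries(self):
        res = paired_timing_test([2.0, 4.0, 10.0], [1.0, 2.0, 1.0])
        assert res.median_ratio == pytest.approx(2.0)
        assert res.min_ratio == pytest.approx(2.0)
        assert res.max_ratio == pytest.approx(10.0)
        assert res.min_ratio <= res.median_ratio <= res.max_ratio

    def test_nonpositive_times_disable_ratios(self):
        res = paired_timing_test([1.0, 2.0], [0.0, 1.0])
        assert res.median_ratio is None

    def test_mean_sd_reported_over_all_pairs(self):
        a = [5.0, 5.0, 8.0]
        b = [5.0, 3.0, 5.0]
        res = paired_timing_test(a, b)
        d = np.array(a) - np.array(b)
        assert res.mean_diff == pytest.approx(d.mean())
        assert res.sd_diff == pytest.approx(d.std(ddof=1))
        assert res.mean_diff_nonzero == pytest.approx(2.5)


class TestLearningEffect:
    def test_constant_durations_p_near_one(self):
        res = learning_effect([5.0] * 8)
        assert res.median_first == res.median_second == 5.0
        assert res.p_value > 0.9

    def test_decreasing_durations_first_half_larger(self):
        res = learning_effect(list(range(20, 0, -1)))
        assert res.median_first > res.median_second
        assert res.p_value < 0.01

    def test_odd_count_extra_goes_to_first_half(self):
        res = learning_effect([9.0, 7.0, 5.0, 3.0, 1.0])
        assert (res.n_first, res.n_second) == (3, 2)
        assert res.median_first == 7.0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            learning_effect([1.0, 2.0, 3.0])

    def test_medians_equal_brute_force_split(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            d = rng.uniform(1, 10, size=int(rng.integers(4, 30)))
            res = learning_effect(d)
            split = (len(d) + 1) // 2
            assert res.median_first == np.median(d[:split])
            assert res.median_second == np.median(d[split:])


class TestDemographics:
    def cohort(self, n, n_female, n_college, n_edu_missing):
        charts = []
        for i in range(n):
            sex = Sex.FEMALE if i < n_female else Sex.MALE
            if i < n_college:
                edu = Education.COLLEGE_OR_MORE
            elif i < n_college + n_edu_missing:
                edu = Education.MISSING
            else:
                edu = Education.LESS_THAN_COLLEGE
            charts.append(make_chart(pid=f"p{i:03d}"))
            charts[-1].patient = make_patient(
                f"p{i:03d}", sex=sex, education=edu,
                ethnic_group=EthnicGroup.WHITE,
                marital_status=MaritalStatus.MARRIED,
            )
        return charts

    def test_female_63_of_100_prints_63_0(self):
        summary = demographic_summary(self.cohort(100, 63, 51, 3))
        assert summary.sex["female"].count == 63
        assert summary.sex["female"].pct == 63.0
        assert summary.college.count == 51
        assert summary.college.pct == 51.0
        assert summary.education_missing == 3

    def test_missing_stays_in_denominator(self):
        # 160 college of 527 with 62 missing: percent uses the full cohort
        summary = demographic_summary(self.cohort(527, 226, 160, 62))
        assert summary.college.pct == 30.4
        assert summary.sex["female"].pct == 42.9

    def test_singleton_cohort_is_100_percent(self):
        summary = demographic_summary(self.cohort(1, 1, 0, 0))
        assert summary.sex["female"].pct == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            demographic_summary([])

    def test_rounding_is_half_up(self):
        assert percent(1, 16) == 6.3       # 6.25 rounds up
        assert percent(1, 3) == 33.3
        assert percent(318, 527) == 60.3   # 60.341...
        assert percent(1, 8) == 12.5

    def test_random_cohorts_equal_brute_force_counts(self):
        rng = random.Random(44)
        for _ in range(20):
            n = rng.randrange(1, 40)
            charts = []
            for i in range(n):
                chart = make_chart(pid=f"p{i:03d}")
                chart.patient = make_patient(
                    f"p{i:03d}",
                    sex=rng.choice(list(Sex)),
                    ethnic_group=rng.choice(list(EthnicGroup)),
                    marital_status=rng.choice(list(MaritalStatus)),
                    education=rng.choice(list(Education)),
                )
                charts.append(chart)
            summary = demographic_summary(charts)
            n_female = sum(1 for c in charts if c.patient.sex is Sex.FEMALE)
            assert summary.sex["female"].count == n_female
            assert summary.sex["female"].pct == percent(n_female, n)
            minority_total = sum(
                1 for c in charts
                if c.patient.ethnic_group.value in
                ("black", "hispanic", "asian", "indigenous")
            )
            assert summary.minorities["total"].count == minority_total
            assert summary.married.count == sum(
                1 for c in charts
                if c.patient.marital_status is MaritalStatus.MARRIED
            )

    def test_encounters_median_min_max(self, simple_chart):
        summary = demographic_summary([simple_chart])
        assert summary.encounters_median == 3
        assert (summary.encounters_min, summary.encounters_max) == (3, 3)
        assert summary.dementia_signal.count == 1  # donepezil + G30.9
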