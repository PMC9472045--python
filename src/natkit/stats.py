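"""Evaluation statistics for annotation studies.

Covers the statistics used to evaluate a semiautomated chart-review
workflow against manual review: Cohen's kappa for interrater and
cross-method agreement (with the preprocessing those comparisons need:
collapsing a five-level cognition adjudication to CN/CI, and dropping
pairs the tool-side rater marked undetermined), an exact/approximate paired
Wilcoxon signed-rank test with timing-ratio summaries, a first-half versus
second-half learning-effect comparison, and cohort demographic summary
tables.

Cohen's kappa is the chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e)

with observed agreement p_o (the contingency diagonal) and chance agreement
p_e = sum_k (row_k / n)(col_k / n).  When both raters use a single category
p_e = 1 and kappa is undefined; that case is flagged, not fudged.

The signed-rank test drops zero differences (Wilcoxon's convention), ranks
absolute differences with midranks for ties, and sums the ranks of positive
differences into W.  For n <= 25 retained pairs the two-sided p-value is
exact, computed from the full null distribution of W (every sign pattern
equally likely); above that a normal approximation with tie and continuity
corrections is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .features import flag_dementia_icd, flag_dementia_medications
from .model import MINORITY_GROUPS, Education, MaritalStatus, PatientChart, Sex

#: Five-level cognition adjudication vocabulary used by upstream studies.
FIVE_CLASS_LABELS = (
    "normal",
    "borderline-MCI",
    "MCI",
    "borderline-dementia",
    "dementia",
)

#: Retained-pair count at or below which the signed-rank p-value is exact.
EXACT_WILCOXON_MAX_N = 25


def binarize_labels(labels: Sequence[str]) -> list[str]:
    """Collapse five-level adjudications to CN/CI: normal -> CN, rest -> CI."""
    out = []
    for lab in labels:
        if lab not in FIVE_CLASS_LABELS:
            raise ValueError(
                f"unknown five-class label {lab!r}; expected one of {FIVE_CLASS_LABELS}"
            )
        out.append("CN" if lab == "normal" else "CI")
    return out


def filter_undetermined(
    pairs: Sequence[tuple[str, str]]
) -> tuple[list[tuple[str, str]], int]:
    """Drop pairs whose first (tool-side) label is ``undetermined``.

    Returns ``(kept_pairs, n_excluded)``.
    """
    kept = [p for p in pairs if p[0] != "undetermined"]
    return kept, len(pairs) - len(kept)


@dataclass(frozen=True)
class ContingencyTable:
    categories: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]  # rows: rater A, columns: rater B

    @property
    def n(self) -> int:
        return sum(sum(row) for row in self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: Optional[float]  # None when pe == 1 (degenerate marginals)
    n: int
    excluded_undetermined: int = 0

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def cohen_kappa(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    categories: Optional[Sequence[str]] = None,
    excluded_undetermined: int = 0,
) -> tuple[KappaResult, ContingencyTable]:
    """Unweighted Cohen's kappa between two equal-length label vectors."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("cannot compute kappa on zero pairs")
    if categories is None:
        categories = sorted(set(labels_a) | set(labels_b))
    else:
        categories = list(categories)
        unknown = (set(labels_a) | set(labels_b)) - set(categories)
        if unknown:
            raise ValueError(f"labels outside the stated categories: {sorted(unknown)}")
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        counts[index[a], index[b]] += 1
    po = float(np.trace(counts)) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    pe = float(np.dot(row, col))
    kappa = None if math.isclose(pe, 1.0, abs_tol=1e-15) else (po - pe) / (1.0 - pe)
    table = ContingencyTable(
        categories=tuple(categories),
        counts=tuple(tuple(int(x) for x in r) for r in counts),
    )
    return (
        KappaResult(po=po, pe=pe, kappa=kappa, n=n,
                    excluded_undetermined=excluded_undetermined),
        table,
    )


# --------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingResult:
    n_pairs: int
    n_zero_dropped: int
    mean_diff: float
    sd_diff: float
    mean_diff_nonzero: Optional[float]
    sd_diff_nonzero: Optional[float]
    median_ratio: Optional[float]
    min_ratio: Optional[float]
    max_ratio: Optional[float]
    w_statistic: Optional[float]
    p_value: Optional[float]
    method: str  # "exact" | "normal_approx" | "undefined"


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p for W = sum of positive-difference ranks.

    Midranks are multiples of 1/2, so doubling makes them integers and the
    null distribution of 2W is a polynomial convolution: coefficient c[s] of
    the product prod_i (1 + x^(2 r_i)) counts the sign patterns with
    2W = s.  Identical counts to full 2^n enumeration, in O(n * sum r).
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(round(2 * w_obs))
    n_total = 1 << len(ranks)
    p_ge = int(sum(counts[w2:]))
    p_le = int(sum(counts[: w2 + 1]))
    p = 2 * min(p_ge, p_le) / n_total
    return min(1.0, p)


def _approx_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    # tie correction over groups of tied absolute differences
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    d = w_obs - mu
    cc = 0.5 * np.sign(d)
    z = (d - cc) / math.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


def paired_timing_test(
    times_a: Sequence[float], times_b: Sequence[float]
) -> TimingResult:
    """Paired signed-rank comparison of two per-patient timing vectors.

    Differences are ``a_i - b_i``; ratio summaries are of ``a_i / b_i`` and
    require strictly positive times (they are reported as ``None`` if any
    time is nonpositive).  Mean/SD of differences are reported both over all
    pairs and over nonzero pairs, since conventions differ.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("times_a and times_b must be equal-length 1-d vectors")
    if len(a) == 0:
        raise ValueError("at least one pair required")

    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1)) if len(d) > 1 else 0.0

    if np.all(a > 0) and np.all(b > 0):
        ratios = a / b
        median_ratio = float(np.median(ratios))
        min_ratio = float(ratios.min())
        max_ratio = float(ratios.max())
    else:
        median_ratio = min_ratio = max_ratio = None

    nonzero = d[d != 0]
    n_dropped = len(d) - len(nonzero)
    if len(nonzero) == 0:
        return TimingResult(
            n_pairs=len(d), n_zero_dropped=n_dropped,
            mean_diff=mean_diff, sd_diff=sd_diff,
            mean_diff_nonzero=None, sd_diff_nonzero=None,
            median_ratio=median_ratio, min_ratio=min_ratio, max_ratio=max_ratio,
            w_statistic=None, p_value=None, method="undefined",
        )

    ranks = sps.rankdata(np.abs(nonzero))
    w = float(ranks[nonzero > 0].sum())
    if len(nonzero) <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w)
        method = "exact"
    else:
        p = _approx_signed_rank_p(ranks, w)
        method = "normal_approx"

    return TimingResult(
        n_pairs=len(d),
        n_zero_dropped=n_dropped,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        mean_diff_nonzero=float(nonzero.mean()),
        sd_diff_nonzero=float(nonzero.std(ddof=1)) if len(nonzero) > 1 else 0.0,
        median_ratio=median_ratio,
        min_ratio=min_ratio,
        max_ratio=max_ratio,
        w_statistic=w,
        p_value=max(p, np.nextafter(0, 1)),
        method=method,
    )


# --------------------------------------------------------------------------
# Learning effect
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LearningEffect:
    n_first: int
    n_second: int
    median_first: float
    median_second: float
    u_statistic: float
    p_value: float


def learning_effect(durations: Sequence[float]) -> LearningEffect:
    """First-half vs second-half comparison of chronologically ordered times.

    With an odd count the extra observation goes to the first half.  The
    halves are compared with a two-sided rank-sum (Mann-Whitney) test.
    """
    d = np.asarray(durations, dtype=float)
    if len(d) < 4:
        raise ValueError("learning_effect requires >= 4 timed annotations")
    split = (len(d) + 1) // 2
    first, second = d[:split], d[split:]
    res = sps.mannwhitneyu(first, second, alternative="two-sided", method="auto")
    return LearningEffect(
        n_first=len(first),
        n_second=len(second),
        median_first=float(np.median(first)),
        median_second=float(np.median(second)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


# --------------------------------------------------------------------------
# Demographic summaries
# --------------------------------------------------------------------------


def percent(count: int, cohort_n: int) -> float:
    """Percent of the full cohort, rounded half-up to one decimal.

    Missing values never shrink the denominator: a variable with missing
    entries reports them separately while percents stay out of 100% of the
    cohort.
    """
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    pct = Decimal(100 * count) / Decimal(cohort_n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoricalCell:
    count: int
    pct: float


@dataclass(frozen=True)
class DemographicSummary:
    cohort_n: int
    sex: dict[str, CategoricalCell]
    sex_missing: int
    minorities: dict[str, CategoricalCell]  # per-group, plus key "total"
    ethnicity_missing: int
    college: CategoricalCell
    education_missing: int
    married: CategoricalCell
    marital_missing: int
    age_mean: float
    age_sd: float
    encounters_median: float
    encounters_min: int
    encounters_max: int
    pcp_visit: CategoricalCell
    dementia_signal: CategoricalCell  # dementia ICD code or medication


def demographic_summary(charts: Sequence[PatientChart]) -> DemographicSummary:
    """Cohort characteristics table from a list of charts.

    Ages are completed years at each chart's period end (period end
    required).  ``dementia_signal`` counts patients whose chart carries a
    dementia ICD code or dementia medication.
    """
    if not charts:
        raise ValueError("cannot summarize an empty cohort")
    n = len(charts)
    patients = [c.patient for c in charts]

    def cell(count: int) -> CategoricalCell:
        return CategoricalCell(count=count, pct=percent(count, n))

    sex_counts = {
        s.value: sum(1 for p in patients if p.sex is s)
        for s in (Sex.MALE, Sex.FEMALE, Sex.OTHER)
    }
    minorities = {
        g.value: cell(sum(1 for p in patients if p.ethnic_group is g))
        for g in MINORITY_GROUPS
    }
    minority_total = sum(
        1 for p in patients if p.ethnic_group in MINORITY_GROUPS
    )
    minorities["total"] = cell(minority_total)

    ages = []
    for c in charts:
        if c.period_end is None:
            raise ValueError(
                f"chart of patient {c.patient.patient_id!r} has no period_end; "
                "age cannot be computed"
            )
        ages.append(c.patient.age_years(c.period_end))
    ages_arr = np.asarray(ages, dtype=float)
    enc = np.asarray([len(c.encounters) for c in charts], dtype=float)

    dementia_n = 0
    for c in charts:
        med_flag, _ = flag_dementia_medications(c.medications)
        icd_flag, _ = flag_dementia_icd(c.diagnoses)
        if med_flag or icd_flag:
            dementia_n += 1

    return DemographicSummary(
        cohort_n=n,
        sex={k: cell(v) for k, v in sex_counts.items() if v or k in ("male", "female")},
        sex_missing=sum(1 for p in patients if p.sex is Sex.MISSING),
        minorities=minorities,
        ethnicity_missing=sum(
            1 for p in patients if p.ethnic_group.value == "missing"
        ),
        college=cell(
            sum(1 for p in patients if p.education is Education.COLLEGE_OR_MORE)
        ),
        education_missing=sum(
            1 for p in patients if p.education is Education.MISSING
        ),
        married=cell(
            sum(1 for p in patients if p.marital_status is MaritalStatus.MARRIED)
        ),
        marital_missing=sum(
            1 for p in patients if p.marital_status is MaritalStatus.MISSING
        ),
        age_mean=float(ages_arr.mean()),
        age_sd=float(ages_arr.std(ddof=1)) if n > 1 else 0.0,
        encounters_median=float(np.median(enc)),
        encounters_min=int(enc.min()),
        encounters_max=int(enc.max()),
        pcp_visit=cell(sum(1 for p in patients if p.pcp_id)),
        dementia_signal=cell(dementia_n),
    )
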