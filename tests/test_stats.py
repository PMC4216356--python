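"""EVLW mapping, diagnostic metrics, agreement/kappa, and the binary NRI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta

from edemascore import (
    CallMatrix,
    ConfusionCounts,
    InputError,
    PairingError,
    ReferenceStandard,
    agreement_stats,
    binary_nri,
    classify_evlw,
    diagnostic_metrics,
    exclude_borderline,
    free_marginal_kappa,
    pairwise_agreement,
    per_reader_confusion,
    pooled_confusion,
    proportion_ci,
)


def make_matrix(bool_rows, readers=None, cases=None):
    import pandas as pd

    arr = np.asarray(bool_rows, dtype=bool)
    readers = readers or [f"r{i}" for i in range(arr.shape[0])]
    cases = cases or [f"c{j}" for j in range(arr.shape[1])]
    return CallMatrix(pd.DataFrame(arr, index=readers, columns=cases))


def make_refs(case_status):
    """Build a reference from {case_id: True(edema)/False(no_edema)}."""
    return [
        ReferenceStandard(c, 18 if is_event else 6)
        for c, is_event in case_status.items()
    ]


class TestClassifyEvlw:
    @pytest.mark.parametrize(
        "evlw, expected",
        [
            (7, "no_edema"), (21, "edema"), (12, "borderline"),
            (8, "no_edema"), (8.4, "no_edema"), (8.5, "borderline"),
            (14.4, "borderline"), (14.5, "edema"), (15, "edema"), (4, "no_edema"),
        ],
    )
    def test_banding_with_half_up_rounding(self, evlw, expected):
        assert classify_evlw(evlw) == expected

    @pytest.mark.parametrize("bad", [0, -3, float("nan"), float("inf")])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(InputError):
            classify_evlw(bad)

    def test_reference_standard_derives_status(self):
        assert ReferenceStandard("x", 16).status == "edema"


class TestConfusion:
    def test_pooled_counts_score_arm(self, paper_study):
        _, score, refs = paper_study
        c = pooled_confusion(score, refs)
        assert (c.tp, c.fn, c.tn, c.fp) == (54, 16, 70, 0)

    def test_pooled_counts_standard_arm(self, paper_study):
        std, _, refs = paper_study
        c = pooled_confusion(std, refs)
        assert (c.tp, c.fn, c.tn, c.fp) == (40, 30, 63, 7)

    def test_perfect_single_reader(self):
        status = {f"e{i}": True for i in range(10)} | {f"n{i}": False for i in range(10)}
        calls = make_matrix([[c.startswith("e") for c in status]], cases=list(status))
        c = pooled_confusion(calls, make_refs(status))
        assert (c.tp, c.fn, c.tn, c.fp) == (10, 0, 10, 0)

    def test_per_reader_counts_sum_to_pooled(self, paper_study):
        std, _, refs = paper_study
        per = per_reader_confusion(std, refs)
        assert sum(c.tp for c in per.values()) == pooled_confusion(std, refs).tp
        assert per["reader_3"].tn == 6

    def test_missing_reference_is_pairing_error(self, paper_study):
        std, _, refs = paper_study
        with pytest.raises(PairingError, match="E01"):
            pooled_confusion(std, refs[1:])

    def test_borderline_case_must_be_excluded_first(self):
        calls = make_matrix([[True, False]], cases=["a", "b"])
        refs = [ReferenceStandard("a", 18), ReferenceStandard("b", 12)]
        with pytest.raises(InputError, match="borderline"):
            pooled_confusion(calls, refs)
        kept, dropped = exclude_borderline(calls, refs)
        assert dropped == ["b"] and kept.cases == ("a",)


class TestDiagnosticMetrics:
    def test_score_arm_point_estimates(self):
        m = diagnostic_metrics(ConfusionCounts(tp=54, fp=0, tn=70, fn=16))
        assert m.sensitivity.value == pytest.approx(100 * 54 / 70)
        assert m.specificity.value == pytest.approx(100.0)
        assert m.ppv.value == pytest.approx(100.0)
        assert m.npv.value == pytest.approx(100 * 70 / 86)

    def test_standard_arm_point_estimates(self):
        m = diagnostic_metrics(ConfusionCounts(tp=40, fp=7, tn=63, fn=30))
        assert m.sensitivity.value == pytest.approx(100 * 40 / 70)
        assert m.specificity.value == pytest.approx(90.0)
        assert m.ppv.value == pytest.approx(100 * 40 / 47)
        assert m.npv.value == pytest.approx(100 * 63 / 93)

    def test_perfect_reader_all_100(self):
        m = diagnostic_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert [x.value for x in (m.sensitivity, m.specificity, m.ppv, m.npv)] == [100] * 4

    def test_point_estimate_inside_ci(self):
        m = diagnostic_metrics(ConfusionCounts(tp=54, fp=0, tn=70, fn=16))
        for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
            lo, hi = est.ci
            assert lo <= est.value <= hi
            assert 0 <= lo <= hi <= 100

    def test_undefined_ppv_flagged_not_forced(self):
        # no positive calls at all: PPV denominator is zero
        m = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=10))
        assert not m.ppv.defined and m.ppv.value is None and m.ppv.ci is None
        assert m.npv.defined

    def test_requires_both_groups(self):
        with pytest.raises(InputError):
            diagnostic_metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=5))


class TestProportionCI:
    def test_all_successes_closed_form(self):
        lo, hi = proportion_ci(70, 70, "clopper_pearson", 0.95)
        assert lo == pytest.approx(100 * 0.025 ** (1 / 70), abs=1e-9)
        assert hi == 100.0

    def test_zero_successes_mirror(self):
        lo, hi = proportion_ci(0, 70, "clopper_pearson", 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(100 * (1 - 0.025 ** (1 / 70)), abs=1e-9)

    def test_matches_beta_quantile_oracle(self):
        lo, hi = proportion_ci(54, 70, "clopper_pearson", 0.95)
        assert lo == pytest.approx(100 * beta.ppf(0.025, 54, 70 - 54 + 1), abs=1e-9)
        assert hi == pytest.approx(100 * beta.ppf(0.975, 54 + 1, 70 - 54), abs=1e-9)

    def test_wilson_matches_closed_form(self):
        x, n, z = 54, 70, 1.959963984540054
        p = x / n
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        lo, hi = proportion_ci(x, n, "wilson", 0.95)
        assert lo == pytest.approx(100 * (centre - half), abs=1e-6)
        assert hi == pytest.approx(100 * (centre + half), abs=1e-6)

    @pytest.mark.parametrize("bad", [(1, 0), (-1, 10), (11, 10)])
    def test_input_validation(self, bad):
        with pytest.raises(InputError):
            proportion_ci(*bad)

    def test_coverage_at_least_nominal(self):
        """Clopper-Pearson coverage >= 95% over binomial draws at n = 70."""
        n, reps = 70, 10_000
        bounds = np.array([proportion_ci(x, n) for x in range(n + 1)])
        rng = np.random.default_rng(20140940)
        for p in (0.5, 0.77, 0.9, 1.0):
            draws = rng.binomial(n, p, size=reps)
            lo, hi = bounds[draws, 0], bounds[draws, 1]
            coverage = np.mean((lo <= 100 * p) & (100 * p <= hi))
            assert coverage >= 0.95


class TestAgreement:
    def test_unanimous_readers(self):
        calls = make_matrix(np.ones((7, 20), dtype=bool))
        assert pairwise_agreement(calls) == 1.0

    def test_two_readers_always_disagreeing(self):
        calls = make_matrix([[True] * 5, [False] * 5])
        assert pairwise_agreement(calls) == 0.0

    def test_four_three_split_single_case(self):
        calls = make_matrix([[True]] * 4 + [[False]] * 3)
        assert pairwise_agreement(calls) == pytest.approx(9 / 21)

    def test_single_reader_rejected(self):
        with pytest.raises(InputError):
            pairwise_agreement(make_matrix([[True, False]]))

    @pytest.mark.parametrize("p0, k, expected", [(0.84, 2, 0.68), (0.67, 2, 0.34)])
    def test_published_kappa_pairs(self, p0, k, expected):
        assert free_marginal_kappa(p0, k) == pytest.approx(expected)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_chance_agreement_gives_zero(self, k):
        assert free_marginal_kappa(1 / k, k) == pytest.approx(0.0)

    def test_kappa_input_validation(self):
        with pytest.raises(InputError):
            free_marginal_kappa(0.5, 1)
        with pytest.raises(InputError):
            free_marginal_kappa(1.2, 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        rows=st.integers(2, 6), cols=st.integers(1, 8), seed=st.integers(0, 2**20)
    )
    def test_kappa_invariant_to_relabeling_and_permutation(self, rows, cols, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((rows, cols)) < 0.5
        base = agreement_stats(make_matrix(arr))
        flipped = agreement_stats(make_matrix(~arr))
        permuted = agreement_stats(
            make_matrix(arr[rng.permutation(rows)][:, rng.permutation(cols)])
        )
        assert flipped.kappa_free == pytest.approx(base.kappa_free)
        assert permuted.kappa_free == pytest.approx(base.kappa_free)
        # two-category identity
        assert base.kappa_free == pytest.approx(2 * base.p_overall - 1)


class TestBinaryNRI:
    def test_pooled_published_study(self, paper_study):
        std, score, refs = paper_study
        res = binary_nri(std, score, refs, scope="pooled")
        assert res.nri == pytest.approx(0.30)
        assert (res.up_events - res.down_events) == 14
        assert (res.down_nonevents - res.up_nonevents) == 7
        lo, hi = res.ci
        assert (round(lo, 2), round(hi, 2)) == (0.18, 0.42)
        assert res.p_value < 0.01

    def test_per_reader_published_study(self, paper_study):
        std, score, refs = paper_study
        per = binary_nri(std, score, refs, scope="per_reader")
        expected = [0.3, 0.1, 0.6, 0.4, 0.3, 0.1, 0.3]
        got = [per[f"reader_{i + 1}"].nri for i in range(7)]
        assert got == pytest.approx(expected)

    def test_no_reclassification_degenerate(self, paper_study):
        std, _, refs = paper_study
        res = binary_nri(std, std, refs)
        assert res.nri == 0.0 and res.se == 0.0
        assert res.p_value is None and not res.p_defined

    def test_unmatched_matrices_raise(self, paper_study):
        std, score, refs = paper_study
        truncated = std.restrict_cases(std.cases[:-1])
        with pytest.raises(PairingError):
            binary_nri(truncated, score, refs)

    def test_nri_bounded(self, paper_study):
        std, score, refs = paper_study
        assert abs(binary_nri(std, score, refs).nri) <= 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        readers=st.integers(1, 5),
        n_ev=st.integers(1, 8),
        n_nev=st.integers(1, 8),
        seed=st.integers(0, 2**20),
    )
    def test_equals_delta_sens_plus_delta_spec_oracle(self, readers, n_ev, n_nev, seed):
        """Pair-counting NRI == change in sensitivity + specificity."""
        rng = np.random.default_rng(seed)
        cases = [f"e{i}" for i in range(n_ev)] + [f"n{i}" for i in range(n_nev)]
        refs = make_refs({c: c.startswith("e") for c in cases})
        old = make_matrix(rng.random((readers, len(cases))) < 0.5, cases=cases)
        new = make_matrix(rng.random((readers, len(cases))) < 0.5, cases=cases)
        res = binary_nri(old, new, refs)
        c_old, c_new = pooled_confusion(old, refs), pooled_confusion(new, refs)
        d_sens = c_new.tp / c_new.n_events - c_old.tp / c_old.n_events
        d_spec = c_new.tn / c_new.n_nonevents - c_old.tn / c_old.n_nonevents
        assert res.nri == pytest.approx(d_sens + d_spec, abs=1e-12)

    def test_pooled_sensitivity_is_mean_of_per_reader(self, paper_study):
        """Balanced design: pooled sens == unweighted mean over readers."""
        std, _, refs = paper_study
        pooled = pooled_confusion(std, refs)
        per = per_reader_confusion(std, refs)
        per_sens = [c.tp / c.n_events for c in per.values()]
        assert pooled.tp / pooled.n_events == pytest.approx(np.mean(per_sens))
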