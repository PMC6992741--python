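"""Metric-panel arithmetic: formula-level oracle checks, null semantics,
and inversion of printed rates back to integer counts."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirmeta.metrics import (
    ConfusionCounts,
    chl_index,
    counts_from_rates,
    panel_from_counts,
    round4,
    write_metric_report,
)


def oracle_panel(tp, fn, fp, tn):
    """Direct, independent evaluation of the metric formulas."""
    n = tp + fn + fp + tn
    acc = (tp + tn) / n
    sn = tp / (tp + fn) if tp + fn else None
    sp = tn / (tn + fp) if tn + fp else None
    prec = tp / (tp + fp) if tp + fp else None
    f1 = (
        2 * prec * sn / (prec + sn)
        if prec is not None and sn is not None and prec + sn > 0
        else (0.0 if prec is not None and sn is not None else None)
    )
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    mccp = (mcc + 1) / 2
    if f1 is None:
        chl = None
    else:
        s = acc * mccp + mccp * f1 + f1 * acc
        chl = 3 * acc * mccp * f1 / s if s > 0 else None
    return sn, sp, acc, prec, f1, mcc, mccp, chl


class TestPanelFromCounts:
    def test_near_perfect_cv_row(self):
        # counts reconstructed from a published CV row with 2588 pairs/side
        p = panel_from_counts(ConfusionCounts(tp=2586, fn=2, fp=5, tn=2583))
        assert round4(p.sn) == 0.9992
        assert round4(p.sp) == 0.9981
        assert round4(p.acc) == 0.9986
        assert round4(p.f1) == 0.9986
        assert round4(p.mcc) == 0.9973
        assert round4(p.mcc_prime) == 0.9986
        assert round4(p.chl) == 0.9986

    def test_all_negative_predictor_null_semantics(self):
        # no positive call: MCC is 0 by convention, F1 and CHL are undefined
        p = panel_from_counts(ConfusionCounts(tp=0, fn=10, fp=0, tn=10))
        assert p.sn == 0.0
        assert p.sp == 1.0
        assert p.mcc == 0.0
        assert p.mcc_prime == 0.5
        assert p.precision is None
        assert p.f1 is None
        assert p.chl is None

    def test_perfect_classifier(self):
        p = panel_from_counts(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        for v in (p.sn, p.sp, p.acc, p.precision, p.f1, p.mcc, p.mcc_prime, p.chl):
            assert v == 1.0

    def test_empty_evaluation_rejected(self):
        with pytest.raises(ValueError, match="empty evaluation"):
            panel_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)

    def test_agrees_with_formula_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fn, fp, tn = (int(v) for v in rng.integers(0, 200, size=4))
            if tp + fn + fp + tn == 0:
                continue
            p = panel_from_counts(ConfusionCounts(tp, fn, fp, tn))
            expected = oracle_panel(tp, fn, fp, tn)
            got = (p.sn, p.sp, p.acc, p.precision, p.f1, p.mcc, p.mcc_prime, p.chl)
            for g, e in zip(got, expected):
                if e is None:
                    assert g is None
                else:
                    assert g == pytest.approx(e, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fn, fp, tn = (int(v) + 1 for v in rng.integers(0, 50, size=4))
            a = panel_from_counts(ConfusionCounts(tp, fn, fp, tn))
            b = panel_from_counts(ConfusionCounts(tn, fp, fn, tp))
            assert a.acc == pytest.approx(b.acc)
            assert a.mcc == pytest.approx(b.mcc)
            assert a.sn == pytest.approx(b.sp)
            assert a.sp == pytest.approx(b.sn)

    def test_mcc_prime_is_affine_map(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            tp, fn, fp, tn = (int(v) + 1 for v in rng.integers(0, 50, size=4))
            p = panel_from_counts(ConfusionCounts(tp, fn, fp, tn))
            assert p.mcc_prime == pytest.approx((p.mcc + 1) / 2, abs=1e-15)
        assert panel_from_counts(ConfusionCounts(0, 5, 0, 5)).mcc_prime == 0.5


class TestCHLIndex:
    @pytest.mark.parametrize(
        "acc,mccp,f1,expected",
        [
            (1.0, 1.0, 1.0, 1.0),
            # published independent-test row; inputs are 4-decimal roundings,
            # so the recomputed value matches within a propagated half-ULP
            (0.7900, 0.5905, 0.8760, 0.7316),
            (0.4498, 0.5571, 0.5453, 0.5127),
        ],
    )
    def test_published_values(self, acc, mccp, f1, expected):
        assert chl_index(acc, mccp, f1) == pytest.approx(expected, abs=1.01e-4)

    def test_zero_input_with_positive_pairwise_product(self):
        assert chl_index(0.0, 0.5, 0.5) == 0.0

    def test_all_pairwise_products_zero_is_undefined(self):
        assert chl_index(0.0, 0.0, 1.0) is None
        assert chl_index(0.0, 0.0, 0.0) is None

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5), (0.5, 0.5, 2.0)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            chl_index(*bad)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(0.01, 1.0),
        st.floats(0.01, 1.0),
        st.floats(0.01, 1.0),
        st.floats(0.001, 0.2),
    )
    def test_strictly_increasing_in_each_argument(self, a, m, f, eps):
        base = chl_index(a, m, f)
        for bumped in (
            chl_index(min(a + eps, 1.0), m, f),
            chl_index(a, min(m + eps, 1.0), f),
            chl_index(a, m, min(f + eps, 1.0)),
        ):
            assert bumped >= base - 1e-12
        if a + eps <= 1.0:
            assert chl_index(a + eps, m, f) > base

    def test_between_min_and_max_of_components(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, m, f = rng.uniform(0.05, 1.0, size=3)
            c = chl_index(a, m, f)
            assert min(a, m, f) <= c <= max(a, m, f)


class TestCountsFromRates:
    @pytest.mark.parametrize(
        "sn,sp,P,N,expected",
        [
            (0.9992, 0.9981, 2588, 2588, (2586, 2, 5, 2583)),
            (1.0, 1.0, 10, 10, (10, 0, 0, 10)),
            (0.8840, 0.2900, 1248, 241, (1103, 145, 171, 70)),
        ],
    )
    def test_examples(self, sn, sp, P, N, expected):
        c = counts_from_rates(sn, sp, P, N)
        assert (c.tp, c.fn, c.fp, c.tn) == expected

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            P, N = (int(v) for v in rng.integers(1, 400, size=2))
            sn, sp = rng.uniform(0, 1, size=2)
            c = counts_from_rates(sn, sp, P, N)
            best_tp = min(range(P + 1), key=lambda t: (abs(t / P - sn), -t))
            best_tn = min(range(N + 1), key=lambda t: (abs(t / N - sp), -t))
            assert (c.tp, c.tn) == (best_tp, best_tn)

    def test_tie_goes_to_larger_count(self):
        # sn = 0.5 with P = 2: tp/P is 0.0, 0.5, 1.0 -> exact hit; P=4, sn=0.625
        # midpoint case: P=2, sn=0.25 is equidistant from tp=0 and tp=1
        c = counts_from_rates(0.25, 1.0, 2, 1)
        assert c.tp == 1

    def test_round_trip_reproduces_rates(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            P, N = (int(v) + 1 for v in rng.integers(1, 500, size=2))
            sn, sp = rng.uniform(0, 1, size=2)
            p = panel_from_counts(counts_from_rates(sn, sp, P, N))
            assert abs(p.sn - sn) <= 1 / (2 * min(P, N)) + 1e-12
            assert abs(p.sp - sp) <= 1 / (2 * min(P, N)) + 1e-12

    def test_requires_positive_sizes(self):
        with pytest.raises(ValueError):
            counts_from_rates(0.5, 0.5, 0, 10)


def test_report_writer_renders_null():
    p = panel_from_counts(ConfusionCounts(0, 10, 0, 10))
    buf = io.StringIO()
    write_metric_report([("all_negative", p)], buf, header_comment="seed=1")
    lines = buf.getvalue().splitlines()
    assert lines[0] == "# seed=1"
    assert lines[1].split("\t") == ["method", "Sn", "Sp", "Acc", "F1", "MCC", "MCCprime", "CHL"]
    cells = lines[2].split("\t")
    assert cells[0] == "all_negative"
    assert cells[4] == "null"  # F1
    assert cells[5] == "0.0000"  # MCC zero-denominator convention
    assert cells[7] == "null"  # CHL
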