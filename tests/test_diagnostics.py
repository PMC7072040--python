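"""Diagnostic statistics against independent oracles and printed tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxaspine import (
    DiagnosticTable,
    chi2_association,
    cohen_kappa,
    confusion,
    percent_agreement,
    project_population,
    roc_auc,
    row_percentages,
    sens_spec,
    sweep_cutoffs,
    unpaired_t_test,
)
from dxaspine.errors import (
    DegenerateInputError,
    InvalidInputError,
    UndefinedMarginError,
)


# --- confusion and rates ----------------------------------------------------------


def test_confusion_worked_example():
    t = confusion([1, 1, 0, 0, 1, 0], [1, 0, 0, 1, 1, 0])
    assert (t.tp, t.fp, t.fn, t.tn) == (2, 1, 1, 2)
    assert t.total == 6


def test_confusion_degenerate_cases():
    t = confusion([1, 1, 1], [1, 1, 1])
    assert (t.tp, t.fp, t.fn, t.tn) == (3, 0, 0, 0)
    t = confusion([1, 0], [0, 1])
    assert (t.tp, t.tn) == (0, 0)
    with pytest.raises(InvalidInputError):
        confusion([1, 0], [1])


def test_sens_spec_hand_and_projected_counts():
    assert sens_spec(DiagnosticTable(tp=2, fn=1, tn=2, fp=1)) == (2 / 3, 2 / 3)
    se, sp = sens_spec(DiagnosticTable(tp=510, fn=80, tn=9118, fp=292))
    assert round(100 * se, 1) == 86.4  # 510/590 reflects count rounding of 86.5
    assert round(100 * sp, 1) == 96.9
    assert sens_spec(DiagnosticTable(tp=5, fn=0, tn=7, fp=0)) == (1.0, 1.0)
    with pytest.raises(UndefinedMarginError):
        sens_spec(DiagnosticTable(tp=0, fn=0, tn=1, fp=1))


# --- ROC / AUC --------------------------------------------------------------------


def _auc_oracle(scores, truth):
    """Exhaustive pairwise Mann-Whitney statistic, ties counting 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=10).auc == pytest.approx(0.75)
    assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1], n_boot=10).auc == pytest.approx(0.5)
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=10).auc == pytest.approx(1.0)
    with pytest.raises(DegenerateInputError):
        roc_auc([0.1, 0.2], [1, 1])


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=50),
    data=st.data(),
)
def test_auc_equals_exhaustive_pair_oracle(scores, data):
    n = len(scores)
    truth = data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda t: 0 < sum(t) < n
        )
    )
    res = roc_auc(scores, truth, n_boot=5)
    assert res.auc == pytest.approx(_auc_oracle(scores, truth), abs=1e-12)


def test_auc_ci_brackets_point_estimate():
    rng = np.random.default_rng(0)
    scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)])
    truth = np.array([0] * 40 + [1] * 40)
    res = roc_auc(scores, truth, n_boot=500, seed=1)
    assert res.ci_low <= res.auc <= res.ci_high
    assert res.ci_high - res.ci_low < 0.5


# --- population projection --------------------------------------------------------


def test_projection_final_operating_point():
    """Sens 86.5%, spec 96.9% at prevalence 5.9% on n=10,000."""
    res = project_population(0.865, 0.969, 0.059, 10_000)
    t = res.table
    assert (t.tp, t.fn, t.tn, t.fp) == (510, 80, 9118, 292)
    assert res.ppv_pct == 63.6
    assert res.npv_pct == 99.1
    assert res.predicted_prevalence_pct == 8.0


def test_projection_perfect_classifier():
    res = project_population(1.0, 1.0, 0.2, 500)
    assert res.ppv_pct == 100.0 and res.npv_pct == 100.0
    assert res.predicted_prevalence == pytest.approx(0.2)


def test_projection_undefined_ppv():
    with pytest.raises(UndefinedMarginError):
        project_population(0.0, 1.0, 0.1, 100)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    sens=st.floats(0.5, 1.0),
    spec=st.floats(0.05, 0.95),
    prev=st.floats(0.01, 0.5),
    n=st.integers(100, 20_000),
)
def test_projection_conserves_total_and_inverts(sens, spec, prev, n):
    res = project_population(sens, spec, prev, n)
    t = res.table
    assert t.total == n
    p_total = t.tp + t.fn
    assert p_total == int(np.floor(n * prev + 0.5))
    # recomputing the rates from the projected integer table returns the
    # inputs within count-rounding error
    se_back, sp_back = sens_spec(t)
    assert abs(se_back - sens) <= 0.5 / p_total + 1e-12
    assert abs(sp_back - spec) <= 0.5 / (n - p_total) + 1e-12


# --- cut-off sweep ----------------------------------------------------------------


def test_sweep_monotone_and_reproducible():
    rng = np.random.default_rng(7)
    truth = rng.random(500) < 0.059
    scores = np.clip(truth * 0.7 + rng.random(500) * 0.6, 0, 1)
    cutoffs = [0.95, 0.98, 0.99, 0.995, 0.999, 0.9995]
    # scores concentrated below the cutoffs still exercise the sweep
    rows1 = sweep_cutoffs(scores, truth.astype(int), cutoffs, seed=3, n_boot=50)
    rows2 = sweep_cutoffs(scores, truth.astype(int), cutoffs, seed=3, n_boot=50)
    sens = [r.sensitivity for r in rows1]
    spec = [r.specificity for r in rows1]
    assert all(a >= b for a, b in zip(sens, sens[1:]))
    assert all(a <= b for a, b in zip(spec, spec[1:]))
    assert [(r.sensitivity, r.specificity, r.auc.auc) for r in rows1] == [
        (r.sensitivity, r.specificity, r.auc.auc) for r in rows2
    ]


def test_sweep_rejects_unsorted_cutoffs():
    with pytest.raises(InvalidInputError):
        sweep_cutoffs([0.5, 0.6], [1, 0], [0.9, 0.8])


# --- Cohen's kappa ----------------------------------------------------------------


def _table_to_ratings(a, b, c, d):
    """2x2 agreement table (a: both pos, b: A pos/B neg, c: A neg/B pos, d: both neg)."""
    ra = [1] * (a + b) + [0] * (c + d)
    rb = [1] * a + [0] * b + [1] * c + [0] * d
    return np.array(ra), np.array(rb)


def test_kappa_identical_ratings():
    res = cohen_kappa([0, 1, 0, 1, 1], [0, 1, 0, 1, 1])
    assert res.kappa == pytest.approx(1.0)
    assert res.percent_agreement == 1.0
    assert res.band() == "almost perfect"


def test_kappa_hand_example():
    # table (20, 5; 5, 70): p_o = 0.9, p_e = 0.25^2 + 0.75^2 = 0.625
    ra, rb = _table_to_ratings(20, 5, 5, 70)
    res = cohen_kappa(ra, rb)
    assert res.percent_agreement == pytest.approx(0.9)
    assert res.kappa == pytest.approx((0.9 - 0.625) / (1 - 0.625), abs=1e-12)
    assert res.kappa == pytest.approx(0.7333, abs=1e-4)
    assert res.ci_low <= res.kappa <= res.ci_high


def test_kappa_matches_sklearn_on_small_table_sweep():
    """Exhaustive sweep of small 2x2 agreement tables vs the independent oracle."""
    from sklearn.metrics import cohen_kappa_score

    for a in range(7):
        for b in range(7):
            for c in range(7):
                for d in range(7):
                    n = a + b + c + d
                    if n < 2:
                        continue
                    ra, rb = _table_to_ratings(a, b, c, d)
                    res = cohen_kappa(ra, rb)
                    if not res.defined:
                        continue
                    assert res.kappa == pytest.approx(
                        cohen_kappa_score(ra, rb), abs=1e-9
                    ), (a, b, c, d)


def test_kappa_undefined_when_both_raters_constant():
    res = cohen_kappa([1, 1, 1], [1, 1, 1])
    assert not res.defined
    assert res.percent_agreement == 1.0


# --- association tests ------------------------------------------------------------


def test_chi2_zero_when_observed_equal_expected():
    stat, p, dof, _ = chi2_association([[10, 20], [20, 40]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert dof == 1


def test_chi2_hand_example():
    stat, p, _, _ = chi2_association([[10, 20], [20, 10]])
    assert stat == pytest.approx(20 / 3, abs=1e-9)


def test_chi2_gender_association_highly_significant():
    # scoliosis-by-gender counts: males 1526/136, females 1709/313
    stat, p, _, _ = chi2_association([[1526, 136], [1709, 313]])
    assert p < 0.001


def test_chi2_rejects_zero_margin():
    with pytest.raises(InvalidInputError):
        chi2_association([[0, 0], [1, 2]])


def test_row_percentages_printed_gender_rows():
    out = row_percentages([[1709, 313], [1526, 136]])
    assert out[0].tolist() == [84.5, 15.5]   # female row
    assert out[1].tolist() == [91.8, 8.2]    # male row
    assert row_percentages([[1, 1]])[0].tolist() == [50.0, 50.0]


def test_row_percentages_rejects_zero_row():
    with pytest.raises(InvalidInputError):
        row_percentages([[0, 0]])


def test_t_test_hand_example_and_symmetry():
    stat, p, (ma, sa), (mb, sb) = unpaired_t_test([1, 2, 3], [4, 5, 6])
    assert stat == pytest.approx(-3.674, abs=1e-3)
    assert (ma, mb) == (2.0, 5.0)
    stat_sw, p_sw, _, _ = unpaired_t_test([4, 5, 6], [1, 2, 3])
    assert stat_sw == pytest.approx(-stat)
    assert p_sw == pytest.approx(p)


def test_t_test_identical_groups_zero_statistic():
    stat, _, _, _ = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_t_test_degenerate_variance_rejected():
    with pytest.raises(DegenerateInputError):
        unpaired_t_test([2.0, 2.0], [2.0, 2.0])


def test_percent_agreement():
    assert percent_agreement([1, 0, 1, 1, 0], [1, 1, 1, 0, 0]) == pytest.approx(0.6)
    assert percent_agreement([1, 1], [1, 1]) == 1.0
    assert percent_agreement([1, 1], [0, 0]) == 0.0
    with pytest.raises(InvalidInputError):
        percent_agreement([1], [1, 0])
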