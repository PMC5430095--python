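"""Caller behavior: the quality-floor sweep, score thresholding, bias
attributes and the post-call filters."""

import numpy as np
import pytest

from panelcall.config import SNVConfig
from panelcall.pileup import PileupColumn, ReadObservation
from panelcall.snv import (NoCall, VariantCall, apply_post_filters,
                           call_variant_at_column, is_homopolymer_context,
                           pv4_attributes, tail_distance_bias_test)
from tests.conftest import build_column

CFG = SNVConfig()


def test_snv_at_4pct_of_400x_is_called():
    """16/400 alt at Q30: the binomial tail is ~1e-20, far past score 50."""
    col = build_column(n_ref=384, n_alt=16, seed=1)
    call = call_variant_at_column(col, CFG)
    assert isinstance(call, VariantCall)
    assert call.alt == "T"
    assert call.sr_percent == pytest.approx(4.0)
    assert call.score == pytest.approx(199.766, abs=0.01)   # frozen brute-force tail
    assert call.qt_called == 20


def test_no_variant_no_call():
    col = build_column(n_ref=400, n_alt=0)
    res = call_variant_at_column(col, CFG)
    assert isinstance(res, NoCall)


def test_single_variant_read_below_threshold():
    """k=1 in 100 Q30 bases: P = 1-(1-0.001)^100 ≈ 0.095, score ≈ 10.2 < 50."""
    col = build_column(n_ref=99, n_alt=1, alt_qual=35, seed=2, pos=7)
    res = call_variant_at_column(col, SNVConfig(min_coverage=100))
    assert isinstance(res, NoCall)
    assert res.reason == "below score threshold"


def test_low_coverage_flagged_not_called():
    col = build_column(n_ref=100, n_alt=40)
    res = call_variant_at_column(col, CFG)
    assert isinstance(res, NoCall)
    assert res.reason == "low_coverage"


def test_all_bases_below_every_qt():
    col = build_column(n_ref=140, n_alt=60, qual=10, alt_qual=10)
    res = call_variant_at_column(col, CFG)
    assert isinstance(res, NoCall)
    assert res.reason == "no qualifying bases"


def test_qt_sweep_inert_on_uniform_q30():
    """On an all-Q30 column every floor in 20..30 retains everything, so a
    variant called at 20 is called throughout and qt_called == 20."""
    col = build_column(n_ref=300, n_alt=100, seed=3)
    call = call_variant_at_column(col, CFG)
    assert call.qt_called == 20
    # restricting the sweep to any single Qt must give the same score
    for qt in range(20, 31):
        single = call_variant_at_column(col, SNVConfig(qt_min=qt, qt_max=qt))
        assert single.score == pytest.approx(call.score)


def test_qt_sweep_rescues_variant_masked_by_low_quality_outlier():
    """One Q5 outlier base drags e to 0.32 at Qt<=5 and kills the test; the
    sweep floors it away and recovers the variant."""
    obs = [ReadObservation("A", 30, "+-"[i % 2], 10) for i in range(280)]
    obs += [ReadObservation("T", 30, "+-"[i % 2], 10) for i in range(20)]
    obs += [ReadObservation("G", 5, "+", 10)]
    col = PileupColumn("chr1", 0, "A", obs)
    wide = call_variant_at_column(col, SNVConfig(qt_min=2, qt_max=30))
    assert isinstance(wide, VariantCall) and wide.alt == "T"
    assert wide.qt_called > 5


def test_observation_order_irrelevant():
    col = build_column(n_ref=350, n_alt=50, seed=4)
    rng = np.random.default_rng(0)
    shuffled = list(col.observations)
    rng.shuffle(shuffled)
    col2 = PileupColumn(col.chrom, col.pos, col.ref_base, shuffled)
    a = call_variant_at_column(col, CFG)
    b = call_variant_at_column(col2, CFG)
    assert (a.alt, a.score, a.qt_called, a.alt_count) == (b.alt, b.score, b.qt_called, b.alt_count)


def test_tie_break_is_lexicographic():
    obs = [ReadObservation("A", 30, "+-"[i % 2], 10) for i in range(300)]
    obs += [ReadObservation("G", 30, "+", 10) for _ in range(30)]
    obs += [ReadObservation("C", 30, "-", 10) for _ in range(30)]
    col = PileupColumn("chr1", 0, "A", obs)
    call = call_variant_at_column(col, CFG)
    assert call.alt == "C"   # equal counts: C before G


def test_sr_percent_uses_full_depth():
    """%SR is quoted against raw depth even when low-quality bases were
    excluded from the test itself."""
    obs = [ReadObservation("A", 30, "+-"[i % 2], 10) for i in range(160)]
    obs += [ReadObservation("A", 10, "+", 10) for _ in range(20)]   # below every Qt
    obs += [ReadObservation("T", 30, "+-"[i % 2], 10) for i in range(20)]
    col = PileupColumn("chr1", 0, "A", obs)
    call = call_variant_at_column(col, CFG)
    assert call.depth == 200
    assert call.sr_percent == pytest.approx(10.0)


def test_score_pvalue_consistency():
    col = build_column(n_ref=384, n_alt=16, seed=5)
    call = call_variant_at_column(col, CFG)
    assert call.score == pytest.approx(-10 * np.log10(call.p_value), rel=1e-9)


# ---------------------------------------------------------------------------
# bias tests
# ---------------------------------------------------------------------------

def test_tail_bias_identical_distances():
    assert tail_distance_bias_test([5, 10, 15], [5, 10, 15]) == pytest.approx(1.0)


def test_tail_bias_single_alt_read_not_applicable():
    assert tail_distance_bias_test([3], []) == 1.0


def test_tail_bias_end_clustered_alt():
    rng = np.random.default_rng(1)
    alt = rng.integers(0, 3, size=50)
    ref = rng.integers(0, 141, size=50)
    assert tail_distance_bias_test(alt, ref) < 1e-5


def test_pv4_balanced_column():
    col = build_column(n_ref=200, n_alt=40, seed=6)
    attrs = pv4_attributes(col, "T")
    assert attrs["strand_bias_p"] == pytest.approx(1.0, abs=0.05)
    assert set(attrs) == {"strand_bias_p", "baseq_bias_p", "tail_bias_p"}


def test_pv4_strand_separation():
    obs = [ReadObservation("A", 30, "+", 10) for _ in range(10)]
    obs += [ReadObservation("T", 30, "-", 10) for _ in range(10)]
    col = PileupColumn("chr1", 0, "A", obs)
    attrs = pv4_attributes(col, "T")
    assert attrs["strand_bias_p"] == pytest.approx(1.082508822446903e-05, rel=1e-6)


# ---------------------------------------------------------------------------
# homopolymer context
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("window,pos,expected", [
    ("AAAAAA", 2, True),            # run spans the anchor
    ("ACGTACGT", 3, False),
    ("GTTTTTTA", 0, True),          # run starts immediately after the anchor
    ("GCTTTTTA", 0, False),         # run of 5 only
    ("AAAAAAG", 6, False),          # run ends before the anchor: not in context
])
def test_homopolymer_context(window, pos, expected):
    assert is_homopolymer_context(window, pos, min_len=6) is expected


def test_homopolymer_window_too_small():
    with pytest.raises(ValueError):
        is_homopolymer_context("AAA", 1, min_len=6)


# ---------------------------------------------------------------------------
# post filters
# ---------------------------------------------------------------------------

def _mk_call(alt="T", sr=25.0, pos=30, tail_p=0.5):
    call = VariantCall("chr1", pos, "A", alt, 400, int(sr * 4), sr, 1e-30, 300.0, 20)
    call.attributes["tail_bias_p"] = tail_p
    return call


def test_filter_low_sr():
    call = _mk_call(sr=1.5)
    apply_post_filters([call], config=CFG)
    assert call.filter_status == {"low_sr"}


def test_filter_tail_bias():
    call = _mk_call(tail_p=1e-7)
    apply_post_filters([call], config=CFG)
    assert call.filter_status == {"tail_bias"}


def test_filter_homopolymer_indel():
    ref = {"chr1": "ACGT" * 10 + "AAAAAAA" + "CGTA" * 10}
    call = _mk_call(alt="-1", sr=8.0, pos=39)   # anchor just before the A-run
    apply_post_filters([call], reference=ref, config=CFG)
    assert call.filter_status == {"homopolymer_indel"}


def test_homopolymer_indel_kept_at_high_sr():
    ref = {"chr1": "ACGT" * 10 + "AAAAAAA" + "CGTA" * 10}
    call = _mk_call(alt="-1", sr=30.0, pos=39)
    apply_post_filters([call], reference=ref, config=CFG)
    assert call.is_pass


def test_clean_snv_passes():
    call = _mk_call()
    apply_post_filters([call], config=CFG)
    assert call.is_pass


def test_filtered_calls_are_retained_not_dropped():
    calls = [_mk_call(sr=1.0), _mk_call()]
    out = apply_post_filters(calls, config=CFG)
    assert len(out) == 2
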