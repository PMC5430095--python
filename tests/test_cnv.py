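import numpy as np
import pytest

from panelcall.cnv import (CNVError, RegionCountVector, build_normal_profile,
                           call_gene_cnv, call_sample_cnvs, gc_correct,
                           gene_weighted_cn, normalize_counts, region_cn_and_z)
from panelcall.config import CNVConfig
from panelcall.manifest import Manifest, PanelRegion

CFG = CNVConfig()


def test_normalize_proportional_to_per_base_rate(toy_manifest):
    m = Manifest([PanelRegion("chr1", 0, 100, "A", 0.5, "a"),
                  PanelRegion("chr1", 200, 400, "B", 0.5, "b")])
    v = RegionCountVector("s", [100, 200], 300)
    norm = normalize_counts(v, m)
    assert norm[0] == pytest.approx(norm[1])     # same reads-per-base


def test_normalize_scale_invariance(toy_manifest):
    counts = np.array([120, 300, 80, 200, 150])
    v1 = RegionCountVector("s", counts, 850)
    v2 = RegionCountVector("s", counts * 7, 850 * 7)
    np.testing.assert_allclose(normalize_counts(v1, toy_manifest),
                               normalize_counts(v2, toy_manifest))


def test_normalize_zero_total_errors(toy_manifest):
    with pytest.raises(CNVError):
        normalize_counts(RegionCountVector("s", [0] * 5, 0), toy_manifest)


def test_gc_correct_single_bin_is_identity():
    norm = np.array([10.0, 12.0, 8.0])
    np.testing.assert_allclose(gc_correct(norm, [0.5, 0.5, 0.5]), norm)


def test_gc_correct_two_bin_arithmetic():
    # bins at GC .30 and .60 with means 10 and 20; global mean 15:
    # bin-1 regions shift +5, bin-2 regions -5
    norm = np.array([9.0, 10.0, 11.0, 19.0, 20.0, 21.0])
    gc = np.array([0.30, 0.30, 0.30, 0.60, 0.60, 0.60])
    corrected = gc_correct(norm, gc)
    np.testing.assert_allclose(corrected, [14.0, 15.0, 16.0, 14.0, 15.0, 16.0])


def test_gc_correct_additivity():
    rng = np.random.default_rng(0)
    norm = rng.uniform(5, 15, size=12)
    gc = rng.uniform(0.3, 0.7, size=12)
    base = gc_correct(norm, gc)
    shifted = gc_correct(norm + 3.0, gc)
    np.testing.assert_allclose(shifted, base + 3.0)


# ---------------------------------------------------------------------------
# profile building
# ---------------------------------------------------------------------------

def test_profile_identical_samples_one_iteration():
    mat = np.tile([10.0, 12.0, 8.0, 9.0, 11.0], (5, 1))
    prof = build_normal_profile(mat, list("abcde"), CFG)
    assert prof.iterations == 1
    assert prof.n_samples_final == 5
    np.testing.assert_allclose(prof.mean, mat[0])
    # sd floored at 5% of mean, never zero
    np.testing.assert_allclose(prof.sd, 0.05 * mat[0])


def test_profile_eliminates_half_coverage_outlier():
    """Hand-run on a 5-region toy: sample 4 has half coverage in 2/5 regions
    (40% deviant > 10% limit) and must be dropped."""
    rng = np.random.default_rng(1)
    mat = 10.0 + rng.normal(0, 0.3, size=(5, 5))
    mat[4, [0, 1]] = 5.0
    prof = build_normal_profile(mat, list("vwxyz"), CFG)
    assert prof.n_samples_final == 4
    assert prof.iterations == 2        # one elimination round, one clean round
    assert abs(prof.mean[0] - 10.0) < 0.5


def test_profile_iteration_bound():
    rng = np.random.default_rng(2)
    mat = 10.0 + rng.normal(0, 0.2, size=(8, 10))
    prof = build_normal_profile(mat, [f"r{i}" for i in range(10)], CFG)
    assert prof.iterations <= 8 - 2 + 1


def test_profile_needs_three_samples():
    with pytest.raises(CNVError):
        build_normal_profile(np.ones((2, 4)), list("abcd"), CFG)


# ---------------------------------------------------------------------------
# CN / Z and gene calls
# ---------------------------------------------------------------------------

def _toy_profile():
    mean = np.array([10.0, 10.0, 10.0, 10.0])
    sd = np.array([0.5, 0.5, 0.5, 0.5])
    from panelcall.cnv import NormalProfile
    return NormalProfile(list("abcd"), mean, sd, 5, 1, 3.0, 0.1, 0.05)


def test_cn_and_z_at_profile_mean():
    prof = _toy_profile()
    cn, z = region_cn_and_z(prof.mean.copy(), prof)
    np.testing.assert_allclose(cn, 2.0)
    np.testing.assert_allclose(z, 0.0)


def test_cn_scales_with_coverage_ratio():
    prof = _toy_profile()
    cn, z = region_cn_and_z(prof.mean * 1.6, prof)
    np.testing.assert_allclose(cn, 3.2)          # the classic amplified-gene scale
    cn, z = region_cn_and_z(prof.mean + 3 * prof.sd, prof)
    np.testing.assert_allclose(z, 3.0)


def test_zero_mean_region_masked():
    prof = _toy_profile()
    prof.mean[2] = 0.0
    cn, _ = region_cn_and_z(np.array([10.0, 10, 10, 10]), prof)
    assert np.isnan(cn[2])


@pytest.mark.parametrize("sizes,cns,expected", [
    ([100, 100], [2.0, 4.0], 3.0),
    ([100, 300], [2.0, 4.0], 3.5),
    ([250], [2.6], 2.6),
])
def test_gene_weighted_cn(sizes, cns, expected):
    mask = np.ones(len(sizes), dtype=bool)
    assert gene_weighted_cn(np.array(cns), np.array(sizes), mask) == pytest.approx(expected)


def test_amplification_call_high_confidence():
    """20 of 23 regions above threshold with strong Z and weighted CN 3.2:
    a textbook high-confidence amplification."""
    cn = np.full(23, 3.0)
    cn[:3] = 2.0
    z = np.full(23, 4.0)
    call = call_gene_cnv("ERBB2", cn, z, weighted_cn=3.2, config=CFG)
    assert call.call == "amplification"
    assert call.n_regions_supporting == 20
    assert call.confidence == "high"


def test_neutral_gene():
    cn = np.full(10, 2.02)
    call = call_gene_cnv("G", cn, np.zeros(10), 2.02, CFG)
    assert call.call == "neutral"


def test_strict_majority_required_for_amplification():
    cn = np.full(10, 2.0)
    cn[:5] = 3.0    # exactly half: NOT a candidate
    call = call_gene_cnv("G", cn, np.zeros(10), 2.5, CFG)
    assert call.call == "neutral"
    cn[5] = 3.0     # 6 of 10: candidate
    call = call_gene_cnv("G", cn, np.zeros(10), 2.5, CFG)
    assert call.call == "amplification"


def test_single_low_region_calls_deletion():
    cn = np.full(8, 2.0)
    cn[3] = 1.0
    call = call_gene_cnv("G", cn, np.zeros(8), 1.9, CFG)
    assert call.call == "deletion"
    assert call.n_regions_supporting == 1
    assert call.confidence == "candidate"   # weighted CN not below threshold


def test_end_to_end_scale_invariance(panel_manifest):
    """Multiplying raw counts and total by a constant changes no gene call."""
    from panelcall.simulate import simulate_cnv_counts, simulate_normal_cohort
    from panelcall.cnv import corrected_coverage
    normals = simulate_normal_cohort(panel_manifest, 8, seed=3)
    mat = np.vstack([corrected_coverage(v, panel_manifest, CFG) for v in normals])
    prof = build_normal_profile(mat, [r.region_id for r in panel_manifest], CFG)
    tumor = simulate_cnv_counts(panel_manifest, {"ERBB2": 8.0}, purity=0.6, seed=4)
    calls1 = call_sample_cnvs(tumor, panel_manifest, prof, CFG)
    scaled = RegionCountVector("s", tumor.counts * 5, tumor.total_on_target_reads * 5)
    calls2 = call_sample_cnvs(scaled, panel_manifest, prof, CFG)
    assert [(c.gene, c.call) for c in calls1] == [(c.gene, c.call) for c in calls2]
    for a, b in zip(calls1, calls2):
        assert a.weighted_cn == pytest.approx(b.weighted_cn)
    assert {c.gene: c.call for c in calls1}["ERBB2"] == "amplification"
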