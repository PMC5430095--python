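import numpy as np
import pytest

from panelcall.manifest import Manifest, PanelRegion
from panelcall.pileup import write_pileup_tsv
from panelcall.qc import ct_conversion_fraction
from panelcall.simulate import (FusionTruth, SimulationConfig, TruthVariant,
                                inject_ffpe_deamination, simulate_cnv_counts,
                                simulate_pileup, simulate_split_reads)
from panelcall.snv import call_pileup


def test_zero_error_config_gives_clean_reference_columns():
    cfg = SimulationConfig(seed=0, n_positions=50, depth_mean=200,
                           sequencing_error=False)
    cols, ref, _ = simulate_pileup(cfg)
    for col in cols:
        assert set(col.allele_counts()) == {col.ref_base}


def test_truth_exact_composition():
    cfg = SimulationConfig(seed=1, n_positions=20, depth_mean=400,
                           depth_dispersion=0.0, sequencing_error=False,
                           truth_variants=(TruthVariant("chr1", 5, "T", 0.10),),
                           composition="exact")
    cols, _, _ = simulate_pileup(cfg)
    col = cols[5]
    assert col.allele_counts()["T"] == int(np.floor(0.10 * col.depth + 0.5))


def test_truth_sampling_mode_within_3_sigma():
    counts = []
    for seed in range(30):
        cfg = SimulationConfig(seed=seed, n_positions=6, depth_mean=1000,
                               depth_dispersion=0.0, sequencing_error=False,
                               truth_variants=(TruthVariant("chr1", 2, "T", 0.5),),
                               composition="sampling")
        cols, _, _ = simulate_pileup(cfg)
        counts.append(cols[2].allele_counts()["T"] / cols[2].depth)
    # binomial moments: mean 0.5, per-draw sd ~ sqrt(.25/1000) = 0.016
    assert abs(np.mean(counts) - 0.5) < 3 * 0.016 / np.sqrt(30)


def test_same_seed_byte_identical_pileup(tmp_path):
    cfg = SimulationConfig(seed=42, n_positions=40, depth_mean=300,
                           truth_variants=(TruthVariant("chr1", 7, "+AG", 0.2),))
    for name in ("a.tsv", "b.tsv"):
        cols, _, _ = simulate_pileup(cfg)
        write_pileup_tsv(cols, tmp_path / name)
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_substitution_truth_never_matches_reference():
    cfg = SimulationConfig(seed=3, n_positions=100, depth_mean=200,
                           truth_variants=tuple(TruthVariant("chr1", p, "T", 0.3)
                                                for p in range(0, 100, 10)))
    _, ref, _ = simulate_pileup(cfg)
    for p in range(0, 100, 10):
        assert ref["chr1"][p] != "T"


# ---------------------------------------------------------------------------
# FFPE deamination
# ---------------------------------------------------------------------------

def test_deamination_rate_zero_is_identity():
    cfg = SimulationConfig(seed=4, n_positions=30, depth_mean=200)
    cols, _, _ = simulate_pileup(cfg)
    assert inject_ffpe_deamination(cols, rate=0.0, seed=1) == cols


def test_deamination_adds_only_transition_alleles():
    cfg = SimulationConfig(seed=5, n_positions=200, depth_mean=300,
                           sequencing_error=False)
    cols, _, _ = simulate_pileup(cfg)
    noisy = inject_ffpe_deamination(cols, rate=1.0, seed=2)
    changed = 0
    for before, after in zip(cols, noisy):
        added = set(after.allele_counts()) - set(before.allele_counts())
        if added:
            changed += 1
            assert (before.ref_base, tuple(added)) in {("C", ("T",)), ("G", ("A",))}
    assert changed > 50


def test_deamination_drives_ct_fraction_monotonically():
    """More deamination -> larger C>T share among the resulting calls,
    eventually past the 0.45 QC gate."""
    truth = tuple(TruthVariant("chr1", p, "G", 0.4) for p in range(10, 400, 40))
    cfg = SimulationConfig(seed=6, n_positions=400, depth_mean=500,
                           truth_variants=truth)
    cols, ref, _ = simulate_pileup(cfg)
    fractions = []
    for rate in (0.0, 0.10, 0.60):
        noisy = inject_ffpe_deamination(cols, rate=rate, seed=3)
        calls, _ = call_pileup(noisy, reference=ref)
        _, frac = ct_conversion_fraction(calls)
        fractions.append(frac)
    assert fractions == sorted(fractions)
    assert fractions[-1] > 0.45


# ---------------------------------------------------------------------------
# CNV counts
# ---------------------------------------------------------------------------

def test_cnv_counts_diploid_baseline(panel_manifest):
    v = simulate_cnv_counts(panel_manifest, {}, purity=0.7, dispersion=0.0,
                            capture_cv=0.0, seed=7)
    sizes = np.array([r.size for r in panel_manifest])
    rate = v.counts / sizes
    # all genes diploid: per-base rate varies only with the mild GC curve
    assert rate.max() / rate.min() < 1.35


def test_cnv_counts_purity_mixture(panel_manifest):
    """Gene at CN 6 with purity 0.5 doubles expected coverage:
    (2*0.5 + 0.5*6)/2 = 2.0x the diploid baseline."""
    ratios = []
    for seed in range(10):
        v = simulate_cnv_counts(panel_manifest, {"MYC": 6.0}, purity=0.5,
                                dispersion=0.01, capture_cv=0.0, seed=seed)
        genes = np.array([r.gene for r in panel_manifest])
        sizes = np.array([r.size for r in panel_manifest])
        rate = v.counts / sizes
        gc = np.array([r.gc_fraction for r in panel_manifest])
        from panelcall.simulate import default_gc_bias
        rate = rate / np.vectorize(default_gc_bias)(gc)
        ratios.append(rate[genes == "MYC"].mean() / rate[genes != "MYC"].mean())
    assert np.mean(ratios) == pytest.approx(2.0, abs=0.05)


def test_cnv_counts_seed_deterministic(panel_manifest):
    a = simulate_cnv_counts(panel_manifest, {"RET": 4.0}, purity=0.4, seed=11)
    b = simulate_cnv_counts(panel_manifest, {"RET": 4.0}, purity=0.4, seed=11)
    np.testing.assert_array_equal(a.counts, b.counts)


# ---------------------------------------------------------------------------
# split reads
# ---------------------------------------------------------------------------

FUSION = FusionTruth("chr10", 43_610_000, "chr10", 61_550_000, tumor_fraction=1.0)


def test_split_reads_binomial_mean():
    counts = [len(simulate_split_reads(FUSION, spanning_reads=40,
                                       capture_probability=0.5, seed=s))
              for s in range(40)]
    # Binomial(40, 0.5): mean 20, sd ~3.2
    assert abs(np.mean(counts) - 20) < 3 * 3.2 / np.sqrt(40)


def test_split_reads_zero_fraction_empty():
    none = FusionTruth("chr10", 1, "chr10", 2_000_000, tumor_fraction=0.0)
    assert simulate_split_reads(none, seed=0) == []


def test_split_read_support_falls_with_dilution():
    means = []
    for frac in (1.0, 0.7, 0.5, 0.3):
        f = FusionTruth("chr10", 43_610_000, "chr10", 61_550_000, frac)
        means.append(np.mean([len(simulate_split_reads(f, seed=s)) for s in range(25)]))
    assert means == sorted(means, reverse=True)


def test_split_read_jitter_within_tolerance():
    evs = simulate_split_reads(FUSION, spanning_reads=200, jitter_rate=0.5, seed=9)
    for e in evs:
        assert abs(e.segment_a.breakpoint - FUSION.breakpoint_a) <= 2
        assert abs(e.segment_b.breakpoint - FUSION.breakpoint_b) <= 2
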