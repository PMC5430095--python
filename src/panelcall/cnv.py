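"""Depth-of-coverage somatic CNV calling against an iteratively built profile
of normal samples.

Per-region read counts are normalized for region size and library size,
GC-corrected (additive, mean-based), and compared to the per-region mean/SD
of a panel of normals.  The normal profile is built by iterative outlier
elimination: at each round a sample whose corrected coverage deviates beyond
a Z cut-off in more than a set fraction of regions is dropped, until no
sample is dropped.  Copy number is anchored at diploid = 2 (profile mean ==
2 copies); gene-level CN is the region-size-weighted mean over the gene's
regions.  A gene is an amplification candidate when a strict majority of its
regions exceed CN 2.7 and a deletion candidate when any region falls below
CN 1.2, with a high-confidence tier requiring the weighted CN past the
threshold and |Z| > 3 in at least half the supporting regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CNVConfig
from .manifest import Manifest


class CNVError(ValueError):
    pass


@dataclass
class RegionCountVector:
    """Raw per-region read counts for one sample, aligned to a manifest."""

    sample_id: str
    counts: np.ndarray          # int counts, len == len(manifest)
    total_on_target_reads: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise CNVError("negative region count")


@dataclass
class NormalProfile:
    """Per-region mean/SD of corrected normalized coverage over normals."""

    region_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray              # after sd_floor
    n_samples_final: int
    iterations: int
    z_cutoff: float
    deviant_region_limit: float
    sd_floor_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_ids, "mean": self.mean,
                             "sd": self.sd, "n": self.n_samples_final})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CNVCall:
    gene: str
    weighted_cn: float
    n_regions: int
    n_regions_supporting: int
    call: str                    # amplification | deletion | neutral
    confidence: str              # high | candidate | (empty for neutral)
    region_cn: np.ndarray = field(repr=False, default=None)
    region_z: np.ndarray = field(repr=False, default=None)


def normalize_counts(v: RegionCountVector, manifest: Manifest) -> np.ndarray:
    """Reads per base per million on-target reads.

    normalized_r = (count_r / size_r) / (total / 1e6).  The 1e6 scale is an
    arbitrary fixed constant — all downstream quantities are ratios — chosen
    so values are comparable across samples and pleasant to read.
    """
    if v.total_on_target_reads <= 0:
        raise CNVError(f"sample {v.sample_id}: total_on_target_reads must be > 0")
    if len(v.counts) != len(manifest):
        raise CNVError(f"sample {v.sample_id}: count vector length {len(v.counts)} "
                       f"!= manifest length {len(manifest)}")
    sizes = np.array([r.size for r in manifest], dtype=float)
    return (v.counts / sizes) / (v.total_on_target_reads / 1e6)


def gc_correct(normalized: np.ndarray, gc_fractions, bin_width: float = 0.02) -> np.ndarray:
    """Mean-based additive GC correction.

    Regions are binned by GC fraction; each region is shifted by
    -(bin mean - global mean).  Bins with fewer than 3 regions are merged
    with the nearest populated bin so correction terms are never estimated
    from one or two regions.
    """
    normalized = np.asarray(normalized, dtype=float)
    gc = np.asarray(gc_fractions, dtype=float)
    if np.isnan(gc).any():
        raise CNVError("gc_fraction unset for one or more regions")
    bins = np.floor(gc / bin_width).astype(int)
    # merge sparse bins into nearest populated neighbor
    uniq, counts = np.unique(bins, return_counts=True)
    big = uniq[counts >= 3]
    if len(big) == 0:
        return normalized.copy()  # single effective bin: correction is zero
    merged = bins.copy()
    for b, c in zip(uniq, counts):
        if c < 3:
            nearest = big[np.argmin(np.abs(big - b))]
            merged[bins == b] = nearest
    global_mean = normalized.mean()
    corrected = normalized.copy()
    for b in np.unique(merged):
        mask = merged == b
        corrected[mask] -= normalized[mask].mean() - global_mean
    return corrected


def corrected_coverage(v: RegionCountVector, manifest: Manifest,
                       config: CNVConfig | None = None) -> np.ndarray:
    """normalize_counts then gc_correct, using manifest GC fractions."""
    cfg = config or CNVConfig()
    gc = [r.gc_fraction if r.gc_fraction is not None else np.nan for r in manifest]
    return gc_correct(normalize_counts(v, manifest), gc, cfg.gc_bin_width)


def build_normal_profile(corrected_matrix, region_ids,
                         config: CNVConfig | None = None) -> NormalProfile:
    """Iterative outlier-eliminating profile over normal samples.

    ``corrected_matrix`` is (n_samples, n_regions) of corrected normalized
    coverage.  Each iteration scores every surviving sample per region with a
    leave-one-out Z — against the mean/SD of the *other* surviving samples,
    so a gross outlier cannot mask itself by inflating the pooled SD — counts
    regions with |Z| beyond the cut-off, and drops samples whose deviant
    count exceeds the configured fraction of regions; stops when nothing is
    dropped or only 2 samples remain.  The reported profile mean/SD are
    pooled over the survivors.
    """
    cfg = config or CNVConfig()
    mat = np.asarray(corrected_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 3:
        raise CNVError("need a (n_samples >= 3, n_regions) matrix")
    n_regions = mat.shape[1]
    if len(region_ids) != n_regions:
        raise CNVError("region_ids length mismatch")
    limit = cfg.deviant_region_fraction * n_regions

    alive = np.ones(mat.shape[0], dtype=bool)
    iterations = 0
    while alive.sum() >= 3:
        iterations += 1
        sub = mat[alive]
        m = sub.shape[0]
        s1 = sub.sum(axis=0)
        s2 = (sub ** 2).sum(axis=0)
        # leave-one-out mean/sd per sample (ddof=1 over the m-1 others)
        loo_mean = (s1 - sub) / (m - 1)
        loo_ss = s2 - sub ** 2 - (m - 1) * loo_mean ** 2
        loo_sd = np.sqrt(np.maximum(loo_ss, 0.0) / max(m - 2, 1))
        sd_eff = np.maximum(loo_sd, cfg.sd_floor_fraction * np.abs(loo_mean))
        sd_eff = np.where(sd_eff > 0, sd_eff, 1.0)  # all-zero region: inert
        z = np.abs((sub - loo_mean) / sd_eff)
        deviant = (z > cfg.z_cutoff).sum(axis=1)
        drop_local = deviant > limit
        if not drop_local.any() or alive.sum() - drop_local.sum() < 2:
            break
        idx = np.flatnonzero(alive)
        alive[idx[drop_local]] = False

    if alive.sum() < 2:
        raise CNVError("profile degenerate: fewer than 2 surviving samples")
    sub = mat[alive]
    mean = sub.mean(axis=0)
    sd = np.maximum(sub.std(axis=0, ddof=1), cfg.sd_floor_fraction * np.abs(mean))
    return NormalProfile(
        region_ids=list(region_ids), mean=mean, sd=sd,
        n_samples_final=int(alive.sum()), iterations=iterations,
        z_cutoff=cfg.z_cutoff, deviant_region_limit=cfg.deviant_region_fraction,
        sd_floor_fraction=cfg.sd_floor_fraction,
    )


def region_cn_and_z(corrected: np.ndarray, profile: NormalProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-region copy number (diploid = 2) and Z score against the profile.

    Regions with zero profile mean are masked (NaN) and excluded from gene
    aggregation.
    """
    corrected = np.asarray(corrected, dtype=float)
    if len(corrected) != len(profile.mean):
        raise CNVError("sample vector not aligned to profile")
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = 2.0 * corrected / profile.mean
        z = (corrected - profile.mean) / profile.sd
    masked = profile.mean == 0
    cn[masked] = np.nan
    z[masked] = np.nan
    return cn, z


def gene_weighted_cn(region_cn: np.ndarray, region_sizes, gene_mask) -> float:
    """Region-size-weighted mean CN over one gene's unmasked regions."""
    cn = np.asarray(region_cn, dtype=float)[gene_mask]
    sizes = np.asarray(region_sizes, dtype=float)[gene_mask]
    ok = ~np.isnan(cn)
    if not ok.any():
        raise CNVError("all regions masked for gene")
    return float((cn[ok] * sizes[ok]).sum() / sizes[ok].sum())


def call_gene_cnv(gene: str, region_cn, region_z, weighted_cn: float,
                  config: CNVConfig | None = None) -> CNVCall:
    """Gene-level amplification/deletion decision.

    Amplification candidate iff a strict majority of regions have CN above
    the amplification threshold; deletion candidate iff any region is below
    the deletion threshold.  High confidence additionally requires the
    weighted CN past the threshold and |Z| > 3 in at least half the
    supporting regions.
    """
    cfg = config or CNVConfig()
    cn = np.asarray(region_cn, dtype=float)
    z = np.asarray(region_z, dtype=float)
    ok = ~np.isnan(cn)
    cn, z = cn[ok], z[ok]
    n = len(cn)
    if n == 0:
        raise CNVError(f"gene {gene}: all regions masked")

    amp_support = cn > cfg.amp_threshold
    del_support = cn < cfg.del_threshold

    def confidence(support_mask, threshold_ok) -> str:
        n_sup = int(support_mask.sum())
        strong = int((np.abs(z[support_mask]) > 3.0).sum())
        if threshold_ok and n_sup > 0 and strong >= 0.5 * n_sup:
            return "high"
        return "candidate"

    if amp_support.sum() > cfg.amp_region_fraction * n:
        return CNVCall(gene, weighted_cn, n, int(amp_support.sum()), "amplification",
                       confidence(amp_support, weighted_cn > cfg.amp_threshold),
                       region_cn=cn, region_z=z)
    if del_support.any():
        return CNVCall(gene, weighted_cn, n, int(del_support.sum()), "deletion",
                       confidence(del_support, weighted_cn < cfg.del_threshold),
                       region_cn=cn, region_z=z)
    return CNVCall(gene, weighted_cn, n, 0, "neutral", "", region_cn=cn, region_z=z)


def call_sample_cnvs(v: RegionCountVector, manifest: Manifest, profile: NormalProfile,
                     config: CNVConfig | None = None) -> list[CNVCall]:
    """End-to-end per-sample CNV path: normalize, correct, compare to the
    profile, aggregate per gene, call."""
    cfg = config or CNVConfig()
    corrected = corrected_coverage(v, manifest, cfg)
    cn, z = region_cn_and_z(corrected, profile)
    sizes = np.array([r.size for r in manifest], dtype=float)
    genes = np.array([r.gene for r in manifest], dtype=object)
    calls = []
    for gene in manifest.genes():
        mask = genes == gene
        if np.isnan(cn[mask]).all():
            continue  # no usable region: no call for this gene
        wcn = gene_weighted_cn(cn, sizes, mask)
        calls.append(call_gene_cnv(gene, cn[mask], z[mask], wcn, cfg))
    return calls


def read_counts_tsv(path, manifest: Manifest, sample_id: str,
                    total_on_target_reads: int | None = None) -> RegionCountVector:
    """Region counts as TSV (region_id, count), validated against the manifest
    order.  Total defaults to the column sum."""
    df = pd.read_csv(path, sep="\t")
    if list(df["region_id"]) != [r.region_id for r in manifest]:
        raise CNVError(f"{path}: region_ids do not match manifest order")
    counts = df["count"].to_numpy()
    total = int(total_on_target_reads if total_on_target_reads is not None else counts.sum())
    return RegionCountVector(sample_id, counts, total)


def write_cnv_calls_tsv(calls: list[CNVCall], path) -> None:
    rows = [{"gene": c.gene, "weighted_cn": round(c.weighted_cn, 3), "call": c.call,
             "confidence": c.confidence,
             "n_supporting": c.n_regions_supporting, "n_regions": c.n_regions}
            for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
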