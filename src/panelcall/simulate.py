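"""Synthetic data for every pipeline input: pileups with Phred-dependent
sequencing error, FFPE deamination noise, hybrid-capture CNV count matrices
under tumor-purity dilution, and chimeric split reads for fusions.

The generators state a world rather than tune one: depth is negative
binomial (capture coverage is super-Poisson), base qualities default to a
Q30 point mass (panel data are Q30-dominated), reads are 150 bp so tail
distances are uniform over read offsets, and truth variants are planted
either at exact count round(vaf * depth) or by binomial draw.  Every
generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import floor
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .cnv import RegionCountVector
from .manifest import Manifest
from .pileup import PileupColumn, ReadObservation, is_indel_allele
from .sv import Segment, SplitReadEvidence

_BASES = np.array(list("ACGT"))


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


@dataclass(frozen=True, slots=True)
class TruthVariant:
    chrom: str
    pos: int          # 0-based
    allele: str       # base, +SEQ or -N
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"vaf must be in (0, 1], got {self.vaf}")


@dataclass
class SimulationConfig:
    """Knobs for pileup simulation.

    ``quality_weights`` is a sequence of (Phred, weight) pairs; ``composition``
    is "exact" (round(vaf*depth) variant reads — the downsampling convention)
    or "sampling" (binomial draw — a sequencing replicate).
    """

    seed: int = 0
    chrom: str = "chr1"
    n_positions: int = 100
    depth_mean: float = 800.0
    depth_dispersion: float = 0.05     # var = m + disp * m^2; 0 -> Poisson
    depth_range: tuple[int, int] | None = None   # discrete-uniform override
    quality_weights: Sequence[tuple[int, float]] = ((30, 1.0),)
    read_length: int = 150
    truth_variants: Sequence[TruthVariant] = ()
    composition: str = "exact"
    sequencing_error: bool = True      # flip non-truth bases at rate 10^(-q/10)
    reference: str | None = None       # generated if None

    def validate(self) -> None:
        if self.composition not in ("exact", "sampling"):
            raise ValueError(f"unknown composition mode {self.composition!r}")
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ValueError("bad depth distribution")
        for t in self.truth_variants:
            if not 0 <= t.pos < self.n_positions:
                raise ValueError(f"truth variant at {t.pos} outside [0, {self.n_positions})")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _draw_qualities(rng: np.random.Generator, weights, n: int) -> np.ndarray:
    qs = np.array([q for q, _ in weights], dtype=np.int64)
    ws = np.array([w for _, w in weights], dtype=float)
    ws = ws / ws.sum()
    return qs[rng.choice(len(qs), size=n, p=ws)]


def simulate_reference(rng: np.random.Generator, length: int,
                       truth_variants: Sequence[TruthVariant] = ()) -> str:
    """Uniform-random reference; at substitution truth loci the reference
    base is redrawn to differ from the planted allele."""
    seq = rng.choice(_BASES, size=length)
    for t in truth_variants:
        if not is_indel_allele(t.allele) and seq[t.pos] == t.allele:
            others = [b for b in "ACGT" if b != t.allele]
            seq[t.pos] = others[rng.integers(len(others))]
    return "".join(seq)


def iter_simulated_columns(config: SimulationConfig) -> Iterator[tuple[PileupColumn, TruthVariant | None]]:
    """Yield (column, truth-or-None) per position; streaming, so panel-scale
    simulations never hold every observation in memory at once."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    reference = config.reference or simulate_reference(
        rng, config.n_positions, config.truth_variants)
    truth_at = {t.pos: t for t in config.truth_variants}

    for pos in range(config.n_positions):
        if config.depth_range is not None:
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        else:
            depth = int(_nb_draw(rng, config.depth_mean, config.depth_dispersion))
        truth = truth_at.get(pos)
        yield _simulate_column(rng, config, reference, pos, depth, truth), truth


def _simulate_column(rng, config, reference, pos, depth, truth) -> PileupColumn:
    ref_base = reference[pos]
    if depth == 0:
        return PileupColumn(config.chrom, pos, ref_base, [])
    quals = _draw_qualities(rng, config.quality_weights, depth)
    alleles = np.full(depth, ref_base, dtype=object)

    n_var = 0
    if truth is not None:
        if config.composition == "exact":
            n_var = min(depth, _round_half_up(truth.vaf * depth))
        else:
            n_var = int(rng.binomial(depth, truth.vaf))
    if n_var:
        idx = rng.choice(depth, size=n_var, replace=False)
        alleles[idx] = truth.allele

    if config.sequencing_error:
        err_p = 10.0 ** (-quals / 10.0)
        flip = (rng.random(depth) < err_p) & (alleles == ref_base)
        for i in np.flatnonzero(flip):
            others = [b for b in "ACGT" if b != ref_base]
            alleles[i] = others[rng.integers(3)]

    offsets = rng.integers(0, config.read_length, size=depth)
    tails = np.minimum(offsets, config.read_length - 1 - offsets)
    obs = [ReadObservation(alleles[i], int(quals[i]), "+" if i % 2 == 0 else "-",
                           int(tails[i]))
           for i in range(depth)]
    return PileupColumn(config.chrom, pos, ref_base, obs)


def simulate_pileup(config: SimulationConfig):
    """Materialized pileup: (columns, reference mapping, truth list)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    reference = config.reference or simulate_reference(
        rng, config.n_positions, config.truth_variants)
    cfg = replace(config, reference=reference)
    columns = [col for col, _ in iter_simulated_columns(cfg)]
    return columns, {config.chrom: reference}, list(config.truth_variants)


def inject_ffpe_deamination(columns: Iterable[PileupColumn], rate: float,
                            vaf_sampler: Callable[[np.random.Generator], float] | None = None,
                            seed: int = 0, complementary: bool = True) -> list[PileupColumn]:
    """Plant C>T (and, in complementary mode, G>A) artifact alleles.

    At each C (or G) reference column, with probability ``rate`` a low-VAF
    deamination allele is added by converting round(vaf * depth) reference
    observations; the VAF comes from ``vaf_sampler`` (default Uniform(0.05,
    0.15), the low-frequency band fixation artifacts occupy).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    sample_vaf = vaf_sampler or (lambda r: float(r.uniform(0.05, 0.15)))
    targets = {"C": "T", "G": "A"} if complementary else {"C": "T"}
    out = []
    for col in columns:
        alt = targets.get(col.ref_base)
        if alt is None or rate == 0 or rng.random() >= rate or col.depth == 0:
            out.append(col)
            continue
        vaf = sample_vaf(rng)
        ref_idx = [i for i, o in enumerate(col.observations) if o.allele == col.ref_base]
        k = min(len(ref_idx), _round_half_up(vaf * col.depth))
        convert = set(rng.choice(len(ref_idx), size=k, replace=False).tolist()) if k else set()
        obs = list(col.observations)
        for j, i in enumerate(ref_idx):
            if j in convert:
                o = obs[i]
                obs[i] = ReadObservation(alt, o.base_quality, o.strand, o.tail_distance)
        out.append(PileupColumn(col.chrom, col.pos, col.ref_base, obs))
    return out


# ---------------------------------------------------------------------------
# CNV counts
# ---------------------------------------------------------------------------

def default_gc_bias(gc: float) -> float:
    """Mild capture-efficiency curve: peak near 45% GC, ±10% at the extremes."""
    return 1.0 - 0.4 * (gc - 0.45) ** 2 / 0.25


from functools import lru_cache


@lru_cache(maxsize=None)
def _capture_efficiency(region_id: str, cv: float) -> float:
    """Reproducible per-region capture efficiency: hybrid-capture probes pull
    down different regions with very different but *stable* efficiency, which
    is exactly what a profile of normals absorbs.  Lognormal with the given
    CV, keyed on the region_id so every simulated sample shares it."""
    import zlib
    rng = np.random.default_rng(zlib.crc32(region_id.encode()))
    sigma = np.sqrt(np.log1p(cv ** 2))
    return float(rng.lognormal(-sigma ** 2 / 2, sigma))


def simulate_cnv_counts(manifest: Manifest, gene_cn: dict[str, float],
                        purity: float = 1.0, reads_per_base: float = 5.0,
                        dispersion: float = 0.005, capture_cv: float = 0.2,
                        gc_bias: Callable[[float], float] | None = None,
                        seed: int = 0, sample_id: str = "sim") -> RegionCountVector:
    """Per-region capture counts for a tumor of the given purity.

    Expected count is proportional to region size, a GC-efficiency curve, a
    sample-independent per-region capture efficiency (lognormal, CV
    ``capture_cv`` — the dominant, reproducible component of the wide
    regional coverage spread of capture panels) and the purity mixture
    (2(1-f) + f*CN)/2; genes absent from ``gene_cn`` are diploid.  The
    per-sample residual is negative binomial with the (small) ``dispersion``.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    curve = gc_bias or default_gc_bias
    counts = np.empty(len(manifest), dtype=np.int64)
    for i, region in enumerate(manifest):
        gc = region.gc_fraction if region.gc_fraction is not None else 0.5
        cn = gene_cn.get(region.gene, 2.0)
        mixture = (2.0 * (1.0 - purity) + purity * cn) / 2.0
        eff = _capture_efficiency(region.region_id, capture_cv) if capture_cv > 0 else 1.0
        mean = reads_per_base * region.size * curve(gc) * eff * mixture
        counts[i] = _nb_draw(rng, mean, dispersion)
    return RegionCountVector(sample_id, counts, int(counts.sum()))


def simulate_normal_cohort(manifest: Manifest, n_samples: int,
                           reads_per_base: float = 5.0, dispersion: float = 0.005,
                           capture_cv: float = 0.2,
                           seed: int = 0) -> list[RegionCountVector]:
    """Diploid samples for profile building (one derived seed per sample)."""
    return [simulate_cnv_counts(manifest, {}, purity=0.0,
                                reads_per_base=reads_per_base,
                                dispersion=dispersion, capture_cv=capture_cv,
                                seed=seed * 1000 + i,
                                sample_id=f"normal{i}")
            for i in range(n_samples)]


# ---------------------------------------------------------------------------
# Split reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class FusionTruth:
    chrom_a: str
    breakpoint_a: int
    chrom_b: str
    breakpoint_b: int
    tumor_fraction: float


def simulate_split_reads(fusion: FusionTruth, spanning_reads: int = 100,
                         capture_probability: float = 0.4,
                         jitter_rate: float = 0.1, seed: int = 0,
                         read_length: int = 150) -> list[SplitReadEvidence]:
    """Chimeric reads over a fusion junction.

    The chimeric read count is Binomial(spanning_reads, capture_probability *
    tumor_fraction), so expected support falls in proportion to dilution.  A
    minor fraction of reads carry breakpoints jittered within ±2 bp to
    exercise the clustering consistency rule.
    """
    if not 0.0 <= fusion.tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(rng.binomial(spanning_reads, capture_probability * fusion.tumor_fraction))
    out = []
    for i in range(n):
        da = db = 0
        if jitter_rate and rng.random() < jitter_rate:
            da = int(rng.integers(-2, 3))
            db = int(rng.integers(-2, 3))
        split_at = int(rng.integers(40, read_length - 40))  # both spans >= 40
        out.append(SplitReadEvidence(
            read_id=f"chimera{i}",
            segment_a=Segment(fusion.chrom_a, fusion.breakpoint_a + da, "+", split_at),
            segment_b=Segment(fusion.chrom_b, fusion.breakpoint_b + db, "+",
                              read_length - split_at),
        ))
    return out
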