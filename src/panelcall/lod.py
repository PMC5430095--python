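"""Limit-of-detection engine: in-silico downsampling of read evidence to a
target coverage and variant allele fraction, detection-probability grids, and
the validation metrics (sensitivity, specificity, %SR concordance).

Downsampling composes each derivative column exactly: k = round(vaf * depth)
variant observations (round half up, so 7% of 150 -> 11) and depth - k
reference observations, drawn without replacement from the source pools.
This mirrors choosing independent read subsets for the variant- and
reference-carrying reads, and makes "detected with 100% probability"
statements well-posed at fixed composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd

from .config import SNVConfig
from .pileup import PileupColumn
from .snv import NoCall, apply_post_filters, call_variant_at_column
from .stats import pearson_r2

__all__ = [
    "DetectionGrid", "downsample_column", "detection_grid",
    "sensitivity", "specificity", "concordance_r2",
]


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def downsample_column(source: PileupColumn, variant_allele: str,
                      target_depth: int, target_vaf: float,
                      seed: int | np.random.Generator) -> PileupColumn:
    """Seeded without-replacement downsampling to an exact composition.

    Picks k = round(target_depth * target_vaf) variant observations and
    target_depth - k non-variant observations from the source column.
    Raises when the source lacks enough reads of either kind, naming the
    deficit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = _round_half_up(target_depth * target_vaf)
    variant_obs = [o for o in source.observations if o.allele == variant_allele]
    other_obs = [o for o in source.observations if o.allele != variant_allele]
    if len(variant_obs) < k:
        raise ValueError(f"source has {len(variant_obs)} variant observations, "
                         f"need {k} (deficit {k - len(variant_obs)})")
    n_ref = target_depth - k
    if len(other_obs) < n_ref:
        raise ValueError(f"source has {len(other_obs)} reference observations, "
                         f"need {n_ref} (deficit {n_ref - len(other_obs)})")
    pick_v = rng.choice(len(variant_obs), size=k, replace=False)
    pick_r = rng.choice(len(other_obs), size=n_ref, replace=False)
    obs = [variant_obs[i] for i in sorted(pick_v)] + [other_obs[i] for i in sorted(pick_r)]
    return PileupColumn(source.chrom, source.pos, source.ref_base, obs)


@dataclass
class DetectionGrid:
    """Detection probability as a function of coverage x VAF."""

    coverages: list[int]
    vafs: list[float]
    replicates: int
    seed: int
    probability: np.ndarray = field(repr=False)   # shape (|coverages|, |vafs|)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"coverage": c, "vaf": v, "probability": self.probability[i, j]}
                for i, c in enumerate(self.coverages)
                for j, v in enumerate(self.vafs)]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def write_json(self, path) -> None:
        payload = {"coverages": self.coverages, "vafs": self.vafs,
                   "replicates": self.replicates, "seed": self.seed,
                   "probability": self.probability.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def detection_grid(source_factory, coverages, vafs, replicates: int,
                   config: SNVConfig | None = None, seed: int = 0,
                   reference=None) -> DetectionGrid:
    """Detection probability per (coverage, VAF) cell over seeded replicates.

    ``source_factory(rng)`` must return a (source column, variant allele)
    pair with enough observations for the largest requested composition;
    each replicate redraws the downsampled subset (and, through the factory,
    the source observations).  A cell's value is the fraction of replicates
    in which the truth allele comes out as a PASS call under ``config``.
    """
    cfg = config or SNVConfig()
    coverages = list(coverages)
    vafs = list(vafs)
    prob = np.zeros((len(coverages), len(vafs)))
    rng = np.random.default_rng(seed)
    for i, cov in enumerate(coverages):
        for j, vaf in enumerate(vafs):
            hits = 0
            for _ in range(replicates):
                source, allele = source_factory(rng)
                col = downsample_column(source, allele, cov, vaf, rng)
                res = call_variant_at_column(col, cfg)
                if isinstance(res, NoCall) or res.alt != allele:
                    continue
                apply_post_filters([res], reference=reference, config=cfg)
                if res.is_pass:
                    hits += 1
            prob[i, j] = hits / replicates
    return DetectionGrid(coverages, vafs, replicates,
                         seed if isinstance(seed, int) else -1, prob)


def _normalize_key(locus_allele) -> tuple:
    chrom, pos, allele = locus_allele
    return (chrom, int(pos), str(allele))


def sensitivity(truth, called) -> float:
    """|truth ∩ called| / |truth| over (chrom, pos, allele) keys.

    Callers should left-normalize InDel representations before matching
    (the pileup layer anchors InDels at their leftmost equivalent position).
    """
    truth_set = {_normalize_key(t) for t in truth}
    if not truth_set:
        raise ValueError("empty truth set")
    called_set = {_normalize_key(c) for c in called}
    return len(truth_set & called_set) / len(truth_set)


def specificity(n_assessed: int, n_false_positive: int) -> float:
    """(assessed - false positives) / assessed."""
    if n_assessed <= 0:
        raise ValueError("assessed positions must be > 0")
    return (n_assessed - n_false_positive) / n_assessed


def concordance_r2(x, y) -> float:
    """Squared Pearson correlation between paired %SR (or frequency)
    vectors, e.g. across replicate runs."""
    return pearson_r2(x, y)
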