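"""Quality-aware binomial SNV/InDel caller.

The caller asks, per pileup column: if this locus were homozygous reference
and every non-reference base a sequencing error, how surprising is the
observed count of the top variant allele?  Concretely, for bases retained at
a quality floor Q_t it computes the binomial upper tail

    P = sum_{j>=k} C(n, j) e^j (1 - e)^(n - j)

with n the retained bases, k the retained count of the most frequent variant
allele and e the error rate of the *lowest* retained quality, then scores it
as -10*log10(P).  Because a single low-quality outlier can inflate e and
mask real variants, the test is swept over quality floors Q_t = 20..30 and a
variant is reported if the score exceeds the threshold (default 50) at any
floor; the lowest such floor is recorded.  If different alleles win at
different floors, only the highest-scoring allele is reported.

Post-call filters (calls are annotated, never dropped):

- ``low_sr``            %SR < 2 against full depth
- ``tail_bias``         alt vs ref tail-distance rank-sum p < 1e-5
- ``homopolymer_indel`` InDel with %SR < 10 inside a homopolymer run >= 6
- ``low_coverage``      column depth below the 150x calling floor
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import SNVConfig
from .pileup import PileupColumn, allele_sort_key, is_indel_allele
from .stats import (binomial_tail_log10, binomial_tail_pvalue,
                    error_rate_from_quality, fisher_exact_2x2, rank_sum_test)


@dataclass
class VariantCall:
    """A called (or filtered) SNV/InDel at one locus."""

    chrom: str
    pos: int                 # 0-based
    ref: str
    alt: str                 # allele token: base, +SEQ or -N
    depth: int
    alt_count: int
    sr_percent: float
    p_value: float           # may underflow to 0; score is authoritative
    score: float
    qt_called: int
    attributes: dict = field(default_factory=dict)
    filter_status: set = field(default_factory=set)  # empty == PASS

    @property
    def is_pass(self) -> bool:
        return not self.filter_status

    @property
    def is_indel(self) -> bool:
        return is_indel_allele(self.alt)


@dataclass
class NoCall:
    chrom: str
    pos: int
    reason: str


def call_variant_at_column(column: PileupColumn, config: SNVConfig | None = None):
    """Run the Q_t-swept binomial test on one column.

    Returns a :class:`VariantCall` (unfiltered; see
    :func:`apply_post_filters`), or :class:`NoCall` with a reason.  Columns
    below ``min_coverage`` are flagged low-coverage and not tested.
    """
    cfg = config or SNVConfig()
    if column.depth == 0:
        return NoCall(column.chrom, column.pos, "no coverage")
    if column.depth < cfg.min_coverage:
        return NoCall(column.chrom, column.pos, "low_coverage")

    arr = column.arrays()
    quals = arr["qual"]
    alleles = arr["allele"]
    ref = column.ref_base

    best = None  # (score, allele, qt, p, n, k_retained)
    any_qualifying = False
    per_allele_qts: dict[str, list[tuple[int, float]]] = {}

    for qt in cfg.qt_range:
        keep = quals >= qt
        n = int(keep.sum())
        if n == 0:
            continue
        any_qualifying = True
        kept_alleles = alleles[keep]
        counts = Counter(a for a in kept_alleles if a != ref)
        if not counts:
            continue
        top_count = max(counts.values())
        winner = min((a for a, c in counts.items() if c == top_count),
                     key=allele_sort_key)
        e = error_rate_from_quality(int(quals[keep].min()))
        log10p = binomial_tail_log10(n, top_count, e)
        score = -10.0 * log10p
        if score > cfg.score_threshold:
            per_allele_qts.setdefault(winner, []).append((qt, score))
            if best is None or score > best[0]:
                best = (score, winner, qt, 10.0 ** log10p, n, top_count)

    if not any_qualifying:
        return NoCall(column.chrom, column.pos, "no qualifying bases")
    if best is None:
        return NoCall(column.chrom, column.pos, "below score threshold")

    score, allele, _, p, n, k = best
    qt_called = min(qt for qt, _ in per_allele_qts[allele])
    alt_count = int((alleles == allele).sum())
    call = VariantCall(
        chrom=column.chrom, pos=column.pos, ref=ref, alt=allele,
        depth=column.depth, alt_count=alt_count,
        sr_percent=100.0 * alt_count / column.depth,
        p_value=p, score=score, qt_called=qt_called,
    )
    call.attributes.update(pv4_attributes(column, allele))
    return call


def tail_distance_bias_test(alt_tail_distances, ref_tail_distances) -> float:
    """Two-sided rank-sum p comparing tail distances of alt- vs
    ref-supporting observations.  Fewer than two observations in total (or
    an empty side) is not testable and returns 1."""
    if len(alt_tail_distances) + len(ref_tail_distances) < 2 \
            or len(alt_tail_distances) == 0 or len(ref_tail_distances) == 0:
        return 1.0
    return rank_sum_test(alt_tail_distances, ref_tail_distances)


def pv4_attributes(column: PileupColumn, alt: str) -> dict:
    """Bias attributes for one alt allele: strand (Fisher exact on the
    ref/alt x strand table), base quality and tail distance (rank-sum).
    All are reported; only tail bias participates in filtering."""
    arr = column.arrays()
    is_alt = arr["allele"] == alt
    is_ref = arr["allele"] == column.ref_base
    plus = arr["strand"] == "+"
    table = [[int((is_ref & plus).sum()), int((is_ref & ~plus).sum())],
             [int((is_alt & plus).sum()), int((is_alt & ~plus).sum())]]
    alt_q, ref_q = arr["qual"][is_alt], arr["qual"][is_ref]
    alt_t, ref_t = arr["tail"][is_alt], arr["tail"][is_ref]
    return {
        "strand_bias_p": fisher_exact_2x2(table),
        "baseq_bias_p": rank_sum_test(alt_q, ref_q) if len(alt_q) and len(ref_q) else 1.0,
        "tail_bias_p": tail_distance_bias_test(alt_t, ref_t),
    }


def is_homopolymer_context(window: str, pos_in_window: int, min_len: int = 6) -> bool:
    """True iff a run of >= ``min_len`` identical bases overlaps the variant
    anchor position or the base immediately after it (InDels sit between the
    anchor and the following base)."""
    if len(window) < min_len:
        raise ValueError(f"window of {len(window)} bases is shorter than min_len={min_len}")
    if not 0 <= pos_in_window < len(window):
        raise ValueError("position outside window")
    window = window.upper()
    run_start = 0
    for i in range(1, len(window) + 1):
        if i == len(window) or window[i] != window[run_start]:
            if i - run_start >= min_len and run_start <= pos_in_window + 1 and i > pos_in_window:
                return True
            run_start = i
    return False


def apply_post_filters(calls, reference=None, config: SNVConfig | None = None,
                       context_window: int = 20):
    """Set filter_status on each call in place and return the list.

    ``reference`` maps chrom -> sequence and is needed for the homopolymer
    InDel filter; without it that filter is skipped (SNV-only filters still
    apply).  Calls are retained whatever their status — the VCF FILTER
    column carries the verdict.
    """
    cfg = config or SNVConfig()
    out = []
    for call in calls:
        if isinstance(call, NoCall):
            out.append(call)
            continue
        status = set()
        if call.sr_percent < cfg.sr_low:
            status.add("low_sr")
        if call.attributes.get("tail_bias_p", 1.0) < cfg.tail_bias_p:
            status.add("tail_bias")
        homopolymer = False
        if call.is_indel and reference is not None:
            seq = str(reference[call.chrom])
            lo = max(0, call.pos - context_window)
            hi = min(len(seq), call.pos + context_window + 1)
            window = seq[lo:hi]
            if len(window) >= cfg.indel_homopolymer_len:
                homopolymer = is_homopolymer_context(
                    window, call.pos - lo, cfg.indel_homopolymer_len)
        call.attributes["homopolymer_context"] = homopolymer
        if call.is_indel and call.sr_percent < cfg.indel_sr_min and homopolymer:
            status.add("homopolymer_indel")
        call.filter_status = status
        out.append(call)
    return out


def call_pileup(columns, reference=None, config: SNVConfig | None = None):
    """Call every column and post-filter: the end-to-end per-sample SNV/InDel
    path.  Returns (variant calls, no-call records)."""
    cfg = config or SNVConfig()
    calls, nocalls = [], []
    for col in columns:
        res = call_variant_at_column(col, cfg)
        if isinstance(res, NoCall):
            nocalls.append(res)
        else:
            calls.append(res)
    apply_post_filters(calls, reference=reference, config=cfg)
    return calls, nocalls
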