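"""Split-read translocation detection.

A read whose two segments align to different genes is evidence for a fusion.
Evidence is grouped by unordered gene pair; within a group the modal
breakpoint pair defines the cluster, and reads whose breakpoints agree with
it within a tolerance (default ±5 bp on both sides) are "consistent".  A
cluster is coherent when consistent reads form a strict majority.  Coherent
clusters with at least 8 consistent reads are reported outright for known
partner pairs and flagged for orthogonal confirmation when the partnership
is novel; weaker clusters are retained with below_threshold status.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .config import SVConfig
from .manifest import Manifest


@dataclass(frozen=True, slots=True)
class Segment:
    chrom: str
    breakpoint: int     # 0-based reference position of the junction
    strand: str
    span: int           # aligned bases in this segment


@dataclass(frozen=True, slots=True)
class SplitReadEvidence:
    read_id: str
    segment_a: Segment
    segment_b: Segment


@dataclass
class SVCall:
    gene_a: str
    gene_b: str
    breakpoint_a: int
    breakpoint_b: int
    n_split_reads: int
    n_consistent: int
    novel_partner: bool
    status: str   # reported | needs_confirmation | below_threshold


def extract_split_evidence(alignments, config: SVConfig | None = None,
                           log_tally: dict | None = None) -> list[SplitReadEvidence]:
    """Collect two-segment split reads from pysam records carrying SA tags.

    Only reads with exactly two mapped segments are used; reads splitting
    into more are tallied and skipped.  Segments must each span at least the
    configured minimum and lie on different chromosomes or further apart
    than the intra-gene distance (default 100 kb) — closer splits are read-
    internal artifacts or small indels, not translocation evidence.
    """
    cfg = config or SVConfig()
    tally = log_tally if log_tally is not None else {}
    tally.setdefault("skipped_multi_segment", 0)
    tally.setdefault("skipped_short_span", 0)
    tally.setdefault("skipped_intragene", 0)

    out = []
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        try:
            sa = rec.get_tag("SA")
        except KeyError:
            continue
        sa_entries = [s for s in sa.split(";") if s]
        if len(sa_entries) != 1:
            tally["skipped_multi_segment"] += 1
            continue
        chrom_b, pos_b, strand_b, cigar_b, _mapq, _nm = sa_entries[0].split(",")[:6]
        span_b = _cigar_ref_span(cigar_b)
        span_a = rec.reference_length or 0
        if span_a < cfg.min_segment_span or span_b < cfg.min_segment_span:
            tally["skipped_short_span"] += 1
            continue
        seg_a = Segment(rec.reference_name, _junction(rec.reference_start, span_a, rec.cigarstring),
                        "-" if rec.is_reverse else "+", span_a)
        seg_b = Segment(chrom_b, int(pos_b) - 1, strand_b, span_b)
        if seg_a.chrom == seg_b.chrom and abs(seg_a.breakpoint - seg_b.breakpoint) <= cfg.min_intergene_distance:
            tally["skipped_intragene"] += 1
            continue
        out.append(SplitReadEvidence(rec.query_name, seg_a, seg_b))
    return out


def _cigar_ref_span(cigar: str) -> int:
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                span += int(num)
            num = ""
    return span


def _junction(ref_start: int, ref_span: int, cigar: str | None) -> int:
    """Breakpoint of the primary segment: the clipped end of its alignment —
    a trailing clip means the read continues elsewhere past the right end."""
    if cigar and cigar[-1] in "SH":
        return ref_start + ref_span - 1
    return ref_start


def read_split_tsv(path) -> list[SplitReadEvidence]:
    """Split segments as TSV: read_id, chromA, posA (1-based), strandA,
    spanA, chromB, posB, strandB, spanB."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(SplitReadEvidence(
            str(row.read_id),
            Segment(str(row.chromA), int(row.posA) - 1, str(row.strandA), int(row.spanA)),
            Segment(str(row.chromB), int(row.posB) - 1, str(row.strandB), int(row.spanB)),
        ))
    return out


def write_split_tsv(evidence, path) -> None:
    rows = [{"read_id": e.read_id,
             "chromA": e.segment_a.chrom, "posA": e.segment_a.breakpoint + 1,
             "strandA": e.segment_a.strand, "spanA": e.segment_a.span,
             "chromB": e.segment_b.chrom, "posB": e.segment_b.breakpoint + 1,
             "strandB": e.segment_b.strand, "spanB": e.segment_b.span}
            for e in evidence]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class BreakpointCluster:
    gene_a: str
    gene_b: str
    breakpoint_a: int          # modal
    breakpoint_b: int
    n_split_reads: int
    n_consistent: int
    coherent: bool
    evidence: list[SplitReadEvidence]


def cluster_breakpoints(evidence, manifest: Manifest,
                        config: SVConfig | None = None,
                        min_span: int | None = None) -> list[BreakpointCluster]:
    """Group evidence by unordered gene pair and find the modal breakpoint
    pair; reads within tolerance on both breakpoints are consistent, and a
    cluster is coherent iff they form a strict majority.

    Evidence whose segments do not both land in (distinct) manifest genes is
    ignored, as is evidence below the minimum segment span.
    """
    cfg = config or SVConfig()
    span_floor = cfg.min_segment_span if min_span is None else min_span
    groups: dict[tuple[str, str], list[tuple[SplitReadEvidence, int, int]]] = {}
    for ev in evidence:
        if ev.segment_a.span < span_floor or ev.segment_b.span < span_floor:
            continue
        gene_a = manifest.gene_for_position(ev.segment_a.chrom, ev.segment_a.breakpoint)
        gene_b = manifest.gene_for_position(ev.segment_b.chrom, ev.segment_b.breakpoint)
        if gene_a is None or gene_b is None or gene_a == gene_b:
            continue
        if gene_a <= gene_b:
            key, bp = (gene_a, gene_b), (ev.segment_a.breakpoint, ev.segment_b.breakpoint)
        else:
            key, bp = (gene_b, gene_a), (ev.segment_b.breakpoint, ev.segment_a.breakpoint)
        groups.setdefault(key, []).append((ev, bp[0], bp[1]))

    clusters = []
    for (ga, gb), items in sorted(groups.items()):
        pairs = Counter((a, b) for _, a, b in items)
        # modal pair; ties broken by genomic order for determinism
        top = max(pairs.values())
        modal_a, modal_b = min(p for p, c in pairs.items() if c == top)
        tol = cfg.breakpoint_tolerance
        consistent = [ev for ev, a, b in items
                      if abs(a - modal_a) <= tol and abs(b - modal_b) <= tol]
        n = len(items)
        clusters.append(BreakpointCluster(
            ga, gb, modal_a, modal_b, n, len(consistent),
            coherent=len(consistent) * 2 > n,
            evidence=[ev for ev, _, _ in items],
        ))
    return clusters


def call_translocations(clusters, known_partners,
                        config: SVConfig | None = None) -> list[SVCall]:
    """Translocation calls from coherent clusters.

    ``known_partners`` is an iterable of gene pairs (order-insensitive).
    Coherent clusters with >= min_support consistent reads are reported
    (known pair) or marked needs_confirmation (novel pair); everything else
    is retained as below_threshold.
    """
    cfg = config or SVConfig()
    known = {tuple(sorted(p)) for p in known_partners}
    calls = []
    for cl in clusters:
        novel = tuple(sorted((cl.gene_a, cl.gene_b))) not in known
        if cl.coherent and cl.n_consistent >= cfg.min_support:
            status = "needs_confirmation" if novel else "reported"
        else:
            status = "below_threshold"
        calls.append(SVCall(cl.gene_a, cl.gene_b, cl.breakpoint_a, cl.breakpoint_b,
                            cl.n_split_reads, cl.n_consistent, novel, status))
    return calls


def write_sv_calls_tsv(calls, path) -> None:
    rows = [{"gene_a": c.gene_a, "gene_b": c.gene_b,
             "breakpoint_a": c.breakpoint_a + 1, "breakpoint_b": c.breakpoint_b + 1,
             "n_split_reads": c.n_split_reads, "n_consistent": c.n_consistent,
             "novel_partner": c.novel_partner, "status": c.status}
            for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_evidence_audit(clusters, path) -> None:
    """Per-cluster evidence dump (read_id + breakpoints) for manual review —
    the deterministic stand-in for genome-browser inspection."""
    rows = []
    for cl in clusters:
        for ev in cl.evidence:
            rows.append({"gene_a": cl.gene_a, "gene_b": cl.gene_b,
                         "read_id": ev.read_id,
                         "bpA": ev.segment_a.breakpoint + 1,
                         "bpB": ev.segment_b.breakpoint + 1})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
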