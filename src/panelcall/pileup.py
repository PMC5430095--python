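"""Per-locus read evidence (pileup columns) and its construction from aligned
reads or from the package's TSV pileup dialect.

An observation records what one read saw at one reference locus: the allele
(reference base, substitution, insertion or deletion), the Phred base quality
(for InDels, the minimum over the event's flanking bases), the strand, and
the distance to the nearer read end ("tail distance" — artifacts cluster at
read ends, and the caller tests alt vs ref tail-distance distributions).

Allele tokens
-------------
- ``A C G T``      single observed base (reference or substitution)
- ``+SEQ``         insertion of SEQ immediately after this position
- ``-N``           deletion of the next N reference bases

TSV pileup dialect (bit-exact round-trip):
``chrom<TAB>pos1based<TAB>ref<TAB>obs1,obs2,...`` where each obs is
``allele:qual:strand:taildist``.  An empty fourth field is a depth-0 column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

MAX_BASE_QUALITY = 60  # sanity bound on Phred scores


class PileupError(ValueError):
    pass


def is_indel_allele(allele: str) -> bool:
    return allele.startswith("+") or allele.startswith("-")


def allele_sort_key(allele: str) -> tuple:
    """Deterministic tie-break order: substitutions (A<C<G<T) before
    insertions before deletions."""
    if allele.startswith("+"):
        return (1, allele[1:])
    if allele.startswith("-"):
        return (2, int(allele[1:]))
    return (0, allele)


@dataclass(frozen=True, slots=True)
class ReadObservation:
    """One read's evidence at one locus."""

    allele: str
    base_quality: int
    strand: str  # '+' or '-'
    tail_distance: int

    def __post_init__(self) -> None:
        if not 0 <= self.base_quality <= MAX_BASE_QUALITY:
            raise PileupError(f"base quality {self.base_quality} outside [0, {MAX_BASE_QUALITY}]")
        if self.strand not in "+-":
            raise PileupError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tail_distance < 0:
            raise PileupError("tail_distance must be >= 0")
        a = self.allele
        if a.startswith("+"):
            if len(a) < 2 or any(b not in "ACGTN" for b in a[1:]):
                raise PileupError(f"bad insertion token {a!r}")
        elif a.startswith("-"):
            if not a[1:].isdigit() or int(a[1:]) < 1:
                raise PileupError(f"bad deletion token {a!r}")
        elif a not in "ACGT":
            raise PileupError(f"bad allele token {a!r}")


class PileupColumn:
    """All read observations covering one reference position (0-based)."""

    __slots__ = ("chrom", "pos", "ref_base", "observations", "_cache")

    def __init__(self, chrom: str, pos: int, ref_base: str,
                 observations: Sequence[ReadObservation] = ()) -> None:
        self.chrom = chrom
        self.pos = pos
        self.ref_base = ref_base
        self.observations: list[ReadObservation] = list(observations)
        self._cache: dict | None = None

    @property
    def depth(self) -> int:
        return len(self.observations)

    def allele_counts(self) -> Counter:
        return Counter(o.allele for o in self.observations)

    def sr_percent(self, allele: str) -> float:
        """Supporting-reads percentage of ``allele`` against full depth."""
        if self.depth == 0:
            return 0.0
        return 100.0 * sum(1 for o in self.observations if o.allele == allele) / self.depth

    def arrays(self) -> dict:
        """Columnar view (cached): allele tokens, qualities, strands, tails."""
        if self._cache is None:
            self._cache = {
                "allele": np.array([o.allele for o in self.observations], dtype=object),
                "qual": np.array([o.base_quality for o in self.observations], dtype=np.int64),
                "strand": np.array([o.strand for o in self.observations], dtype=object),
                "tail": np.array([o.tail_distance for o in self.observations], dtype=np.int64),
            }
        return self._cache

    def __repr__(self) -> str:
        return f"PileupColumn({self.chrom}:{self.pos} ref={self.ref_base} depth={self.depth})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, PileupColumn):
            return NotImplemented
        return (self.chrom, self.pos, self.ref_base, self.observations) == (
            other.chrom, other.pos, other.ref_base, other.observations)


# ---------------------------------------------------------------------------
# TSV pileup dialect
# ---------------------------------------------------------------------------

def _obs_to_token(o: ReadObservation) -> str:
    return f"{o.allele}:{o.base_quality}:{o.strand}:{o.tail_distance}"


def _token_to_obs(token: str, where: str) -> ReadObservation:
    parts = token.split(":")
    if len(parts) != 4:
        raise PileupError(f"{where}: malformed observation token {token!r}")
    allele, qual_s, strand, tail_s = parts
    try:
        return ReadObservation(allele, int(qual_s), strand, int(tail_s))
    except (ValueError, PileupError) as exc:
        raise PileupError(f"{where}: bad observation {token!r}: {exc}") from exc


def write_pileup_tsv(columns: Iterable[PileupColumn], path) -> None:
    with open(path, "w") as fh:
        for col in columns:
            obs = ",".join(_obs_to_token(o) for o in col.observations)
            fh.write(f"{col.chrom}\t{col.pos + 1}\t{col.ref_base}\t{obs}\n")


def read_pileup_tsv(path) -> list[PileupColumn]:
    """Parse the TSV pileup dialect; positions in the file are 1-based."""
    out: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PileupError(f"{path}:{lineno}: expected ≥3 columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            obs_field = fields[3] if len(fields) > 3 else ""
            try:
                pos = int(pos_s) - 1
            except ValueError as exc:
                raise PileupError(f"{path}:{lineno}: non-integer position") from exc
            observations = []
            if obs_field:
                for tok in obs_field.split(","):
                    observations.append(_token_to_obs(tok, f"{path}:{lineno}"))
            out.append(PileupColumn(chrom, pos, ref, observations))
    return out


# ---------------------------------------------------------------------------
# InDel left-alignment
# ---------------------------------------------------------------------------

def left_align_indel(ref_seq: str, seq_start: int, anchor: int, allele: str,
                     event_seq: str = "") -> tuple[int, str]:
    """Shift an InDel to its leftmost equivalent anchor.

    ``ref_seq`` is reference sequence starting at coordinate ``seq_start``;
    ``anchor`` is the 0-based reference base the event follows.  For a
    deletion ``-N`` the deleted bases are ref[anchor+1 .. anchor+N]; for an
    insertion ``+SEQ``, ``event_seq`` (= SEQ) is inserted after ``anchor``.
    Returns (new_anchor, allele); the allele token for a deletion is
    unchanged, and for an insertion the sequence is rotated as it shifts.
    """
    def ref_at(pos: int) -> str:
        i = pos - seq_start
        if i < 0 or i >= len(ref_seq):
            return ""  # ran out of context; stop shifting
        return ref_seq[i]

    if allele.startswith("-"):
        length = int(allele[1:])
        a = anchor
        # can shift left when the base entering the deleted window from the
        # left equals the base leaving it on the right
        while ref_at(a) and ref_at(a) == ref_at(a + length):
            a -= 1
        if a < anchor and not ref_at(a + 1):
            a = anchor  # insufficient context
        return max(a, seq_start), allele
    if allele.startswith("+"):
        seq = event_seq or allele[1:]
        a = anchor
        while ref_at(a) and ref_at(a) == seq[-1]:
            seq = seq[-1] + seq[:-1]
            a -= 1
        return max(a, seq_start), "+" + seq


# ---------------------------------------------------------------------------
# Pileup construction from aligned reads (SAM/BAM via pysam)
# ---------------------------------------------------------------------------

def columns_from_alignments(alignments, region, reference=None,
                            min_mapping_quality: int = 0,
                            log_tally: dict | None = None) -> list[PileupColumn]:
    """Build pileup columns over ``region`` from coordinate-sorted pysam
    ``AlignedSegment`` records.

    Duplicate-flagged, secondary and unmapped records are skipped (PCR
    duplicate marking happens upstream; it is honored here, never redone).
    Records not overlapping the region are skipped and tallied in
    ``log_tally['skipped_off_region']``.  InDels are anchored at the leftmost
    reference base they follow and, when ``reference`` is given, left-aligned
    against it.  Raises on unsorted input.
    """
    tally = log_tally if log_tally is not None else {}
    tally.setdefault("skipped_off_region", 0)
    tally.setdefault("skipped_flagged", 0)

    by_pos: dict[int, list[ReadObservation]] = {p: [] for p in range(region.start, region.end)}
    last_start = -1
    ref_window = None
    if reference is not None:
        from .manifest import _fetch
        pad = 200
        win_start = max(0, region.start - pad)
        ref_window = (_fetch(reference, region.chrom, win_start, region.end + pad), win_start)

    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
            tally["skipped_flagged"] += 1
            continue
        if rec.reference_start < last_start:
            raise PileupError("alignment records are not coordinate-sorted")
        last_start = rec.reference_start
        if rec.reference_name != region.chrom or rec.reference_end <= region.start \
                or rec.reference_start >= region.end:
            tally["skipped_off_region"] += 1
            continue
        if rec.mapping_quality < min_mapping_quality:
            tally["skipped_flagged"] += 1
            continue
        _add_read_observations(rec, region, by_pos, ref_window)

    cols = []
    for pos in range(region.start, region.end):
        obs = by_pos[pos]
        if not obs:
            continue
        ref_base = "N"
        if ref_window is not None:
            seq, win_start = ref_window
            ref_base = seq[pos - win_start].upper()
        cols.append(PileupColumn(region.chrom, pos, ref_base, obs))
    return cols


def _add_read_observations(rec, region, by_pos, ref_window) -> None:
    strand = "-" if rec.is_reverse else "+"
    quals = rec.query_qualities
    read_len = rec.query_length or (len(quals) if quals is not None else 0)

    def tail(qpos: int) -> int:
        return min(qpos, max(read_len - 1 - qpos, 0))

    def qual(qpos: int) -> int:
        if quals is None:
            return 30
        return min(int(quals[qpos]), MAX_BASE_QUALITY)

    rpos = rec.reference_start
    qpos = 0
    seq = rec.query_sequence or ""
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            for i in range(length):
                p = rpos + i
                if region.start <= p < region.end:
                    base = seq[qpos + i].upper()
                    if base in "ACGT":
                        by_pos[p].append(ReadObservation(base, qual(qpos + i), strand, tail(qpos + i)))
            rpos += length
            qpos += length
        elif op == 1:  # insertion after ref base rpos-1
            anchor = rpos - 1
            ins = seq[qpos:qpos + length].upper()
            q = min(qual(max(qpos - 1, 0)), qual(min(qpos + length, read_len - 1)))
            allele = "+" + ins
            if ref_window is not None:
                anchor, allele = left_align_indel(ref_window[0], ref_window[1], anchor, allele, ins)
            if region.start <= anchor < region.end:
                by_pos[anchor].append(ReadObservation(allele, q, strand, tail(qpos)))
            qpos += length
        elif op == 2:  # deletion; anchored at the ref base it follows
            anchor = rpos - 1
            q = min(qual(max(qpos - 1, 0)), qual(min(qpos, read_len - 1)))
            allele = f"-{length}"
            if ref_window is not None:
                anchor, allele = left_align_indel(ref_window[0], ref_window[1], anchor, allele)
            if region.start <= anchor < region.end:
                by_pos[anchor].append(ReadObservation(allele, q, strand, tail(qpos)))
            rpos += length
        elif op == 3:  # N (skip)
            rpos += length
        elif op == 4:  # soft clip
            qpos += length
        # 5 (hard clip) and 6 (pad) consume nothing we track
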