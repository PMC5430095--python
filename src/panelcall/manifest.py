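"""Targeted-panel manifest: the ordered set of capture regions every other
module indexes against.

A manifest is a BED-like file (0-based, half-open) with four mandatory
columns — chrom, start, end, gene — and an optional fifth column carrying
the region's GC fraction.  Region identifiers are ``chrom:start-end`` unless
the file supplies them; they must be unique.  GC fractions may instead be
computed from a reference sequence with :func:`compute_gc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence


class ManifestError(ValueError):
    """Malformed or internally inconsistent panel manifest."""


@dataclass(frozen=True, slots=True)
class PanelRegion:
    """One capture target: half-open interval [start, end) on ``chrom``.

    ``gc_fraction`` is ``None`` until set from the manifest's optional GC
    column or by :func:`compute_gc`; CNV normalization refuses to run on
    regions where it is unset.
    """

    chrom: str
    start: int
    end: int
    gene: str
    gc_fraction: float | None = None
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ManifestError(
                f"region {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise ManifestError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if not self.region_id:
            object.__setattr__(self, "region_id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class Manifest:
    """Ordered collection of :class:`PanelRegion` with unique region_ids."""

    regions: list[PanelRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.regions:
            if r.region_id in seen:
                raise ManifestError(f"duplicate region_id {r.region_id!r}")
            seen.add(r.region_id)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[PanelRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> PanelRegion:
        return self.regions[i]

    def genes(self) -> list[str]:
        """Gene symbols in first-appearance order."""
        out: list[str] = []
        for r in self.regions:
            if r.gene not in out:
                out.append(r.gene)
        return out

    def regions_for_gene(self, gene: str) -> list[PanelRegion]:
        return [r for r in self.regions if r.gene == gene]

    def gene_for_position(self, chrom: str, pos: int) -> str | None:
        """Gene whose region contains (chrom, pos), or None if off-target."""
        for r in self.regions:
            if r.chrom == chrom and r.start <= pos < r.end:
                return r.gene
        return None

    def with_gc(self, reference: Mapping[str, str]) -> "Manifest":
        """Return a copy with gc_fraction computed from ``reference`` for
        every region where it is unset."""
        out = []
        for r in self.regions:
            if r.gc_fraction is None:
                gc = compute_gc(r, reference)
                r = PanelRegion(r.chrom, r.start, r.end, r.gene, gc, r.region_id)
            out.append(r)
        return Manifest(out)


def read_manifest(path) -> Manifest:
    """Read a BED-like panel manifest.

    Columns (tab-separated): chrom, start, end, gene, [gc_fraction].
    Lines beginning with ``#`` or ``track`` are skipped.  Regions are
    returned in file order.
    """
    regions: list[PanelRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ManifestError(f"{path}:{lineno}: expected ≥4 tab-separated columns")
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ManifestError(f"{path}:{lineno}: non-integer coordinate") from exc
            gc: float | None = None
            if len(fields) >= 5 and fields[4] != "":
                try:
                    gc = float(fields[4])
                except ValueError as exc:
                    raise ManifestError(f"{path}:{lineno}: bad gc value {fields[4]!r}") from exc
            try:
                regions.append(PanelRegion(chrom, start, end, gene, gc))
            except ManifestError as exc:
                raise ManifestError(f"{path}:{lineno}: {exc}") from exc
    return Manifest(regions)


def write_manifest(manifest: Manifest, path) -> None:
    """Write a manifest in the same BED-like dialect read_manifest accepts.

    read_manifest(write_manifest(m)) reproduces m exactly (round-trip)."""
    with open(path, "w") as fh:
        for r in manifest:
            cols = [r.chrom, str(r.start), str(r.end), r.gene]
            if r.gc_fraction is not None:
                cols.append(repr(r.gc_fraction))
            fh.write("\t".join(cols) + "\n")


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Sequence for [start, end) from a dict of strings or a pyfaidx-like
    object (anything whose __getitem__ supports slicing to str-able)."""
    seq = reference[chrom]
    return str(seq[start:end])


def compute_gc(region: PanelRegion, reference) -> float:
    """GC fraction of a region: (#G + #C) / (#A + #C + #G + #T).

    Case-insensitive; N and other ambiguity codes are excluded from both
    numerator and denominator.  A region of only ambiguous bases is an error,
    as is a region extending past the reference contig.
    """
    seq = _fetch(reference, region.chrom, region.start, region.end).upper()
    if len(seq) < region.size:
        raise ManifestError(
            f"region {region.region_id} extends past end of reference contig"
        )
    gc = sum(1 for b in seq if b in "GC")
    acgt = sum(1 for b in seq if b in "ACGT")
    if acgt == 0:
        raise ManifestError(f"region {region.region_id}: no unambiguous bases")
    return gc / acgt
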