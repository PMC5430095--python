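"""Sample-level QC: panel coverage metrics and the FFPE fixation-artifact
gates.

Formalin fixation deaminates cytosine; deaminated C is read as T, so poorly
fixed samples show an excess of low-frequency C>T (G>A on the opposite
strand) calls and an inflated overall variant count.  Well-behaved samples
sit around a 30-40% C>T share among substitutions at >= 5 %SR with roughly
250-330 such variants; a sample fails QC when the deamination-type share
exceeds 45% or the variant count exceeds 500.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .config import QCConfig
from .manifest import Manifest

_DEAMINATION_PAIRS = {("C", "T"), ("G", "A")}


@dataclass
class QCReport:
    mean_coverage: float = 0.0
    pct_bases_ge_100x: float = 0.0
    pct_bases_ge_200x: float = 0.0
    pct_on_target: float | None = None
    pct_duplicates: float | None = None   # reported upstream, echoed for QC
    n_variants_ge5sr: int = 0
    ct_fraction: float = 0.0
    qc_status: str = "pass"
    reasons: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        lines = [
            f"mean coverage        {self.mean_coverage:.1f}x",
            f"% bases >= 100x      {self.pct_bases_ge_100x:.1f}",
            f"% bases >= 200x      {self.pct_bases_ge_200x:.1f}",
            f"variants >= 5 %SR    {self.n_variants_ge5sr}",
            f"C>T fraction         {self.ct_fraction:.3f}",
            f"QC status            {self.qc_status.upper()}"
            + (f" ({'; '.join(self.reasons)})" if self.reasons else ""),
        ]
        if self.pct_on_target is not None:
            lines.insert(0, f"% on-target reads    {self.pct_on_target:.1f}")
        if self.pct_duplicates is not None:
            lines.insert(0, f"% duplicates         {self.pct_duplicates:.1f}")
        return "\n".join(lines)


def coverage_metrics(depths, manifest: Manifest | None = None,
                     total_reads: int | None = None,
                     on_target_reads: int | None = None,
                     duplicate_fraction: float | None = None) -> QCReport:
    """Coverage fields of the QC report from a per-base depth vector over the
    panel.  Depth thresholds are >= 100x and >= 200x."""
    depths = np.asarray(depths, dtype=float)
    if manifest is not None and len(manifest) == 0 or depths.size == 0:
        raise ValueError("empty manifest / depth vector")
    report = QCReport(
        mean_coverage=float(depths.mean()),
        pct_bases_ge_100x=float(100.0 * (depths >= 100).mean()),
        pct_bases_ge_200x=float(100.0 * (depths >= 200).mean()),
    )
    if total_reads and on_target_reads is not None:
        report.pct_on_target = 100.0 * on_target_reads / total_reads
    if duplicate_fraction is not None:
        report.pct_duplicates = 100.0 * duplicate_fraction
    return report


def ct_conversion_fraction(calls, min_sr: float = 5.0,
                           count_ga: bool = True) -> tuple[int, float]:
    """(number of substitution calls at >= min_sr %SR, fraction of them that
    are deamination-type).

    Deamination-type means ref C -> alt T, and — in the default
    strand-complementary mode — ref G -> alt A.  Returns (0, 0.0) when no
    call qualifies.
    """
    pairs = _DEAMINATION_PAIRS if count_ga else {("C", "T")}
    snvs = [c for c in calls
            if not c.is_indel and c.sr_percent >= min_sr]
    if not snvs:
        return 0, 0.0
    n_deam = sum(1 for c in snvs if (c.ref, c.alt) in pairs)
    return len(snvs), n_deam / len(snvs)


def sample_qc(report: QCReport, calls=None, config: QCConfig | None = None) -> QCReport:
    """Apply the fixation-artifact gates and set qc_status in place.

    When ``calls`` is given, n_variants_ge5sr and ct_fraction are (re)computed
    from it first.  Fails iff ct_fraction > ct_max or n_variants_ge5sr >
    nvar_max; reasons are listed.
    """
    cfg = config or QCConfig()
    if calls is not None:
        report.n_variants_ge5sr, report.ct_fraction = ct_conversion_fraction(
            calls, min_sr=cfg.qc_sr_min, count_ga=cfg.count_ga_with_ct)
    reasons = []
    if report.ct_fraction > cfg.ct_max:
        reasons.append(f"deamination: C>T fraction {report.ct_fraction:.3f} > {cfg.ct_max}")
    if report.n_variants_ge5sr > cfg.nvar_max:
        reasons.append(f"variant burden: {report.n_variants_ge5sr} > {cfg.nvar_max}")
    report.reasons = reasons
    report.qc_status = "fail" if reasons else "pass"
    return report
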