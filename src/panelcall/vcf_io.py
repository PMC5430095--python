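"""VCF 4.2 output for SNV/InDel calls.

Internal coordinates are 0-based half-open; VCF positions are 1-based.
Insertion tokens ``+SEQ`` become REF=anchor base, ALT=anchor+SEQ; deletion
tokens ``-N`` become REF=anchor+deleted bases, ALT=anchor base, so a
reference is required whenever InDel calls are present.
"""

from __future__ import annotations

from .snv import VariantCall

_HEADER = """\
##fileformat=VCFv4.2
##source=panelcall
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the locus">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting read count">
##INFO=<ID=SR,Number=1,Type=Float,Description="Supporting reads percentage against full depth">
##INFO=<ID=QT,Number=1,Type=Integer,Description="Lowest base-quality floor at which the variant was called">
##INFO=<ID=PSTRAND,Number=1,Type=Float,Description="Strand bias Fisher exact p-value">
##INFO=<ID=PBASEQ,Number=1,Type=Float,Description="Base-quality bias rank-sum p-value">
##INFO=<ID=PTAIL,Number=1,Type=Float,Description="Tail-distance bias rank-sum p-value">
##FILTER=<ID=homopolymer_indel,Description="InDel with %SR<10 in a homopolymer run of 6+ bases">
##FILTER=<ID=tail_bias,Description="Tail-distance bias rank-sum p < 1e-5">
##FILTER=<ID=low_sr,Description="Supporting reads percentage < 2">
##FILTER=<ID=low_coverage,Description="Depth below the minimum calling coverage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _ref_alt(call: VariantCall, reference) -> tuple[int, str, str]:
    """(1-based POS, REF, ALT) in VCF representation."""
    if not call.is_indel:
        return call.pos + 1, call.ref, call.alt
    if reference is None:
        raise ValueError("a reference is required to write InDel calls to VCF")
    seq = str(reference[call.chrom])
    anchor = seq[call.pos].upper()
    if call.alt.startswith("+"):
        return call.pos + 1, anchor, anchor + call.alt[1:]
    length = int(call.alt[1:])
    deleted = seq[call.pos + 1: call.pos + 1 + length].upper()
    return call.pos + 1, anchor + deleted, anchor


def format_vcf_record(call: VariantCall, reference=None) -> str:
    pos1, ref, alt = _ref_alt(call, reference)
    filt = "PASS" if call.is_pass else ";".join(sorted(call.filter_status))
    a = call.attributes
    info = (f"DP={call.depth};AC={call.alt_count};SR={call.sr_percent:.1f};"
            f"QT={call.qt_called};PSTRAND={a.get('strand_bias_p', 1.0):.4g};"
            f"PBASEQ={a.get('baseq_bias_p', 1.0):.4g};"
            f"PTAIL={a.get('tail_bias_p', 1.0):.4g}")
    return f"{call.chrom}\t{pos1}\t.\t{ref}\t{alt}\t{call.score:.2f}\t{filt}\t{info}"


def write_vcf(calls, path, reference=None) -> None:
    """Write calls (PASS and filtered alike) as a VCF 4.2 file."""
    records = sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for call in records:
            fh.write(format_vcf_record(call, reference) + "\n")
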