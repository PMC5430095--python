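import numpy as np
import pytest

from panelcall.manifest import Manifest, PanelRegion
from panelcall.pileup import PileupColumn, ReadObservation


def build_column(n_ref, n_alt, alt="T", ref="A", qual=30, alt_qual=None,
                 chrom="chr1", pos=100, seed=0, read_length=150,
                 alt_tails=None, ref_tails=None):
    """Column with n_ref reference and n_alt alt observations; tail
    distances uniform over read offsets unless given explicitly."""
    rng = np.random.default_rng(seed)

    def tails(n, fixed):
        if fixed is not None:
            return list(fixed)
        off = rng.integers(0, read_length, size=n)
        return np.minimum(off, read_length - 1 - off).tolist()

    obs = []
    for i, t in enumerate(tails(n_ref, ref_tails)):
        obs.append(ReadObservation(ref, qual, "+" if i % 2 == 0 else "-", int(t)))
    for i, t in enumerate(tails(n_alt, alt_tails)):
        obs.append(ReadObservation(alt, alt_qual if alt_qual is not None else qual,
                                   "+" if i % 2 == 0 else "-", int(t)))
    return PileupColumn(chrom, pos, ref, obs)


@pytest.fixture
def toy_manifest():
    """Two genes, five regions, GC set."""
    return Manifest([
        PanelRegion("chr17", 100, 200, "ERBB2", 0.50, "r1"),
        PanelRegion("chr17", 300, 450, "ERBB2", 0.52, "r2"),
        PanelRegion("chr17", 500, 700, "ERBB2", 0.48, "r3"),
        PanelRegion("chr10", 100, 300, "RET", 0.44, "r4"),
        PanelRegion("chr10", 400, 500, "RET", 0.46, "r5"),
    ])


@pytest.fixture(scope="session")
def panel_manifest():
    """Bigger panel: 4 genes x 8 regions of varying size and GC, for CNV
    simulation tests."""
    rng = np.random.default_rng(7)
    regions = []
    pos = 0
    for g, gene in enumerate(["ERBB2", "MYC", "CDKN2A", "RET"]):
        for i in range(8):
            size = int(rng.integers(120, 400))
            gc = float(rng.uniform(0.35, 0.65))
            regions.append(PanelRegion(f"chr{g + 1}", pos, pos + size, gene, gc,
                                       f"{gene}_{i}"))
            pos += size + 50
    return Manifest(regions)
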