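import numpy as np
import pytest

from nmdscreen.barcodes import BarcodeManifest
from nmdscreen.panel import AlleleDef, AmpliconPanel
from nmdscreen.scoring import Carrier, PoolDesign
from nmdscreen.simulate import build_barcode_manifest, build_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_manifest():
    """Four plates x eight wells, well-separated barcodes, deterministic."""
    rng = np.random.default_rng(99)
    return build_barcode_manifest(rng, n_plates=4, wells_per_plate=8)


@pytest.fixture
def tiny_manifest():
    """Hand-built manifest with known barcodes for exact-semantics tests."""
    return BarcodeManifest(
        plate_barcodes={"P1": "AAAAAAAA", "P2": "CCCCCCCC"},
        well_barcodes={"A1": "ACGTACGTAC", "A2": "TGCATGCATG"},
        plate_barcode_offset=0,
        well_barcode_offset=8,
        max_mismatches=1,
    )


@pytest.fixture
def panel(rng):
    return build_panel(rng)


@pytest.fixture
def design():
    return PoolDesign(
        n_lines=3,
        carriers={
            "STAG2_clone2_mut": Carrier("STAG2", 1, 1.0),
            "STAG2_clone8_mut": Carrier("STAG2", 1, 1.0),
            "TP53_clone221_mut": Carrier("TP53", 1, 1.0),
        },
    )


@pytest.fixture
def het_design():
    """Pool with one heterozygous carrier (dosage 0.5)."""
    return PoolDesign(
        n_lines=3,
        carriers={"GENE_mut": Carrier("GENE", 1, 0.5)},
    )


@pytest.fixture
def toy_panel():
    """Two-gene toy panel with obvious diagnostic windows."""
    return AmpliconPanel(
        [
            AlleleDef("G1", "G1_wt", "AAAACCCCGGGGTTTTAAAACCCC", (4, 12), False),
            AlleleDef("G1", "G1_m1_mut", "AAAATTTTGGGGTTTTAAAACCCC", (4, 12), True, "line1"),
            AlleleDef("G2", "G2_wt", "GATCGATCGATCAAGGCCTTACGT", (8, 16), False),
            AlleleDef("G2", "G2_m1_mut", "GATCGATCTTTTAAGGCCTTACGT", (4, 12), True, "line2"),
        ]
    )
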