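import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("edsmap", derandomize=True, deadline=None)
settings.load_profile("edsmap")

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from edsmap import EDSGraph, RefIndicator, build_graph, classify_variants

#: the running example: reference TTNGACAATGAT with a 1-bp deletion (GA>G),
#: an AT>TA replacement and a copy-number variation over positions 3..11
TOY_REF = "TTNGACAATGAT"
TOY_GSTRING = "TT#NG(A|)CA(AT|TA)GA#T"
TOY_EDGES = [(1, 1), (2, 1), (2, 2)]
TOY_INDICATOR = "1101101001101100001101"

TOY_VCF_ROWS = [
    ("toy", 2, "T", ("<DUP>",), {"SVTYPE": "DUP", "END": 11}),
    ("toy", 4, "GA", ("G",), {}),
    ("toy", 8, "AT", ("TA",), {}),
]

TOY_FASTA_TEXT = ">toy\nTTNGACAATGAT\n"
TOY_VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=toy,length=12>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">
##ALT=<ID=DUP,Description="Duplication">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
toy\t2\t.\tT\t<DUP>\t.\t.\tSVTYPE=DUP;END=11
toy\t4\t.\tGA\tG\t.\t.\t.
toy\t8\t.\tAT\tTA\t.\t.\t.
"""


@pytest.fixture
def toy_graph() -> EDSGraph:
    """The worked-example graph, constructed directly from its string form."""
    return EDSGraph.from_gstring(TOY_GSTRING, edges=TOY_EDGES)


@pytest.fixture
def toy_indicator() -> RefIndicator:
    return RefIndicator.from_01_string(TOY_INDICATOR)


@pytest.fixture
def toy_built():
    """The same graph assembled from reference + variants."""
    variants, skipped = classify_variants(TOY_VCF_ROWS)
    assert not skipped
    graph, bits, dropped = build_graph({"toy": TOY_REF}, variants)
    return graph, RefIndicator(bits)


@pytest.fixture
def toy_files(tmp_path):
    fasta = tmp_path / "toy.fa"
    vcf = tmp_path / "toy.vcf"
    fasta.write_text(TOY_FASTA_TEXT)
    vcf.write_text(TOY_VCF_TEXT)
    return fasta, vcf, tmp_path
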