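import numpy as np
import pytest

from mrnspec.hgvs import parse_cdna_change, parse_protein_change
from mrnspec.ingest import MutationRecord


def make_record(gene="MRE11", sample="S1", aa="E185Q", cdna=None,
                tissue="large_intestine", origin="unknown",
                zygosity="unknown", pubmed=None):
    return MutationRecord(
        gene=gene, sample_id=sample,
        protein_change=parse_protein_change(aa),
        cdna_change=parse_cdna_change(cdna) if cdna else None,
        tissue=tissue, origin=origin, zygosity=zygosity, pubmed_id=pubmed)


@pytest.fixture
def toy_records():
    """Small mixed-kind record set for one gene."""
    return [
        make_record(sample="S1", aa="E185Q", cdna="c.553G>C"),
        make_record(sample="S2", aa="Q689*", cdna="c.2065C>T"),
        make_record(sample="S3", aa="N511Ifs*13", cdna="c.1532del"),
        make_record(sample="S4", aa="L34=", cdna="c.102G>A"),
        make_record(sample="S5", aa="p.?", cdna="c.123+5G>A"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
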