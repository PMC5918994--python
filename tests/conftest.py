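import warnings

import numpy as np
import pytest

import snvppv as sp


@pytest.fixture(scope="session")
def default_table():
    """A 500-row training table from the default generative conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sp.simulate_training_table(sp.default_config(seed=42))


@pytest.fixture(scope="session")
def m116_model(default_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sp.fit(default_table, sp.named_spec("m11_6"))


def make_record(pos=100, ref="A", alt="G", genotype="het", qual=50.0, depth=30, contig="chr1"):
    return sp.VariantRecord(
        contig=contig, pos=pos, ref=ref, alt=alt, genotype=genotype, qual=qual, depth=depth
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def toy_vcf(tmp_path):
    """Write records to a VCF file and return its path."""

    def _write(records, name="toy.vcf"):
        path = tmp_path / name
        sp.write_vcf(records, path)
        return str(path)

    return _write
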