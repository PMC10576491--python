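import pytest

from mitochar.gene_order import load_template
from mitochar.synth_data import SynthConfig, generate_mitogenome


@pytest.fixture(scope="session")
def phyllo_template():
    return load_template("phylloscopus")


@pytest.fixture(scope="session")
def gallus_template():
    return load_template("gallus_like")


@pytest.fixture(scope="session")
def synth_genome():
    """One deterministic synthetic mitogenome plus its planted truth."""
    return generate_mitogenome(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def synth_genbank(tmp_path_factory, synth_genome):
    from mitochar.mito_io import write_genbank

    rec, _ = synth_genome
    path = tmp_path_factory.mktemp("gb") / "synthetic.gb"
    write_genbank([rec], path)
    return path
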