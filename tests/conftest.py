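import pytest

from faersig.contingency import ContingencyTable
from faersig.pipeline import RunConfig, run
from faersig.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def sevelamer_table() -> ContingencyTable:
    """The strongest-signal drug's 2x2 table, reconstructed from published
    margins (a, N, event margin) plus the drug margin solved from the
    published ROR of 115.51."""
    return ContingencyTable.from_margins_and_ror(
        a=2369, n=50_659_288, event_margin=169_897, ror=115.51
    )


@pytest.fixture(scope="session")
def synth(tmp_path_factory):
    """One default synthetic dataset shared across the suite: generated
    files, ground-truth ledger, and the full pipeline run on them."""
    data_dir = tmp_path_factory.mktemp("synth_data")
    out_dir = tmp_path_factory.mktemp("synth_out")
    config = SyntheticConfig(seed=20240331, n_reports=20000)
    ledger = generate(config, str(data_dir))
    result = run(RunConfig(input_dir=str(data_dir), out_dir=str(out_dir),
                           top_n=8, seed=7))
    return {"config": config, "data_dir": str(data_dir), "ledger": ledger,
            "result": result}
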