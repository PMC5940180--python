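import numpy as np
import pytest

from phosphonet.io_model import RunConfig


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def make_measurement(
    peptide="p1",
    protein="P1",
    site=10,
    window="AAAAAASAAAAAA",
    early=(1.0, 1.0, 1.0),
    late=(1.0, 1.0),
    significant=None,
):
    from phosphonet.io_model import PeptideMeasurement

    return PeptideMeasurement(
        peptide_id=peptide,
        protein_id=protein,
        site=site,
        window=window,
        ratios={
            "nacl_5min": tuple(early),
            "nacl_15min": (late[0],),
            "nacl_30min": (late[1],),
        },
        significant=significant,
    )
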