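import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_params():
    """A quick-to-simulate parameter set for mechanics tests."""
    from netpol.simulator import ModelParameters
    return ModelParameters(total_time=4.0)


@pytest.fixture
def toy_annotation():
    """Three plus- and two minus-strand genes on one small chromosome."""
    rows = [
        ("gA", "c1", 1000, 2600, "+"),
        ("gB", "c1", 3500, 5200, "+"),
        ("gC", "c1", 6000, 7400, "-"),
        ("gD", "c1", 8200, 10200, "+"),
        ("gE", "c1", 11000, 12800, "-"),
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["length"] = df["end"] - df["start"]
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["pas"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    df["biotype"] = "protein_coding"
    return df


@pytest.fixture
def empty_track_factory():
    from netpol.seqproc import SignalTrack

    def make(sample="s", length=14000, chrom="c1"):
        return SignalTrack(sample, {chrom: {"+": np.zeros(length),
                                            "-": np.zeros(length)}})
    return make
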