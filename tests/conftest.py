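import pytest

from proxilearn import ProteomeDb, SynthConfig, generate_experiment


@pytest.fixture(scope="session")
def tiny_db() -> ProteomeDb:
    return ProteomeDb(records={
        "P1": ("gen-1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        "P2": ("gen-2", "ACDEFGHIKLMNPQRSTVWY" * 3),
        "P3": (None, "WWWWYYYYYCCCCMMMMHHHH"),
    })


@pytest.fixture(scope="session")
def bundle7():
    """One default synthetic experiment, shared across tests (read-only)."""
    return generate_experiment(SynthConfig(seed=7))
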