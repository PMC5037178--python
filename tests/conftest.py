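import pytest

from spaudit import SyntheticConfig, run_synthetic_study


@pytest.fixture(scope="session")
def small_study():
    """One complete synthetic audit run at reduced size, shared read-only."""
    return run_synthetic_study(
        seed=7,
        config=SyntheticConfig(n_pos=30, n_neg=30, seed=7),
        n_bootstrap=30,
        keep_replicates=True,
    )


@pytest.fixture()
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
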