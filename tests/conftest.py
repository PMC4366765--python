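from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import pytest

from spectracount.identification import PsmRecord


@pytest.fixture
def make_psm():
    """Factory for PSM records with sensible defaults."""

    counter = {"n": 0}

    def _make(
        probability: float = 0.95,
        peptide: str = "PEPTIDEK",
        accessions: tuple[str, ...] = ("P1",),
        run_id: str = "sham_1_1",
        decoy: bool = False,
        protein_probability: float = 0.99,
    ) -> PsmRecord:
        counter["n"] += 1
        return PsmRecord(
            spectrum_id=f"spec{counter['n']}",
            run_id=run_id,
            peptide_sequence=peptide,
            protein_accessions=accessions,
            peptide_probability=probability,
            protein_probability=protein_probability,
            decoy_flag=decoy,
        )

    return _make
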