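import pytest

from gluquant import PeptideMeasurement, ProteinRecord, SimConfig, simulate


def make_measurement(
    subject_id="S1",
    group="case",
    replicate_index=1,
    accession="P1",
    peptide_sequence="ACK",
    cys_positions=(2,),
    confidence_pct=99.0,
    h_to_l=1.0,
    sample_id=None,
):
    return PeptideMeasurement(
        sample_id=sample_id or f"{subject_id}_R{replicate_index}",
        subject_id=subject_id,
        group=group,
        replicate_index=replicate_index,
        accession=accession,
        peptide_sequence=peptide_sequence,
        peptide_cys_positions=tuple(cys_positions),
        confidence_pct=confidence_pct,
        h_to_l=h_to_l,
    )


@pytest.fixture
def measurement_factory():
    return make_measurement


@pytest.fixture
def small_protein():
    return ProteinRecord(accession="P1", description="P1", sequence="MACDEFCK")


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulation with planted effects, shared across tests."""
    return simulate(SimConfig(seed=11, n_proteins=20))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free, dropout-free simulation: observed ratios are exact."""
    return simulate(
        SimConfig(
            seed=12,
            n_proteins=15,
            noise_cv=0.0,
            missing_rate=0.0,
            confidence_high_fraction=1.0,
        )
    )


def balanced_design(values_by_subject, **kwargs):
    """Build measurements for one peptide from {(subject, group): [replicates]}."""
    out = []
    for (subject, group), reps in values_by_subject.items():
        for i, v in enumerate(reps, start=1):
            out.append(
                make_measurement(
                    subject_id=subject,
                    group=group,
                    replicate_index=i,
                    h_to_l=v,
                    **kwargs,
                )
            )
    return out
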