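import pytest

from circuitseq import CircuitAnnotation, GroundTruth, Part, PartType

REF = "plasmid"
REF_LENGTH = 6000


def build_two_gate_annotation() -> CircuitAnnotation:
    """Two transcription units, each promoter -> ribozyme -> gene ->
    terminator, on a 6 kb plasmid."""
    parts = [
        Part("P1", PartType.PROMOTER, REF, 100, 135, "+", {"tss": 135}),
        Part("R1", PartType.RIBOZYME, REF, 135, 210, "+", {"cut_site": 180}),
        Part("G1", PartType.CDS, REF, 240, 1140, "+"),
        Part("T1", PartType.TERMINATOR, REF, 1160, 1220, "+"),
        Part("P2", PartType.PROMOTER, REF, 1300, 1335, "+", {"tss": 1335}),
        Part("R2", PartType.RIBOZYME, REF, 1335, 1410, "+", {"cut_site": 1380}),
        Part("G2", PartType.CDS, REF, 1440, 2340, "+"),
        Part("T2", PartType.TERMINATOR, REF, 2360, 2420, "+"),
    ]
    return CircuitAnnotation(parts, REF, REF_LENGTH)


def build_truth(noise_sigma: float = 0.0) -> GroundTruth:
    return GroundTruth(
        promoter_activities={"s1": {"P1": 2.0, "P2": 4.0}},
        terminator_ts={"T1": 80.0, "T2": 150.0},
        ribozyme_pc={"R1": 0.95, "R2": 0.95},
        read_through_in=0.05,
        noise_sigma=noise_sigma,
    )


@pytest.fixture
def annotation() -> CircuitAnnotation:
    return build_two_gate_annotation()


@pytest.fixture
def truth() -> GroundTruth:
    return build_truth()
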