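import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def synthetic_genome():
    """A seeded genome with a planted atp8-like ORF, plus its truth table."""
    from mytilomito.synthetic import SyntheticGenomeSpec, generate_mitogenome

    return generate_mitogenome(SyntheticGenomeSpec(seed=42))


@pytest.fixture
def toy_genome():
    """Tiny hand-built circular genome: two genes and one long spacer."""
    from mytilomito.mito_io import GeneFeature, Mitogenome

    seq = ("ATG" + "GCA" * 38 + "TAA") + "T" * 100 + ("ATG" + "GGT" * 18 + "TAG")
    features = [
        GeneFeature("cox1", "PCG", 0, 120, "+"),
        GeneFeature("nad1", "PCG", 220, 280, "+"),
    ]
    return Mitogenome("toy", seq + "A" * 20, circular=True, features=features)
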