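import numpy as np
import pytest
from hypothesis import settings

from tagsip.gradient_io import FractionRecord, GradientProfile

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_profile(densities, dna, counts_by_otu, sample_id="test", isotope="12C"):
    """Build a GradientProfile from parallel vectors.

    ``counts_by_otu`` maps otu_id -> per-fraction count list.
    """
    fractions = []
    for i, (rho, mass) in enumerate(zip(densities, dna)):
        counts = {otu: int(v[i]) for otu, v in counts_by_otu.items()}
        fractions.append(
            FractionRecord(
                fraction_id=i + 1,
                buoyant_density=float(rho),
                dna_mass=float(mass),
                counts=counts,
            )
        )
    return GradientProfile(sample_id=sample_id, isotope=isotope, fractions=fractions)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def five_fraction_profile():
    """Minimal analyzable gradient: 5 fractions, 2 OTUs."""
    densities = [1.68, 1.69, 1.70, 1.71, 1.72]
    dna = [5.0, 10.0, 20.0, 10.0, 5.0]
    counts = {
        "otuA": [10, 40, 100, 40, 10],
        "otuB": [5, 20, 50, 20, 5],
    }
    return make_profile(densities, dna, counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
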