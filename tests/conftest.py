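import pytest

from cisscan.cgf_profile import CGFProfile, GeneFamily, classify_family
from cisscan.synthetic_data import default_reference_catalog


def make_profile(spec, n_references=8):
    """Build a profile from {family_id: (role, frequency)} shorthand."""
    families = tuple(
        GeneFamily(
            family_id=fam,
            role=role,
            frequency=freq,
            category=classify_family(freq),
        )
        for fam, (role, freq) in spec.items()
    )
    return CGFProfile(families=families, n_references=n_references)


@pytest.fixture(scope="session")
def catalog():
    """Default seeded synthetic reference catalog: (membership, profile,
    role_map)."""
    return default_reference_catalog(seed=7)


@pytest.fixture(scope="session")
def profile(catalog):
    return catalog[1]


@pytest.fixture(scope="session")
def membership(catalog):
    return catalog[0]


@pytest.fixture()
def toy_profile():
    """Small profile with one family per role used by a handful of tests."""
    spec = {
        "famA": ("Cis8", 1.0),
        "famB": ("Cis1", 7 / 8),
        "famC": ("Cis4", 7 / 8),
        "famD": ("Cis15", 3 / 8),
        "famE": ("Cis13", 5 / 8),
        "famF": ("Cis14", 5 / 8),
        "famG": ("Cis6", 4 / 8),
        "famH": ("unknown", 1 / 8),
    }
    return make_profile(spec)
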