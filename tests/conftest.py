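import pytest

from phamkit.alignment import AlignmentCache
from phamkit.clustering import assemble_phams
from phamkit.fixtures import FixtureSpec, build_fixture

#: Seed used for the planted-truth suites (derandomised; any seed works,
#: these just keep runs reproducible).
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def shared_cache():
    return AlignmentCache()


@pytest.fixture(scope="session")
def trapfree_fixture():
    """5 planted families x 8 members at identities 0.9/0.7/0.5/0.4/0.35
    plus 10 orphams — the standard study conditions."""
    return build_fixture(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def trapfree_phams(trapfree_fixture, shared_cache):
    """Default two-stage pipeline run once over the trap-free fixture."""
    return assemble_phams(trapfree_fixture.genomes, cache=shared_cache)


@pytest.fixture(scope="session")
def trap_fixture():
    return build_fixture(
        FixtureSpec(seed=FIXTURE_SEED, domain_chain=True, intein=True,
                    short_fragment=True)
    )


@pytest.fixture(scope="session")
def trap_phams(trap_fixture, shared_cache):
    return assemble_phams(trap_fixture.genomes, cache=shared_cache)


@pytest.fixture(scope="session")
def small_fixture():
    """Smaller, cheaper dataset for grid-search and CLI tests."""
    return build_fixture(
        FixtureSpec(
            n_families=3, members_per_family=4,
            family_identities=(0.9, 0.6, 0.4), ancestor_length=120,
            n_orphams=3, orpham_length=120, seed=FIXTURE_SEED,
        )
    )
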