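import pytest

from nguild.auxotrophy import community_profiles
from nguild.core_model import qc_filter
from nguild.nitrogen_census import census_community, default_marker_map
from nguild.pathway_engine import default_pathways
from nguild.synthetic_data import build_fixture


@pytest.fixture(scope="session")
def fixture_community():
    """The packaged 55-MAG community after QC (all genomes pass)."""
    return qc_filter(build_fixture())


@pytest.fixture(scope="session")
def defs():
    return default_pathways()


@pytest.fixture(scope="session")
def cfix_defs(defs):
    return [d for d in defs if d.category == "carbon_fixation"]


@pytest.fixture(scope="session")
def marker_map():
    return default_marker_map()


@pytest.fixture(scope="session")
def fixture_reps(fixture_community, marker_map):
    return census_community(fixture_community, marker_map)


@pytest.fixture(scope="session")
def fixture_profiles(fixture_community, defs):
    return community_profiles(fixture_community, defs)
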