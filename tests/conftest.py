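import pytest

import swathqc as sq


@pytest.fixture(scope="session")
def sim_config():
    return sq.SimulationConfig(seed=7, n_proteins=25)


@pytest.fixture(scope="session")
def proteome_records(sim_config):
    return sq.generate_proteome(sim_config)


@pytest.fixture(scope="session")
def proteome_index(sim_config, proteome_records):
    return sq.index_records(proteome_records, sim_config.digest_params)


@pytest.fixture(scope="session")
def clean_library(sim_config, proteome_records):
    """A conflict-free synthetic library with fully theoretical m/z."""
    return sq.generate_library(sim_config, proteome_records)


@pytest.fixture(scope="session")
def covering_scheme(clean_library):
    """A 64-window variable scheme spanning the library's precursor range."""
    lo = min(a.precursor_mz for a in clean_library.assays) - 5.0
    hi = max(a.precursor_mz for a in clean_library.assays) + 5.0
    return sq.generate_swath_scheme(64, lo, hi, overlap=1.0, variable=True, seed=11)


@pytest.fixture(scope="session")
def conflict_free_library(clean_library, covering_scheme):
    """The clean library with incidentally conflicting assays removed."""
    return sq.filter_conflicts(clean_library, covering_scheme).clean_library
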