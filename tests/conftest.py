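import warnings

import pytest

import karyosort as ks


@pytest.fixture(scope="session")
def table1_records():
    """The packaged published count table, loaded once (warnings silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ks.CountInconsistencyWarning)
        return ks.load_table1_fixture()


@pytest.fixture(scope="session")
def two_site_cross():
    """U=4 architecture with 2 fusion sites; parents 2n=8 and 2n=4."""
    arch = ks.FusionArchitecture(4, ((1, 2), (3, 4)))
    p1 = ks.RaceKaryotype(arch, frozenset(), name="P1")
    p2 = ks.RaceKaryotype(arch, frozenset({0, 1}), name="P2")
    return arch, p1, p2


def race_pair(n_sites: int, n_units: int | None = None):
    """An architecture with n_sites sites plus all-unfused / all-fused races."""
    n_units = n_units if n_units is not None else 2 * n_sites + 1
    arch = ks.FusionArchitecture(
        n_units, tuple((2 * i + 1, 2 * i + 2) for i in range(n_sites))
    )
    return (
        arch,
        ks.RaceKaryotype(arch, frozenset(), name="A"),
        ks.RaceKaryotype(arch, frozenset(range(n_sites)), name="B"),
    )
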