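import pytest

from ovfatigue import (
    FatigueProtocol,
    FoundationStack,
    LoadCase,
    ModelConstants,
    VeneerGeometry,
    load_packaged_experiment,
    preset_material,
)


@pytest.fixture(scope="session")
def zirconia():
    return preset_material("zirconia_5y")


@pytest.fixture(scope="session")
def lithium_disilicate():
    return preset_material("lithium_disilicate")


@pytest.fixture(scope="session")
def foundation():
    return FoundationStack(
        cement_modulus_Es=7.9, substrate_modulus_Ec=18.6, cement_thickness_h=0.04
    )


@pytest.fixture(scope="session")
def load_case():
    return LoadCase(applied_load_F=49.0, frequency_f=1.6, reference_time_t0=1.0)


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def protocol():
    return FatigueProtocol()


@pytest.fixture(scope="session")
def geometry_05():
    return VeneerGeometry(thickness_d=0.5, cusp_incline_theta=15.0)


@pytest.fixture(scope="session")
def experiment_table():
    return load_packaged_experiment()
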