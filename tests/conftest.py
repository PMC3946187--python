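import pytest

from gambi.core_index import EcologicalGroup, EcologicalGroupMap, StationSample


@pytest.fixture
def five_group_map() -> EcologicalGroupMap:
    """One species per ecological group plus one unassigned."""
    eg = EcologicalGroupMap()
    eg.add("Aphelochaeta marioni", "Annelida", EcologicalGroup.IV)
    eg.add("Abra alba", "Mollusca", EcologicalGroup.III)
    eg.add("Ampelisca brevicornis", "Arthropoda", EcologicalGroup.I)
    eg.add("Capitella capitata", "Annelida", EcologicalGroup.V)
    eg.add("Cirratulus cirratus", "Annelida", EcologicalGroup.II)
    eg.add("Incerta sedis", "Mollusca", EcologicalGroup.UNASSIGNED)
    return eg


@pytest.fixture
def sample_factory():
    def make(station_id="st1", **abundances):
        return StationSample(station_id=station_id, abundances=dict(abundances))

    return make
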