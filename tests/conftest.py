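import pytest

from connmine.lexicon import RegionEntry, RegionLexicon
from connmine.relations import ExtractorConfig


@pytest.fixture(scope="session")
def bg_lexicon() -> RegionLexicon:
    """A small basal-ganglia-style lexicon with synonyms and a hierarchy."""
    entries = [
        RegionEntry("GPI", "globus pallidus internal segment", {"GPi", "internal globus pallidus", "entopeduncular nucleus"}),
        RegionEntry("GPE", "globus pallidus external segment", {"GPe"}),
        RegionEntry("GP", "globus pallidus", {"pallidum"}),
        RegionEntry("STN", "subthalamic nucleus", {"STN"}),
        RegionEntry("TH", "thalamus"),
        RegionEntry("VT", "ventral thalamic nuclei", {"ventral thalamus"}, parent_id="TH"),
        RegionEntry("HY", "hypothalamus"),
        RegionEntry("CBN", "cerebellar nuclei"),
        RegionEntry("SN", "substantia nigra", {"SN"}),
        RegionEntry("SNC", "substantia nigra pars compacta", {"SNc"}, parent_id="SN"),
        RegionEntry("A", "region A"),
        RegionEntry("C", "region C"),
        RegionEntry("D", "region D"),
    ]
    return RegionLexicon(entries, source_order=["aba"])


@pytest.fixture(scope="session")
def extractor_cfg() -> ExtractorConfig:
    return ExtractorConfig()
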