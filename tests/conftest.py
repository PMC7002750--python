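import numpy as np
import pytest

from driverscan import ElementSet, GenomicElement, RegionMask


@pytest.fixture
def rng():
    return np.random.default_rng(20201021)


@pytest.fixture
def toy_elements():
    """Three small elements on two chromosomes."""
    es = ElementSet("toy")
    es.add(GenomicElement("e1", {"chr1": [(0, 100)]}))
    es.add(GenomicElement("e2", {"chr1": [(150, 250), (300, 350)]}))
    es.add(GenomicElement("e3", {"chr2": [(10, 60)]}))
    return es


@pytest.fixture
def half_mask():
    """Mask covering the first half of e1 and all of e3."""
    return RegionMask({"chr1": [(0, 50)], "chr2": [(0, 100)]})


def bed_file(tmp_path, lines, name="elements.bed"):
    path = tmp_path / name
    path.write_text("".join(line + "\n" for line in lines))
    return str(path)
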