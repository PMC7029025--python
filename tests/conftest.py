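import pytest

import lipoladder as lp


@pytest.fixture()
def family_peaks():
    """The bundled six-peak isoform-family peak list (four cyclic, two linear)."""
    return lp.bundled_peaklist()


@pytest.fixture()
def annotated_family(family_peaks):
    """Fully annotated family, anchored at the C13 member (id "B")."""
    families = lp.annotate_peaks(family_peaks, anchor=("B", 13))
    assert len(families) == 1
    return families[0]


@pytest.fixture()
def activity_records():
    return lp.load_activity_table()
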