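import pytest

from driftkit import synthgen
from driftkit.core import AOI, AOISet, Fixation, FixationSequence, line_centers


@pytest.fixture(scope="session")
def page3x5():
    """Synthetic 3-line, 5-words-per-line stimulus with known word AOIs."""
    return synthgen.make_stimulus_fixture(n_lines=3, words_per_line=5)


@pytest.fixture(scope="session")
def aois3x5(page3x5):
    return page3x5[1]


@pytest.fixture(scope="session")
def geom3x5(aois3x5):
    return line_centers(aois3x5)


@pytest.fixture
def clean_trial(aois3x5):
    """Regression-free, lightly jittered fixations plus their true lines."""
    return synthgen.gen_basic(aois3x5, synthgen.GenParams(dispersion_sd=3, seed=1))


@pytest.fixture(scope="session")
def table2_aois():
    """The three word AOIs of the published sample hit-test report."""
    return AOISet([
        AOI("word", 137.5, 147, 119, 44, line=1, part=1, image="stimulus.png"),
        AOI("word", 262.5, 147, 112, 44, line=1, part=2, image="stimulus.png"),
        AOI("word", 382.5, 147, 65, 44, line=1, part=3, image="stimulus.png"),
    ])


@pytest.fixture(scope="session")
def table2_fixations():
    """The three printed fixations matching the sample report rows."""
    return FixationSequence([
        Fixation(168, 166, 300),
        Fixation(308, 166, 250),
        Fixation(399, 178, 200),
    ])
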