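import numpy as np
import pytest

from epiallele.panel import AmpliconLocus, make_locus_panel


@pytest.fixture(scope="session")
def panel():
    return make_locus_panel(n_cpgs_per_locus=10, amplicon_length=200, rng_seed=1)


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {loc.name: loc for loc in panel}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_locus():
    """A hand-built locus whose layout is fully known.

    reference ACCGTTCCGAACCGTTCCGAACCGTCAT: CpG cytosines at 2, 7, 12, 17,
    22; non-CpG cytosines at 1, 6, 11, 16, 21, 25.
    """
    return AmpliconLocus(
        name="TINY",
        imprint_class="germ_marker",
        reference="ACCGTTCCGAACCGTTCCGAACCGTCAT",
        cpg_positions=(2, 7, 12, 17, 22),
        non_cpg_c_positions=(1, 6, 11, 16, 21, 25),
    )
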