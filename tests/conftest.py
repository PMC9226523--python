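import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from scarcall.amplicon import AmpliconReference, find_homopolymer_tracts
from scarcall.simulate import SimulationConfig, make_reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# tiny handmade amplicon for unit tests: 6-bp primers, cut between the
# repeat cassette halves
TOY_PRIMER_FWD = "ACGTAC"
TOY_PRIMER_REV = "CATGGA"  # revcomp = TCCATG
TOY_CORE = "GGCATCATGGAAAAGGCTTCCGATTGCA"


@pytest.fixture(scope="session")
def toy_ref() -> AmpliconReference:
    seq = TOY_PRIMER_FWD + TOY_CORE + "TCCATG"
    return AmpliconReference(
        name="toy",
        sequence=seq,
        cut_site=len(seq) // 2,
        primer_fwd=TOY_PRIMER_FWD,
        primer_rev=TOY_PRIMER_REV,
        tracts=tuple(find_homopolymer_tracts(seq, 4)),
    )


@pytest.fixture(scope="session")
def sim_amplicon():
    return make_reference(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
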