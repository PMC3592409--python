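import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from seqverify import ReferenceSeq, ScoringScheme


@pytest.fixture
def scoring():
    return ScoringScheme()


@pytest.fixture
def toy_scoring():
    """Thresholds relaxed so short synthetic sequences can align."""
    return ScoringScheme(min_placement_score=5.0, min_identity=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_ref(length, seed=0, ref_id="ref"):
    g = np.random.default_rng(seed)
    return ReferenceSeq(ref_id, "".join(g.choice(list("ACGT"), size=length)))
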