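import numpy as np
import pytest

from exoeval.normalize import ReferenceSequence
from exoeval.simulate import amplicon_config, make_reference, make_truth, simulate_library


@pytest.fixture(scope="session")
def toy_reference() -> ReferenceSequence:
    """Small fixed reference with a homopolymer run and a repeat."""
    return ReferenceSequence(
        {
            "chr1": "ATTTTCGGACGTACGTAAAAACGTGCATGCATGCATGCAGTCAGTACGGT",
            "chr2": "ACGTACGTACGTACGTACGT",
        }
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One seeded amplicon simulation shared by read-heavy tests.

    60X keeps the per-amplicon read counts inside the trim space so that
    coordinate duplicates are dominated by the injected PCR copies.
    """
    cfg = amplicon_config(seed=11, mean_depth=60.0)
    reference, features = make_reference(cfg)
    truth = make_truth(reference, cfg, features)
    library = simulate_library(reference, truth, cfg)
    return cfg, reference, features, truth, library
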