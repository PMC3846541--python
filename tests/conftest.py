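import numpy as np
import pytest

from vdjcapture.locus import LocusBlueprint, LocusSpec, build_synthetic_model, design_baits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def igh_model():
    """Small IGH-like locus: 3 V (23-spacer), 2 D (12/23), 2 J (12-spacer)."""
    bp = LocusBlueprint(
        loci=[LocusSpec(name="IGH", n_v=3, n_d=2, n_j=2, spacing=600, margin=2000)],
        seed=11,
    )
    return build_synthetic_model(bp)


@pytest.fixture(scope="session")
def igk_inverted_model():
    """IGK-like locus with J segments in inverted orientation (inversional V-J)."""
    bp = LocusBlueprint(
        loci=[LocusSpec(name="IGK", n_v=2, n_d=0, n_j=2, invert_j=True,
                        spacing=700, margin=2000)],
        seed=5,
    )
    return build_synthetic_model(bp)


@pytest.fixture(scope="session")
def igh_baits(igh_model):
    return design_baits(igh_model)
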