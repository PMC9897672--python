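import numpy as np
import pytest

from tadbound.formats import ContactMatrix
from tadbound.synthetic import (
    BoundarySpec,
    DecayModel,
    TadLayout,
    evenly_spaced_layout,
    expected_matrix,
)


@pytest.fixture(scope="session")
def decay() -> DecayModel:
    return DecayModel()


@pytest.fixture(scope="session")
def two_tad_expected(decay) -> tuple[TadLayout, ContactMatrix]:
    """Noise-free matrix with one strong central boundary (two TADs)."""
    layout = TadLayout(chrom="chrT", bin_size=10_000, n_bins=120,
                       boundaries=(BoundarySpec(bin=60, strength=0.8),))
    return layout, expected_matrix(layout, decay)


@pytest.fixture(scope="session")
def ten_boundary_layout() -> TadLayout:
    return evenly_spaced_layout(n_boundaries=10, strength=0.7)


@pytest.fixture
def uniform_matrix() -> ContactMatrix:
    return ContactMatrix(chrom="chrU", bin_size=10_000,
                         counts=np.full((80, 80), 7.0))
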