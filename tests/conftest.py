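import numpy as np
import pytest

from sctsynth.nn import (DiscriminatorSpec, GeneratorSpec, PatchDiscriminator,
                         ProjectionHeads, ProjectionHeadSpec, ResnetGenerator)
from sctsynth.phantom import (PhantomSpec, generate_phantom_pair,
                              monotone_tissue_table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_gen_spec():
    return GeneratorSpec(base_filters=4, n_res_blocks=1, n_downsamples=2)


@pytest.fixture
def tiny_generator(tiny_gen_spec):
    return ResnetGenerator(tiny_gen_spec, rng=np.random.default_rng(7))


@pytest.fixture
def tiny_discriminator():
    return PatchDiscriminator(DiscriminatorSpec(base_filters=4),
                              rng=np.random.default_rng(8))


@pytest.fixture
def tiny_heads(tiny_gen_spec):
    return ProjectionHeads(tiny_gen_spec, ProjectionHeadSpec(hidden_dim=8, out_dim=8),
                           rng=np.random.default_rng(9))


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic default-table phantom subject."""
    spec = PhantomSpec(n_subjects=2, grid_shape=(16, 32, 32), seed=5)
    return generate_phantom_pair(spec, 0)


@pytest.fixture(scope="session")
def monotone_subjects():
    """Three monotone-mapping subjects (two train, one held out)."""
    spec = PhantomSpec(n_subjects=3, grid_shape=(16, 64, 64), seed=11,
                       tissue_table=tuple(monotone_tissue_table()),
                       require_contrast_inversion=False)
    return [generate_phantom_pair(spec, i) for i in range(3)]
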