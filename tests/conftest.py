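import pytest

from silkgene import synth
from silkgene.repeats import detect_repeats


@pytest.fixture(scope="session")
def full_scale_gene():
    """Full-architecture gene: 16 repeats (15 x 540 + 375), 993 nt terminals."""
    return synth.generate_gene(synth.full_scale_model(seed=1))


@pytest.fixture(scope="session")
def full_scale_decomposition(full_scale_gene):
    deco = detect_repeats(full_scale_gene.cds)
    assert deco is not None
    return deco


@pytest.fixture(scope="session")
def small_model():
    """Reduced architecture used where full scale adds nothing but time."""
    return synth.SpidroinModel(
        n_repeats=5, repeat_len_nt=120, nterm_len_nt=120, cterm_len_nt=120, seed=11
    )


@pytest.fixture(scope="session")
def small_gene(small_model):
    return synth.generate_gene(small_model)
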