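import pytest

from pharmflow.fixtures import make_reference_complex
from pharmflow.pharmacophore import build_receptor_model


@pytest.fixture(scope="session")
def ref():
    """The reference-mimic complex in a seed-1 rigid frame."""
    return make_reference_complex(seed=1)


@pytest.fixture(scope="session")
def model(ref):
    """Receptor-based model built from the reference complex."""
    return build_receptor_model(ref.protein, ref.ligand, [ref.water])
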