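import pytest

from mitocr.core import load_reference_annotation
from mitocr.synthetic import CRGeneratorConfig, generate_control_region, generate_repeat_array


@pytest.fixture(scope="session")
def reference_annotation():
    return load_reference_annotation()


@pytest.fixture(scope="session")
def default_repeat_array():
    """Paper-default synthetic tandem array (52 full 18-mers + 13-bp partial)."""
    return generate_repeat_array(CRGeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def default_control_region():
    """Paper-default synthetic control region with ground truth."""
    return generate_control_region(CRGeneratorConfig(), seed=1)
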