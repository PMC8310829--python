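import numpy as np
import pytest

from ovarisk.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def solid_case():
    return generate_phantom(
        PhantomSpec(mass_type="solid", malignant=True, shadow=False,
                    menopausal="pre", seed=101)
    )


@pytest.fixture(scope="session")
def cystic_case():
    return generate_phantom(
        PhantomSpec(mass_type="cystic", malignant=False, shadow=False,
                    menopausal="post", seed=102)
    )


@pytest.fixture(scope="session")
def mixed_case():
    return generate_phantom(
        PhantomSpec(mass_type="mixed", malignant=True, shadow=True,
                    menopausal="post", seed=103)
    )


@pytest.fixture()
def circle_contour():
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    return np.column_stack((64 + 40 * np.cos(theta), 64 + 40 * np.sin(theta)))
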