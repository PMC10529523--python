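import numpy as np
import pytest

from thyrotex.synthetic import NoduleSpec, make_default_suite, render_nodule


@pytest.fixture(scope="session")
def small_suite():
    """Six small phantoms with cystic fractions spanning 10-90%."""
    return make_default_suite(
        n_nodules=6, seed=7, image_shape=(192, 192),
        fractions=np.linspace(0.1, 0.9, 6),
    )


@pytest.fixture(scope="session")
def one_nodule():
    spec = NoduleSpec(center_px=(96, 96), axes_px=(60, 55),
                      cystic_fraction_true=0.30, seed=3)
    return render_nodule((192, 192), spec)
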