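import numpy as np
import pytest

from morphomil.datamodel import PatchBag


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def make_bag(rng, m=5, d_g=8, d_m=4, label=1, slide_id="S1", patient_id="P1",
             time_months=None, event=None):
    cols = max(int(np.ceil(np.sqrt(m))), 1)
    coords = np.stack([(np.arange(m) % cols) * 224,
                       (np.arange(m) // cols) * 224], axis=1)
    return PatchBag(
        slide_id=slide_id,
        patient_id=patient_id,
        coords=coords,
        generic_features=rng.standard_normal((m, d_g)).astype(np.float32),
        morph_features=rng.standard_normal((m, d_m)).astype(np.float32),
        label=label,
        time_months=time_months,
        event=event,
    )


@pytest.fixture
def small_bag(rng):
    return make_bag(rng)
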