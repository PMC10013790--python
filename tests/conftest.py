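import numpy as np
import pytest

from wheatseg import fieldsim, framestore
from wheatseg.cutouts import cut_fake_instances, extract_instances


@pytest.fixture(scope="session")
def field_spec():
    return fieldsim.FieldSpec(canvas=(64, 64), n_heads=5, minor_axis=(5, 7), major_axis=(8, 12), seed=0)


@pytest.fixture(scope="session")
def annotated_frame(field_spec):
    """One simulated wheat frame plus its exact instance masks."""
    frame, instances = fieldsim.make_field_frame(field_spec, seed=3)
    return frame, instances


@pytest.fixture(scope="session")
def banks(annotated_frame):
    """Real and cookie-cutter fake cutout banks from the annotated frame."""
    frame, instances = annotated_frame
    union = np.bitwise_or.reduce(np.stack(instances), axis=0)
    real = extract_instances(frame.image, instances, source_id="fix")
    fake = cut_fake_instances(
        frame.image, union, [c.footprint for c in real.cutouts], rng_seed=7, source_id="fix"
    )
    return real, fake


@pytest.fixture(scope="session")
def backgrounds(field_spec):
    spec = fieldsim.FieldSpec(canvas=(64, 64), background_rgb=(0.36, 0.33, 0.20), seed=0)
    return [
        framestore.Frame(index=i, image=fieldsim.make_background(spec, seed=100 + i).image, clip_id=f"bg-{i}")
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def tiny_net():
    from wheatseg.nn import ModelSpec, build_model

    return build_model(ModelSpec(encoder_name="tiny"), seed=0)
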