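import numpy as np
import pytest

from sspt.synthetic import SyntheticCrystalSpec, render_video


def small_spec(**overrides) -> SyntheticCrystalSpec:
    """A fast-rendering 64x64 spec with a centred square crystal."""
    base = dict(
        image_height_px=64,
        image_width_px=64,
        crystal_polygon=[(8.0, 8.0), (8.0, 56.0), (56.0, 56.0), (56.0, 8.0)],
        duration_s=120.0,
        t1_mean_s=58.0,
        noise_sd=0.0,
        shoulder_fraction=0.0,
        seed=0,
    )
    base.update(overrides)
    return SyntheticCrystalSpec(**base)


@pytest.fixture(scope="session")
def clean_stack_and_field():
    """Noiseless, shoulder-free stack with a constant T1 field (58 s)."""
    return render_video(small_spec())


@pytest.fixture(scope="session")
def study_stack_and_field():
    """Study-condition stack: noise sd 2, shoulder 0.2, smooth T1 variation."""
    spec = SyntheticCrystalSpec(
        duration_s=240.0,
        t1_mean_s=75.0,
        t1_noise_sd_s=2.0,
        noise_sd=2.0,
        seed=11,
    )
    return render_video(spec)
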