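import numpy as np
import pytest

from hemocount import (
    HemocyteCounter,
    RGBImage,
    SyntheticSpec,
    generate_training_set,
)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Smaller field for fast unit tests; same appearance model."""
    return SyntheticSpec(
        shape=(144, 144),
        nucleus_count=6,
        fiber_count=2,
        fiber_length=(30, 60),
        hemocyte_lambda=3.0,
    )


@pytest.fixture(scope="session")
def trained_counter(small_spec) -> HemocyteCounter:
    """Counter calibrated once on small synthetic training fields."""
    images, annots, _ = generate_training_set(
        small_spec, n_images=6, cells_per_image=4, seed=42
    )
    return HemocyteCounter(selected_pc="auto").fit(images, annots)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_image(rng: np.random.Generator, h: int = 12, w: int = 12) -> RGBImage:
    return RGBImage(
        pixels=rng.integers(0, 256, (h, w, 3), dtype=np.uint8).astype(np.uint8),
        id="random",
    )
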