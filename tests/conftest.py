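import numpy as np
import pytest

from steatox.synth import (ChemicalProfile, CurveParams, ImageSceneSpec,
                           generate_image_scene)

EIGHT_POINT_SERIES = tuple(np.geomspace(1.0, 1000.0, 8))


@pytest.fixture(scope="session")
def oa_pa_profile():
    """A 2.3-fold lipid-accumulation inducer with inflection at 100 uM."""
    return ChemicalProfile(
        "oa_pa",
        {"lipid_accumulation": CurveParams(b=-1.0, c=1.0, d=2.3, e=100.0)},
        EIGHT_POINT_SERIES,
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 12-hepatocyte field with known truth."""
    return generate_image_scene(ImageSceneSpec(n_hepatocytes=12, seed=3))
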