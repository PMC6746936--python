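import numpy as np
import pytest

from dxafem.io import PatientBundle
from dxafem.model import FemurFallModel
from dxafem.phantom import FemurShapeParams, generate_femur_image

DEFAULT_META = {
    "height_m": 1.6,
    "weight_kg": 70.0,
    "t_score": -1.5,
    "spacing_mm": 0.5,
}


def make_bundle(seed=1, noise_sd=0.0, params=None, meta=None, **kwargs):
    image, masks, truth = generate_femur_image(
        params or FemurShapeParams(), noise_sd=noise_sd, seed=seed, **kwargs
    )
    return (
        PatientBundle(
            patient_id=f"phantom_{seed}",
            image=image,
            femur_mask=masks["femur"],
            labels=masks["labels"],
            roi_means=truth.roi_mean_bmd,
            metadata=dict(meta or DEFAULT_META),
            hsa=truth.hsa_row,
        ),
        masks,
        truth,
    )


@pytest.fixture(scope="session")
def phantom_noiseless():
    """One noiseless default phantom: (bundle, masks, truth)."""
    return make_bundle(seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def fitted(phantom_noiseless):
    """A fitted fall model on the noiseless phantom (expensive, shared)."""
    bundle, _, _ = phantom_noiseless
    return FemurFallModel(bundle).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
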