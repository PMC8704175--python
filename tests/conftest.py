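import numpy as np
import pytest

from segeval.geometry import Mask3D
from segeval.metrics import dsc
from segeval.phantoms import PhantomConfig, generate_phantom_cohort
from segeval.wunet import WUNet, WUNetConfig


def random_mask(rng: np.random.Generator, shape=(4, 8, 8), p=0.3, spacing=(2.0, 1.0, 1.0)):
    vox = (rng.random(shape) < p).astype(np.uint8)
    if not vox.any():
        vox[tuple(s // 2 for s in shape)] = 1
    return Mask3D(vox, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_benchmark():
    """Full desk-scale training run under the benchmark study conditions:
    depth-3, base-16 weighted-dense-skip U-Net, 40 seeded 64x64 phantom
    slices, 50 epochs, lowest-validation-loss checkpoint. Shared across
    tests because the run takes minutes."""
    train_cases = generate_phantom_cohort(
        PhantomConfig(n_patients=40, slices_per_patient=1, seed=101)
    )
    test_cases = generate_phantom_cohort(
        PhantomConfig(n_patients=10, slices_per_patient=1, seed=102)
    )
    dataset = [
        (sl, msk) for c in train_cases for sl, msk in zip(c.images, c.mask.voxels)
    ]
    model = WUNet(WUNetConfig(depth=3, base_channels=16, input_size=(64, 64)), seed=7)
    result = model.fit(dataset, epochs=50, seed=7, batch_size=8)
    return {
        "model": model,
        "result": result,
        "test_cases": test_cases,
    }


def heldout_dsc_values(model, test_cases, backbone_only=False):
    out = []
    for case in test_cases:
        if backbone_only:
            probs = model.forward(case.images[:, None], backbone_only=True)[:, 0]
            vox = (probs >= 0.5).astype(np.uint8)
            pred = Mask3D(vox, case.mask.spacing)
        else:
            pred = model.predict_stack(case.images, spacing=case.mask.spacing)
        out.append(dsc(case.mask, pred))
    return out
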