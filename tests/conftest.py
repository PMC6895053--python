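import numpy as np
import pytest


from emomap.studies import default_latent_spec, make_group_dimensions
from emomap.synthetic import PlantedGradientSpec, gen_voxel_roi

SEED = 7


@pytest.fixture(scope="session")
def latent_spec():
    return default_latent_spec()


@pytest.fixture(scope="session")
def small_panel(latent_spec):
    """12 raters x 400 TRs sharing three smooth latents."""
    panel, group, dims, design, gt = make_group_dimensions(
        SEED, n_subjects=12, n_timepoints=400
    )
    return {
        "panel": panel,
        "group": group,
        "dims": dims,
        "design": design,
        "ground_truth": gt,
    }


@pytest.fixture(scope="session")
def planted_roi():
    """15 mm ROI on a 3 mm grid with three orthogonal noiseless gradients."""
    spec = PlantedGradientSpec(
        directions=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        slopes=(1.0, 1.0, 1.0),
        offsets=(0.0, 0.0, 0.0),
    )
    roi, beta, gt = gen_voxel_roi(np.zeros(3), 15.0, 3.0, spec, seed=SEED)
    return {"roi": roi, "beta": beta, "spec": spec}


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def ar1_series(rng, t, phi=0.8, n=1):
    eps = rng.standard_normal((t, n))
    z = np.empty((t, n))
    z[0] = eps[0]
    c = np.sqrt(1 - phi**2)
    for i in range(1, t):
        z[i] = phi * z[i - 1] + c * eps[i]
    return z if n > 1 else z[:, 0]
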