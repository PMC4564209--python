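"""Shared fixtures: seeded phantoms and the two expensive registration runs.

The affine and deformable registration runs are session-scoped so the
parameter-recovery, trace-monotonicity and overlap-improvement checks all
reuse a single computation.
"""

import numpy as np
import pytest

from coralign.affine_register import SearchConfig, register_affine
from coralign.evaluation import mad
from coralign.phantom import (
    PhantomSpec,
    apply_known_affine,
    apply_known_deformation,
    make_phantom,
)
from coralign.symmetric_cc_register import SymConfig, register_symmetric
from coralign.volume_io import Volume

# phantom tissue contrast is max(means) - min(means) = 150 - 45 = 105;
# simulated noise is 2% of that
NOISE_SD = 0.02 * 105.0
TRUE_TRANSLATION = (5.0, -3.0, 2.0)   # mm
TRUE_ROTATION_DEG = 7.0               # about z


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_volume(rng, shape, spacing=(1.0, 1.0, 1.0)):
    return Volume(rng.normal(size=shape), spacing, (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def affine_case():
    """64^3 rigid-motion phantom registered back with the full pipeline."""
    spec = PhantomSpec(size=(64, 64, 64), noise_sd=NOISE_SD, seed=7)
    vol, lab = make_phantom(spec)
    params = np.zeros(12)
    params[6:9] = 1.0
    params[:3] = TRUE_TRANSLATION
    params[5] = np.deg2rad(TRUE_ROTATION_DEG)
    moved, moved_lab, t_gt = apply_known_affine(vol, lab, params)
    recovered, trace = register_affine(vol, moved, SearchConfig(dof=6))
    rec_params = recovered.to_params(center=vol.center_world)
    return {
        "volume": vol,
        "labels": lab,
        "moved": moved,
        "moved_labels": moved_lab,
        "true_params": params,
        "t_gt": t_gt,
        "recovered": recovered,
        "recovered_params": rec_params,
        "trace": trace,
    }


@pytest.fixture(scope="session")
def deform_case():
    """40^3 phantom under a known smooth warp, refined symmetrically."""
    spec = PhantomSpec(size=(40, 40, 40), noise_sd=NOISE_SD, seed=3)
    vol, lab = make_phantom(spec)
    moved, moved_lab, gt_field = apply_known_deformation(
        vol, lab, amplitude_mm=3.0, smoothness_mm=8.0, seed=3
    )
    config = SymConfig(radius=3, iterations=40)
    phi1, phi2, warped, trace = register_symmetric(vol, moved, config=config)
    return {
        "volume": vol,
        "labels": lab,
        "moved": moved,
        "moved_labels": moved_lab,
        "gt_field": gt_field,
        "phi1": phi1,
        "phi2": phi2,
        "warped": warped,
        "trace": trace,
        "mad_before": mad(vol, moved),
        "mad_after": mad(vol, warped),
        "config": config,
    }
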