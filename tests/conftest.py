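"""Shared fixtures.

Heavy artifacts (the clean phantom subject, the demons registration of it,
the trained desk-scale U-net) are session-scoped and shared between the
module tests and the acceptance tests so each expensive computation runs
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from ventimap.phantom import PhantomSpec, make_cohort, make_subject
from ventimap.registration import RegistrationParams, demons_register


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Default phantom geometry without stochastic corruption."""
    return PhantomSpec(noise_sd=0.0, shading_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_subject(clean_spec):
    """Noiseless default subject with analytic truth."""
    return make_subject(clean_spec, "clean")


@pytest.fixture(scope="session")
def notexture_subject():
    """Noiseless subject with spatially uniform lung density (no vascular
    texture), where the density-change and Jacobian estimators coincide
    analytically."""
    return make_subject(
        PhantomSpec(noise_sd=0.0, shading_amplitude=0.0, texture_amplitude=0.0),
        "notexture",
    )


@pytest.fixture(scope="session")
def demons_result(clean_subject):
    """Demons registration of the clean subject's T50/T00 pair (default params)."""
    return demons_register(
        clean_subject.series.exhale, clean_subject.series.inhale, RegistrationParams()
    )


def dl_base_spec() -> PhantomSpec:
    """Phantom geometry for the learned-regressor experiments: 2 mm in-plane
    (lungs well-resolved inside the 64-voxel crop), 4 mm slices, uniform
    lung density (no vascular texture, whose out-of-plane advection no
    2-D slice model can resolve)."""
    return PhantomSpec(
        shape=(96, 96, 32),
        spacing=(2.0, 2.0, 4.0),
        texture_amplitude=0.0,
        lung_centers=((60.0, 92.0, 62.0), (130.0, 92.0, 62.0)),
        lung_semiaxes=((25.0, 40.0, 38.0), (25.0, 40.0, 38.0)),
    )


@pytest.fixture(scope="session")
def dl_cohort():
    """Eight-subject cohort for the train/test experiment (6 train, 2 test)."""
    return make_cohort(8, base_spec=dl_base_spec(), seed=11)


@pytest.fixture(scope="session")
def dl_model_config():
    from ventimap.dlmodel import ModelConfig

    return ModelConfig(
        input_mode="phases2", in_plane_size=64, depth=3, base_filters=8, dropout_rate=0.0
    )


def dl_train_config():
    """Desk-scale schedule: augmentation shift scaled to the 64-voxel field
    of view (3 px ~ 5% of the in-plane size, the fraction a 10 px shift is
    of a 192-voxel plane)."""
    from ventimap.dlmodel import TrainConfig

    return TrainConfig(max_epochs=150, seed=3, augment_shift_px=3.0)


@pytest.fixture(scope="session")
def overfit_history(dl_cohort, dl_model_config):
    """Memorization run: 8 phantom slices as both train and validation."""
    from ventimap.dlmodel import TrainConfig, build_unet, make_samples, train

    samples = make_samples([dl_cohort[0]], dl_model_config)[4:12]
    net = build_unet(dl_model_config, seed=4)
    cfg = TrainConfig(max_epochs=200, seed=7, augment_flip=False,
                      augment_rotate_deg=0, augment_scale=0, augment_shift_px=0)
    _, history = train(samples, net, cfg, val_samples=samples)
    return history


@pytest.fixture(scope="session")
def dl_trained(dl_cohort, dl_model_config):
    """U-net trained on the first six cohort subjects (desk scale)."""
    from ventimap.dlmodel import build_unet, make_samples, train

    samples = make_samples(dl_cohort[:6], dl_model_config)
    model = build_unet(dl_model_config, seed=2)
    model, history = train(samples, model, dl_train_config())
    return model, history
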