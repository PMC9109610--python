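"""Train the U-net phase-stack regressor on a small phantom cohort.

Six subjects train (with an internal subject-level validation split), two
are held out; predictions are compared against the phantom truth.  This is
the desk-scale configuration (64x64 slices, depth 3, 8 base filters); it
takes a few minutes on one CPU.
"""

import numpy as np

from ventimap.dlmodel import (
    ModelConfig,
    TrainConfig,
    build_unet,
    make_samples,
    predict_volume,
    train,
)
from ventimap.evaluation import spearman_masked
from ventimap.phantom import PhantomSpec, make_cohort

base = PhantomSpec(
    shape=(96, 96, 32), spacing=(2.0, 2.0, 4.0), texture_amplitude=0.0,
    lung_centers=((60.0, 92.0, 62.0), (130.0, 92.0, 62.0)),
    lung_semiaxes=((25.0, 40.0, 38.0), (25.0, 40.0, 38.0)),
)
cohort = make_cohort(8, base_spec=base, seed=11)

config = ModelConfig(input_mode="phases2", in_plane_size=64, depth=3,
                     base_filters=8, dropout_rate=0.0)
samples = make_samples(cohort[:6], config)
print(f"training on {len(samples)} slices from 6 subjects "
      f"({config.n_channels} channels each)")

model = build_unet(config, seed=2)
model, history = train(samples, model,
                       TrainConfig(max_epochs=150, seed=3, augment_shift_px=3.0))
print(f"stopped after {len(history)} epochs; best validation MSE "
      f"{history.val_loss.min():.4f} at epoch {history.attrs['best_epoch']}")

rs = []
for subject in cohort[6:]:
    vi = predict_volume(model, subject, config, filter_size=1)
    r = spearman_masked(vi, subject.true_ventilation, subject.exhale_mask)
    rs.append(r)
    print(f"held-out {subject.subject_id}: rs(prediction, truth) = {r:.3f}")
print(f"mean held-out correlation: {np.mean(rs):.3f}")
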