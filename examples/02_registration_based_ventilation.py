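"""Demons registration and the two registration-based ventilation estimators.

Registers peak exhale (fixed) to peak inhale (moving), derives the
density-change (HU) and Jacobian (JAC) ventilation maps, and compares both
— plus the maps computed from the analytic true field — against the
phantom's ground truth with masked Spearman correlation.
"""

import numpy as np

from ventimap.evaluation import spearman_masked
from ventimap.phantom import PhantomSpec, make_subject
from ventimap.registration import RegistrationParams, demons_register
from ventimap.ventilation import ventilation_density_change, ventilation_jacobian

subject = make_subject(PhantomSpec(noise_sd=0.0, shading_amplitude=0.0))
mask = subject.exhale_mask

dvf = demons_register(subject.series.exhale, subject.series.inhale, RegistrationParams())
epe = np.sqrt(((dvf.u - subject.true_dvf.u) ** 2).sum(axis=0))[mask.values]
print(f"demons mean endpoint error:   {epe.mean():.2f} mm (voxel = 2 mm)")

for name, field in (("true field", subject.true_dvf), ("demons field", dvf)):
    vi_jac = ventilation_jacobian(field, mask)
    vi_hu = ventilation_density_change(
        subject.series.inhale, subject.series.exhale, field, mask
    )
    rs_jac = spearman_masked(vi_jac, subject.true_ventilation, mask)
    rs_hu = spearman_masked(vi_hu, subject.true_ventilation, mask)
    print(f"{name:13s} rs(JAC, truth) = {rs_jac:+.3f}   rs(HU, truth) = {rs_hu:+.3f}")

print(
    "\nWith the true field both estimators track truth almost perfectly; with an\n"
    "estimated field the Jacobian differentiates registration error, and the\n"
    "voxel-wise correlation collapses even at sub-voxel accuracy — the classic\n"
    "weakness of registration-based ventilation."
)
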