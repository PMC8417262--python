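"""Build a synthetic head phantom and its ground-truth brain-shift field.

The phantom is an ellipsoidal intracranial cavity (maximum cranial
breadth 137 mm, antero-posterior diameter 176 mm) inside a rigid
high-intensity skull shell, with textured tissue and embedded deep-brain
structures. The shift field emulates positional brain shift between
prone and supine: dominant posterior translation, a small sagittal
rotation about an inferior pivot, a leftward component, and anterior
expansion/posterior compression, all damped to zero at the skull and at
the falx/tentorium membranes.
"""

import numpy as np

from pbshift.cohortstats import to_spherical
from pbshift.synthcohort import PBSFieldSpec, PhantomSpec, generate_phantom, generate_pbs_field
from pbshift.volio import roi_mask

vol, skull, brain, atlas = generate_phantom(PhantomSpec())
field = generate_pbs_field(PBSFieldSpec(), brain)

mags = np.linalg.norm(field.vectors[brain.data], axis=-1)
mean_vec = field.vectors[brain.data].mean(axis=0)
sph = to_spherical(mean_vec)

print(f"grid: {vol.shape} voxels at {vol.spacing[0]:.1f} mm")
print(f"brain voxels: {int(brain.data.sum())}")
print(f"mean |u| over brain: {mags.mean():.3f} mm (calibrated to 0.57)")
print(f"mean components (L-R, P-A, I-S): "
      f"({mean_vec[0]:+.3f}, {mean_vec[1]:+.3f}, {mean_vec[2]:+.3f}) mm")
print(f"mean-vector azimuth {sph.azimuth:.1f} deg (posterior-left), "
      f"elevation {sph.elevation:.1f} deg")

deep = roi_mask(atlas, ["T", "Put", "Pall"]).data
gm = roi_mask(atlas, "GM").data
mag_map = np.linalg.norm(field.vectors, axis=-1)
print(f"deep-nucleus mean |u|: {mag_map[deep].mean():.3f} mm vs "
      f"cortical {mag_map[gm].mean():.3f} mm (shift is larger away from "
      f"anatomical boundaries)")
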