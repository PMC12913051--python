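"""Quantify perfusion and arterial arrival time from synthetic multi-PLD pCASL.

Generates a small volume with known CBF/AAT maps, fits the single-compartment
kinetic model voxel by voxel, applies the R^2 > 0.6 quality gate and prints
global summaries next to the ground truth.
"""

import numpy as np

from cyclovasc import asl
from cyclovasc.synthetic import default_asl_truth, gen_asl_dataset

truth = default_asl_truth(shape=(8, 8, 2), noise_sd=0.5, seed=0)
schedule = asl.default_schedule()
series, _ = gen_asl_dataset(truth, schedule)

# CSF reference chosen so the derived blood M0 equals the generator's
unit = asl.M0Calibration(m0_csf=1.0)
cal = asl.M0Calibration(m0_csf=truth.m0_blood / unit.m0_blood)

fits = asl.fit_kinetic(series, cal)
gm_cbf, gm_aat = asl.global_summary(fits)

print(f"voxels fitted: {fits.f.size}, passed R^2 > 0.6: {fits.passed.sum()}")
print(f"global perfusion: {gm_cbf:6.2f} ml/100g/min "
      f"(truth mean {truth.cbf_map.mean():6.2f})")
print(f"global AAT:       {gm_aat:6.3f} s "
      f"(truth mean {truth.aat_map.mean():6.3f})")
print(f"median |f error|: "
      f"{np.median(np.abs(fits.f - truth.cbf_map)):.2f} ml/100g/min")
# the global means should track the truth within the noise level; each
# voxel's fit recovers its own (f, aat) pair from 12 post-labelling delays
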