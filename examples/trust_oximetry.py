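"""Venous oximetry from a synthetic TRUST decay curve.

Forward-generates a mono-exponential decay for a known venous saturation,
fits blood T2, inverts the T2-oxygenation calibration and prints OEF and
CMRO2 alongside the generating truth.
"""

from cyclovasc import trust
from cyclovasc.synthetic import gen_trust_curve

yv_true, hb, gm_cbf = 0.62, 13.5, 52.0
t2_true = trust.t2_from_yv(yv_true, hct=hb / 34.0)
sample = gen_trust_curve(t2_true, s0=100.0, noise_sd=5.0, n_averages=3,
                         seed=1)

result = trust.oximetry_from_sample(sample, gm_cbf=gm_cbf, hb=hb)
oef_true = (0.98 - yv_true) / 0.98

print(f"true T2 {t2_true * 1e3:5.1f} ms -> fitted {result.t2_blood * 1e3:5.1f} ms")
print(f"true Yv {yv_true:.3f} -> estimated {result.yv:.3f}")
print(f"OEF: {result.oef:.3f} (truth {oef_true:.3f})")
print(f"CMRO2 (printed-formula units): {result.cmro2:.0f}")
# OEF is the fraction of delivered arterial oxygen extracted by the brain;
# CMRO2 multiplies it by perfusion and arterial oxygen content
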