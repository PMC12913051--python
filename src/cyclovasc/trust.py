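"""TRUST venous oximetry: blood T2 -> venous saturation -> OEF -> CMRO2.

T2-relaxation-under-spin-tagging (TRUST) isolates pure venous blood
signal in the sagittal sinus; its mono-exponential decay across effective
echo times yields venous blood T2.  T2 is converted to venous oxygen
saturation (Yv) by inverting an in-vitro calibration in which the blood
relaxation rate 1/T2 is quadratic in (1 - Yv) with haematocrit-dependent
coefficients.  Oxygen extraction fraction follows as
``OEF = (SaO2 - Yv)/SaO2`` and the cerebral metabolic rate of oxygen as
the product of grey-matter perfusion and the arterial oxygen content
term.

The CMRO2 arithmetic is implemented exactly as printed in the source
protocol, where the "CaO2" term folds OEF and the 39.34 µmol/ml O2
conversion into one factor::

    CaO2_term = (Hb * 1.34 * SaO2) * OEF * 39.34
    CMRO2     = gmCBF * CaO2_term

With Hb in g/dL this leaves a factor-100 (dL -> ml) offset versus the
conventional decomposition; ``convention="standard"`` applies the /100
so that CMRO2 comes out in µmol/100 g/min.  See docs/methods.md.

A haemoglobin pathway from an inversion-recovery T1 measurement of
venous blood is included: Hb is linear in the relaxation rate 1/T1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "TrustSample",
    "OximetryResult",
    "T2YvCalibration",
    "HB_FROM_T1_DEFAULT",
    "select_sinus_signal",
    "fit_t2",
    "fit_t1_ir",
    "hb_from_t1",
    "yv_from_t2",
    "t2_from_yv",
    "oef",
    "cmro2",
]


@dataclass(frozen=True)
class TrustSample:
    """Difference-signal amplitudes at each effective echo time (ms)."""

    etes: tuple[float, ...]
    signals: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.etes) != len(self.signals):
            raise ValueError("etes and signals must have equal length")
        if any(e < 0 for e in self.etes):
            raise ValueError("effective echo times must be non-negative")


@dataclass
class OximetryResult:
    """Oximetry chain outputs for one session."""

    t2_blood: float      # s
    yv: float            # venous saturation, [0, 1]
    sao2: float          # arterial saturation, [0, 1]
    hb: float            # g/dL
    oef: float
    cao2_term: float     # printed definition (folds OEF and 39.34)
    cmro2: float

    def __post_init__(self) -> None:
        if not 0 <= self.yv <= self.sao2 <= 1:
            warnings.warn(
                f"non-physiological saturations: Yv={self.yv:.3f}, "
                f"SaO2={self.sao2:.3f}", stacklevel=2)


def select_sinus_signal(volume_series: np.ndarray, roi: np.ndarray,
                        etes: tuple[float, ...] = (0.0, 40.0, 80.0, 160.0),
                        ) -> TrustSample:
    """Average of the two most intense ROI voxels at every echo time.

    ``volume_series`` has shape ``(n_etes,) + spatial`` ordered like
    ``etes`` (ms, eTE = 0 first); the two voxels are chosen by intensity
    in the eTE = 0 image and the same two voxels are averaged at every
    echo time.
    """
    vols = np.asarray(volume_series, dtype=float)
    if vols.shape[0] != len(etes):
        raise ValueError("volume count must match the echo-time list")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vols.shape[1:]:
        raise ValueError("ROI shape must match the spatial volume shape")
    n_roi = int(roi.sum())
    if n_roi < 2:
        raise ValueError(f"ROI must contain at least 2 voxels, has {n_roi}")
    base = vols[0][roi]
    top2 = np.argsort(base)[-2:]
    sig = vols[:, roi][:, top2].mean(axis=1)
    return TrustSample(etes=tuple(etes), signals=tuple(sig))


def fit_t2(sample: TrustSample) -> tuple[float, float]:
    """Mono-exponential least-squares fit ``s0 * exp(-eTE / T2)``.

    Returns ``(t2_s, s0)`` with T2 in seconds (echo times are in ms).
    Non-decaying data produce a warning; flat data return T2 = inf
    (non-physiological, flagged by the warning).
    """
    ete = np.asarray(sample.etes, dtype=float)
    sig = np.asarray(sample.signals, dtype=float)
    if len(np.unique(ete)) < 3:
        raise ValueError("need at least 3 distinct echo times")

    # log-linear seed from the positive samples (noise can push the
    # longest echoes negative); fall back to a nominal venous T2
    pos = sig > 0
    if pos.sum() >= 2 and len(np.unique(ete[pos])) >= 2:
        slope, intercept = np.polyfit(ete[pos], np.log(sig[pos]), 1)
        if slope >= -1e-12:
            warnings.warn("signal does not decay with echo time; "
                          "fitted T2 is non-physiological", stacklevel=2)
            if abs(slope) <= 1e-12:     # flat signal: T2 -> infinity
                return np.inf, float(np.exp(intercept))
        p0 = (float(np.exp(intercept)), -1.0 / slope)
    else:
        p0 = (float(sig.max()), 60.0)
    popt, _ = curve_fit(lambda t, s0, t2: s0 * np.exp(-t / t2), ete, sig,
                        p0=p0, maxfev=10000)
    s0, t2_ms = popt
    return float(t2_ms) / 1e3, float(s0)


def _ir_model(ti, a, b, t1):
    return np.abs(a - b * np.exp(-ti / t1))


def fit_t1_ir(ti_values: np.ndarray, signals: np.ndarray) -> float:
    """Venous-blood T1 from a magnitude inversion-recovery series.

    Fits ``|A - B exp(-TI/T1)|`` (TI in ms) by least squares.  Returns T1
    in seconds.  The series should bracket the signal null; otherwise a
    warning is issued and the fit is still attempted.
    """
    ti = np.asarray(ti_values, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if ti.size < 4:
        raise ValueError("need at least 4 inversion times")
    i_min = int(np.argmin(sig))
    if i_min in (0, ti.size - 1):
        warnings.warn("inversion-recovery series does not bracket the "
                      "signal null; T1 may be poorly conditioned",
                      stacklevel=2)
    a0 = float(np.max(sig))
    b0 = 2.0 * a0
    t1_0 = max(ti[i_min] / np.log(2.0), ti[1])
    popt, _ = curve_fit(_ir_model, ti, sig, p0=(a0, b0, t1_0), maxfev=20000)
    return float(popt[2]) / 1e3


#: Hb (g/dL) = c0 + c1 / T1 (s); derived from the linear venous-blood
#: relaxometry calibration 1/T1 = 0.52*Hct + 0.38 (s^-1) with Hct = Hb/34.
HB_FROM_T1_DEFAULT: tuple[float, float] = (-0.38 * 34.0 / 0.52, 34.0 / 0.52)


def hb_from_t1(t1_blood: float,
               calibration_coefficients: tuple[float, float] | None = None,
               *, strict: bool = False) -> float:
    """Haemoglobin (g/dL) from venous-blood T1 (s): ``c0 + c1 / T1``.

    In strict mode the calibration must be supplied explicitly; the
    default coefficients otherwise follow the linear 1/T1–haematocrit
    relaxometry calibration (see module docstring).
    """
    if t1_blood <= 0:
        raise ValueError("T1 must be positive")
    if calibration_coefficients is None:
        if strict:
            raise ValueError(
                "strict mode: Hb-from-T1 calibration coefficients must be "
                "supplied explicitly (no silent default)")
        calibration_coefficients = HB_FROM_T1_DEFAULT
    c0, c1 = calibration_coefficients
    return c0 + c1 / t1_blood


@dataclass(frozen=True)
class T2YvCalibration:
    """Quadratic blood T2–oxygenation calibration.

    ``1/T2 = A(Hct) + B(Hct)*(1-Yv) + C(Hct)*(1-Yv)^2`` in s^-1, with the
    in-vitro bovine-blood coefficients for a 10 ms refocusing interval::

        A = a1 + a2*Hct + a3*Hct^2
        B = b1*Hct + b2*Hct^2
        C = c1*Hct*(1 - Hct)
    """

    a: tuple[float, float, float] = (-13.5, 80.2, -75.9)
    b: tuple[float, float] = (-0.5, 3.4)
    c: float = 247.4

    def coefficients(self, hct: float) -> tuple[float, float, float]:
        if not 0 < hct < 1:
            raise ValueError("haematocrit must be a fraction in (0, 1)")
        a1, a2, a3 = self.a
        b1, b2 = self.b
        A = a1 + a2 * hct + a3 * hct ** 2
        B = b1 * hct + b2 * hct ** 2
        C = self.c * hct * (1.0 - hct)
        return A, B, C

    def r2_of_yv(self, yv, hct: float):
        A, B, C = self.coefficients(hct)
        one_minus = 1.0 - np.asarray(yv, dtype=float)
        return A + B * one_minus + C * one_minus ** 2


def t2_from_yv(yv: float, hct: float,
               calibration: T2YvCalibration | None = None) -> float:
    """Forward calibration: blood T2 (s) at venous saturation ``yv``."""
    cal = calibration or T2YvCalibration()
    r2 = float(cal.r2_of_yv(yv, hct))
    if r2 <= 0:
        raise ValueError("calibration yields non-positive relaxation rate")
    return 1.0 / r2


def yv_from_t2(t2_blood: float, hct: float,
               calibration: T2YvCalibration | None = None) -> float:
    """Invert the T2–oxygenation calibration on Yv in [0, 1].

    The quadratic has B, C >= 0 over the physiological haematocrit range,
    so 1/T2 decreases monotonically in Yv and the root in [0, 1] is
    unique (the physiological branch).
    """
    if t2_blood <= 0:
        raise ValueError("T2 must be positive")
    cal = calibration or T2YvCalibration()
    target = 1.0 / t2_blood

    def g(yv: float) -> float:
        return float(cal.r2_of_yv(yv, hct)) - target

    g0, g1 = g(0.0), g(1.0)
    if g0 * g1 > 0:
        t2_lo = 1.0 / float(cal.r2_of_yv(0.0, hct))
        t2_hi = 1.0 / float(cal.r2_of_yv(1.0, hct))
        raise ValueError(
            f"T2 = {t2_blood * 1e3:.1f} ms outside the calibrated range "
            f"[{t2_lo * 1e3:.1f}, {t2_hi * 1e3:.1f}] ms for Hct = {hct:.2f}")
    return float(brentq(g, 0.0, 1.0, xtol=1e-12))


def oef(sao2: float, yv: float) -> float:
    """Oxygen extraction fraction ``(SaO2 - Yv) / SaO2``."""
    if not 0 < sao2 <= 1:
        raise ValueError("SaO2 must be in (0, 1]")
    if not 0 <= yv <= 1:
        raise ValueError("Yv must be in [0, 1]")
    val = (sao2 - yv) / sao2
    if val < 0:
        warnings.warn("Yv exceeds SaO2: negative OEF returned", stacklevel=2)
    return val


def cmro2(gm_cbf: float, hb: float, sao2: float, oef_value: float,
          convention: str = "printed") -> tuple[float, float]:
    """CMRO2 from grey-matter perfusion and the arterial oxygen term.

    Returns ``(cmro2, cao2_term)``.  ``convention="printed"`` evaluates
    the protocol's expression literally (Hb in g/dL, no dL->ml factor);
    ``"standard"`` divides the oxygen content by 100 so that with gm_cbf
    in ml/100 g/min the result is in µmol O2/100 g/min.
    """
    if min(gm_cbf, hb, sao2) < 0:
        raise ValueError("inputs must be non-negative")
    cao2_term = (hb * 1.34 * sao2) * oef_value * 39.34
    if convention == "standard":
        cao2_term /= 100.0
    elif convention != "printed":
        raise ValueError(f"unknown convention: {convention!r}")
    return gm_cbf * cao2_term, cao2_term


def oximetry_from_sample(sample: TrustSample, gm_cbf: float,
                         hb: float | None = None,
                         t1_blood: float | None = None,
                         sao2: float = 0.98,
                         hb_coefficients: tuple[float, float] | None = None,
                         calibration: T2YvCalibration | None = None,
                         hct_per_hb: float = 1.0 / 34.0,
                         convention: str = "printed",
                         strict: bool = False) -> OximetryResult:
    """Full oximetry chain for one session.

    Haemoglobin may be given directly or derived from a venous T1; the
    haematocrit entering the T2 calibration is ``hb * hct_per_hb``.
    """
    if hb is None:
        if t1_blood is None:
            raise ValueError("supply either hb or a venous-blood T1")
        hb = hb_from_t1(t1_blood, hb_coefficients, strict=strict)
    t2_s, _ = fit_t2(sample)
    yv = yv_from_t2(t2_s, hct=hb * hct_per_hb, calibration=calibration)
    oef_val = oef(sao2, yv)
    cmro2_val, cao2_term = cmro2(gm_cbf, hb, sao2, oef_val, convention)
    return OximetryResult(t2_blood=t2_s, yv=yv, sao2=sao2, hb=hb,
                          oef=oef_val, cao2_term=cao2_term, cmro2=cmro2_val)
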