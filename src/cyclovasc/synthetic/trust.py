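"""Mono-exponential TRUST and inversion-recovery curve generators."""

from __future__ import annotations

import numpy as np

from ..trust import TrustSample

__all__ = ["gen_trust_curve", "gen_ir_curve", "gen_sinus_volumes"]

PROTOCOL_ETES_MS = (0.0, 40.0, 80.0, 160.0)


def gen_trust_curve(t2b_true: float, s0: float = 100.0,
                    etes: tuple[float, ...] = PROTOCOL_ETES_MS,
                    noise_sd: float = 0.0, seed: int = 0,
                    n_averages: int = 1) -> TrustSample:
    """Sample ``s0 * exp(-eTE / T2)`` (+ Gaussian noise) at each echo time.

    ``t2b_true`` is in seconds; echo times in ms.  ``noise_sd`` is the
    per-acquisition noise; a TRUST session conventionally acquires
    several label/control repeats per echo time and fits their averaged
    difference curve, so with ``n_averages`` repeats the sampled curve
    carries noise ``noise_sd / sqrt(n_averages)``.
    """
    if t2b_true <= 0:
        raise ValueError("true T2 must be positive")
    if any(e < 0 for e in etes):
        raise ValueError("echo times must be non-negative")
    if n_averages < 1:
        raise ValueError("n_averages must be at least 1")
    rng = np.random.default_rng(seed)
    ete = np.asarray(etes, dtype=float)
    sig = s0 * np.exp(-ete / (t2b_true * 1e3))
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd / np.sqrt(n_averages), sig.shape)
    return TrustSample(etes=tuple(ete), signals=tuple(sig))


def gen_ir_curve(t1_true: float, a: float = 100.0, b: float = 200.0,
                 tis: np.ndarray | None = None, noise_sd: float = 0.0,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude inversion-recovery series ``|A - B exp(-TI/T1)|``.

    ``t1_true`` in seconds, inversion times in ms (default 150 ms steps
    spanning 150-3600 ms, bracketing the null for physiological T1).
    Returns ``(tis_ms, signals)``.
    """
    if t1_true <= 0:
        raise ValueError("true T1 must be positive")
    if tis is None:
        tis = np.arange(150.0, 3601.0, 150.0)
    tis = np.asarray(tis, dtype=float)
    rng = np.random.default_rng(seed)
    sig = np.abs(a - b * np.exp(-tis / (t1_true * 1e3)))
    if noise_sd > 0:
        sig = np.abs(sig + rng.normal(0.0, noise_sd, sig.shape))
    return tis, sig


def gen_sinus_volumes(t2b_true: float, s0: float = 100.0,
                      etes: tuple[float, ...] = PROTOCOL_ETES_MS,
                      shape: tuple[int, int] = (16, 16),
                      blob_center: tuple[int, int] = (8, 8),
                      noise_sd: float = 0.0, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Small volume series with a bright sagittal-sinus-like blob.

    The blob is a Gaussian intensity profile whose two brightest voxels
    carry the pure venous decay.  Returns ``(volumes, roi_mask,
    brightest_voxel)`` with volumes shaped ``(n_etes, ny, nx)``.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = blob_center
    profile = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * 1.5 ** 2))
    ete = np.asarray(etes, dtype=float)
    decay = np.exp(-ete / (t2b_true * 1e3))
    vols = s0 * profile[None] * decay[:, None, None]
    if noise_sd > 0:
        vols = vols + rng.normal(0.0, noise_sd, vols.shape)
    roi = profile > 0.05
    return vols, roi, (cy, cx)
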