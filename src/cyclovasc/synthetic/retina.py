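"""Procedural retinal vessel trees rendered as binarised angiograms.

Trees are grown as straight segments branching recursively from roots at
the image border towards the fovea-centred field, with radii tapering at
each generation.  Every rendered segment carries its true length and
radius (µm) and the analytic Poiseuille resistance, so skeleton-graph
measurements can be validated against an exact truth table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..octa import BLOOD_VISCOSITY, BinaryAngiogram

__all__ = ["TreeSpec", "gen_vessel_tree", "render_segments",
           "gen_retina_image"]


@dataclass(frozen=True)
class TreeSpec:
    """Branching parameters of a procedural vascular tree.

    Radii taper by ``radius_ratio`` per generation from ``root_radius_um``
    and segment lengths shrink by ``length_ratio`` from
    ``root_length_um``; each branch forks into two children at
    ``branch_angle_deg`` +- jitter.
    """

    n_roots: int = 4
    depth: int = 4
    root_radius_um: float = 22.0
    radius_ratio: float = 0.78
    root_length_um: float = 650.0
    length_ratio: float = 0.8
    branch_angle_deg: float = 35.0
    angle_jitter_deg: float = 10.0


def gen_vessel_tree(spec: TreeSpec = TreeSpec(), field_um: float = 3000.0,
                    seed: int = 0) -> pd.DataFrame:
    """Segment table (µm coordinates) of a random branching tree.

    Columns: ``y0, x0, y1, x1, length_um, radius_um, generation``.
    Roots start on the field border aimed at the centre.
    """
    rng = np.random.default_rng(seed)
    segments: list[dict] = []
    half = field_um / 2.0

    def grow(y, x, angle, length, radius, gen):
        if gen >= spec.depth or radius <= 0:
            return
        y1 = y + length * np.sin(angle)
        x1 = x + length * np.cos(angle)
        y1 = float(np.clip(y1, -half, half))
        x1 = float(np.clip(x1, -half, half))
        seg_len = float(np.hypot(y1 - y, x1 - x))
        if seg_len < 2.0:
            return
        segments.append({"y0": y, "x0": x, "y1": y1, "x1": x1,
                         "length_um": seg_len, "radius_um": radius,
                         "generation": gen})
        jitter = np.radians(spec.angle_jitter_deg)
        for sign in (-1.0, 1.0):
            child = angle + sign * np.radians(spec.branch_angle_deg) \
                + rng.uniform(-jitter, jitter)
            grow(y1, x1, child, length * spec.length_ratio,
                 radius * spec.radius_ratio, gen + 1)

    for i in range(spec.n_roots):
        border_angle = 2.0 * np.pi * (i + rng.uniform(0.2, 0.8)) / spec.n_roots
        y0 = float(np.clip(half * np.sin(border_angle) * 0.98, -half, half))
        x0 = float(np.clip(half * np.cos(border_angle) * 0.98, -half, half))
        inward = np.arctan2(-y0, -x0) + rng.uniform(-0.3, 0.3)
        grow(y0, x0, inward, spec.root_length_um, spec.root_radius_um, 0)
    return pd.DataFrame(segments)


def render_segments(segments: pd.DataFrame, pixel_pitch: float,
                    image_size: int, center_origin: bool = True
                    ) -> tuple[BinaryAngiogram, pd.DataFrame]:
    """Rasterise straight segments into a binary mask with a truth table.

    A pixel is vessel if its centre lies within the segment's radius of
    the centreline.  Segments whose radius falls below one pixel cannot
    be rendered faithfully and are rejected with a warning naming them.
    The returned truth table adds the analytic ``resistance`` column
    (Pa s/µm^3).
    """
    mask = np.zeros((image_size, image_size), dtype=bool)
    kept_rows = []
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    offset = (image_size - 1) / 2.0 if center_origin else 0.0
    for idx, seg in segments.iterrows():
        r_px = seg.radius_um / pixel_pitch
        if r_px < 1.0:
            warnings.warn(
                f"segment {idx} radius {seg.radius_um:.1f} µm is below one "
                f"pixel ({pixel_pitch:.2f} µm/px); rejected", stacklevel=2)
            continue
        p0 = np.array([seg.y0, seg.x0]) / pixel_pitch + offset
        p1 = np.array([seg.y1, seg.x1]) / pixel_pitch + offset
        d = p1 - p0
        len2 = float(d @ d)
        if len2 == 0:
            continue
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r_px - 1), 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r_px + 2),
                        image_size).astype(int)
        ys = slice(lo[0], hi[0])
        xs = slice(lo[1], hi[1])
        t = ((yy[ys, xs] - p0[0]) * d[0] + (xx[ys, xs] - p0[1]) * d[1]) / len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(yy[ys, xs] - (p0[0] + t * d[0]),
                        xx[ys, xs] - (p0[1] + t * d[1]))
        mask[ys, xs] |= dist <= r_px
        kept_rows.append(seg)
    truth = pd.DataFrame(kept_rows)
    if len(truth):
        truth["resistance"] = (8.0 * BLOOD_VISCOSITY * truth["length_um"]
                               / (np.pi * truth["radius_um"] ** 4))
    else:
        truth = pd.DataFrame(columns=[*segments.columns, "resistance"])
    angio = BinaryAngiogram(mask=mask.astype(np.uint8), pixel_pitch=pixel_pitch)
    return angio, truth


def gen_retina_image(tree_spec: TreeSpec = TreeSpec(),
                     pixel_pitch: float = 9.375, image_size: int = 320,
                     seed: int = 0) -> tuple[BinaryAngiogram, pd.DataFrame]:
    """Random 3 x 3 mm angiogram with its ground-truth segment table.

    Defaults give a 320 px grid over 3 mm (9.375 µm/px).  An empty tree
    yields an all-black image and an empty truth table.
    """
    field_um = pixel_pitch * image_size
    segments = gen_vessel_tree(tree_spec, field_um=field_um, seed=seed)
    if segments.empty:
        blank = BinaryAngiogram(
            mask=np.zeros((image_size, image_size), dtype=np.uint8),
            pixel_pitch=pixel_pitch)
        return blank, pd.DataFrame(
            columns=["y0", "x0", "y1", "x1", "length_um", "radius_um",
                     "generation", "resistance"])
    return render_segments(segments, pixel_pitch, image_size)
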