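"""Retinal vessel-network metrics from binarised OCT-A angiograms.

A fovea-centred 3 x 3 mm en-face angiogram, already binarised into
vessel/non-vessel pixels, is cleaned (isolated clusters of fewer than 30
pixels removed), skeletonised to a one-pixel centreline, and modelled as
a graph whose nodes are centreline pixels with an attached local radius
(Euclidean distance from the centreline pixel to the nearest non-vessel
pixel, minus half a pixel to refer the distance to the vessel boundary
rather than to the neighbouring background-pixel centre).  Maximal
centreline paths between junction or end nodes form vessel segments;
each segment's laminar (Poiseuille) flow resistance is

    R = 8 * eta * l / (pi * r**4)

with segment length ``l`` and mean radius ``r`` in µm and the blood
viscosity ``eta`` constant at 2.084e-3 Pa s, giving R in Pa s/µm^3.

Metrics are summarised over the ETDRS-style sector geometry: a central
foveal disc (1 mm diameter), and the parafoveal ring (3 mm outer
diameter) split into superior/temporal/inferior/nasal quadrants by
diagonals at 45 degrees through the fovea centre.  Temporal/nasal labels
flip with eye laterality.  Vessel density is the vessel-pixel fraction
of the foveal disc and of the parafoveal ring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects, skeletonize

__all__ = [
    "BLOOD_VISCOSITY",
    "BinaryAngiogram",
    "SkeletonGraph",
    "VesselSegment",
    "SectorGeometry",
    "clean_mask",
    "skeletonize_and_graph",
    "extract_segments",
    "segment_resistance",
    "vessel_density",
    "sector_metrics",
]

logger = logging.getLogger(__name__)

#: constant blood viscosity (Pa s)
BLOOD_VISCOSITY = 2.084e-3
#: clusters with fewer white pixels than this are removed
MIN_CLUSTER_PIXELS = 30

SECTORS = ("central", "superior", "temporal", "inferior", "nasal")


@dataclass
class BinaryAngiogram:
    """Binarised en-face angiogram with its physical scale.

    ``pixel_pitch`` is in µm/pixel; ``center`` is the fovea position as a
    (row, col) pixel coordinate (defaults to the image centre).  Image
    origin is top-left with y increasing downwards.
    """

    mask: np.ndarray
    pixel_pitch: float
    center: tuple[float, float] | None = None
    field_mm: float = 3.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise ValueError("angiogram mask must be 2-D")
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (values in {0, 1})")
        self.mask = mask.astype(bool)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.center is None:
            self.center = ((mask.shape[0] - 1) / 2.0,
                           (mask.shape[1] - 1) / 2.0)


@dataclass
class SkeletonGraph:
    """Centreline network: 8-connected skeleton pixels with radii (µm)."""

    graph: nx.Graph              # nodes: (row, col); attrs: radius_um
    pixel_pitch: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class VesselSegment:
    """A maximal centreline path between junction/end nodes."""

    path: list[tuple[int, int]]
    length_um: float
    radius_um: float

    @property
    def midpoint(self) -> tuple[int, int]:
        return self.path[len(self.path) // 2]

    @property
    def resistance(self) -> float:
        return segment_resistance(self.length_um, self.radius_um)


def clean_mask(mask: np.ndarray,
               min_pixels: int = MIN_CLUSTER_PIXELS) -> np.ndarray:
    """Remove isolated 8-connected clusters of fewer than ``min_pixels``."""
    mask = np.asarray(mask).astype(bool)
    # max_size removes components of size <= value, i.e. strictly < min_pixels
    return remove_small_objects(mask, max_size=min_pixels - 1, connectivity=2)


def skeletonize_and_graph(angio: BinaryAngiogram) -> SkeletonGraph:
    """One-pixel centreline network with per-node radii.

    Node radius is the Euclidean distance transform at the centreline
    pixel minus half a pixel (boundary-referred), scaled to µm; a
    width-9 bar therefore reads radius 4.5 px away from its ends.
    """
    mask = angio.mask
    g = nx.Graph()
    if not mask.any():
        return SkeletonGraph(graph=g, pixel_pitch=angio.pixel_pitch)
    skel = skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)
    pts = np.argwhere(skel)
    pset = set(map(tuple, pts))
    for y, x in pts:
        r_px = max(edt[y, x] - 0.5, 0.5)
        g.add_node((int(y), int(x)), radius_um=r_px * angio.pixel_pitch)
    for y, x in pts:
        for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (int(y + dy), int(x + dx))
            if nb in pset:
                g.add_edge((int(y), int(x)), nb,
                           step=float(np.hypot(dy, dx)))
    return SkeletonGraph(graph=g, pixel_pitch=angio.pixel_pitch)


def _walk(graph: nx.Graph, start, first, visited_edges) -> list:
    """Follow a degree-2 chain from ``start`` through ``first``."""
    path = [start, first]
    visited_edges.add(frozenset((start, first)))
    prev, cur = start, first
    while graph.degree(cur) == 2:
        nxt = next(n for n in graph.neighbors(cur) if n != prev)
        edge = frozenset((cur, nxt))
        if edge in visited_edges:
            break
        visited_edges.add(edge)
        path.append(nxt)
        prev, cur = cur, nxt
    return path


def extract_segments(skeleton: SkeletonGraph,
                     min_nodes: int = 3) -> list[VesselSegment]:
    """Maximal paths between nodes of degree != 2.

    Length is the sum of step lengths (1 or sqrt(2) pixels x pitch);
    radius is the mean of path-node radii.  Paths with fewer than
    ``min_nodes`` nodes are discarded; isolated closed loops (every node
    degree 2) are skipped with a log entry.
    """
    g = skeleton.graph
    pitch = skeleton.pixel_pitch
    visited: set[frozenset] = set()
    segments: list[VesselSegment] = []

    def finish(path):
        if len(path) < min_nodes:
            return
        length = sum(g.edges[a, b]["step"]
                     for a, b in zip(path[:-1], path[1:])) * pitch
        radius = float(np.mean([g.nodes[n]["radius_um"] for n in path]))
        segments.append(VesselSegment(path=path, length_um=length,
                                      radius_um=radius))

    for node in g.nodes:
        if g.degree(node) == 2:
            continue
        for nb in g.neighbors(node):
            if frozenset((node, nb)) in visited:
                continue
            finish(_walk(g, node, nb, visited))

    n_loop_edges = sum(1 for a, b in g.edges
                       if frozenset((a, b)) not in visited)
    if n_loop_edges:
        logger.info("skipped %d edges in isolated closed loops", n_loop_edges)
    return segments


def segment_resistance(length_um: float, radius_um: float,
                       eta: float = BLOOD_VISCOSITY) -> float:
    """Poiseuille resistance 8*eta*l/(pi*r^4) in Pa s/µm^3."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if length_um <= 0:
        raise ValueError("length must be positive")
    return 8.0 * eta * length_um / (np.pi * radius_um ** 4)


def vessel_density(mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Vessel-pixel fraction within a region of interest."""
    mask = np.asarray(mask).astype(bool)
    region = np.asarray(region_mask).astype(bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region of interest")
    return float(mask[region].sum()) / n


@dataclass
class SectorGeometry:
    """ETDRS-style sectors of a fovea-centred scan.

    The foveal disc has ``fovea_diameter_mm`` diameter; the parafoveal
    ring extends to ``parafovea_diameter_mm`` and is split into four
    quadrants by the 45-degree diagonals.  For a right eye the temporal
    retina appears on the image left; for a left eye on the image right
    (so temporal/nasal labels swap under horizontal mirroring).
    """

    center: tuple[float, float]      # (row, col), px
    pixel_pitch: float               # µm/px
    eye: str = "left"
    fovea_diameter_mm: float = 1.0
    parafovea_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")

    def classify(self, point: tuple[float, float]) -> str | None:
        """Sector label of a pixel coordinate, or None outside the ring."""
        dy = (point[0] - self.center[0]) * self.pixel_pitch
        dx = (point[1] - self.center[1]) * self.pixel_pitch
        rad = np.hypot(dy, dx)
        if rad <= self.fovea_diameter_mm * 500.0:
            return "central"
        if rad > self.parafovea_diameter_mm * 500.0:
            return None
        if -dy >= abs(dx):          # image y grows downwards
            return "superior"
        if dy >= abs(dx):
            return "inferior"
        image_right = dx > 0
        if self.eye == "right":
            return "nasal" if image_right else "temporal"
        return "temporal" if image_right else "nasal"

    def region_mask(self, shape: tuple[int, int], which: str) -> np.ndarray:
        """Boolean mask of the foveal disc or parafoveal ring."""
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        rad = np.hypot((yy - self.center[0]) * self.pixel_pitch,
                       (xx - self.center[1]) * self.pixel_pitch)
        fovea = rad <= self.fovea_diameter_mm * 500.0
        if which == "fovea":
            return fovea
        if which == "parafovea":
            return (rad <= self.parafovea_diameter_mm * 500.0) & ~fovea
        raise ValueError("which must be 'fovea' or 'parafovea'")


def sector_metrics(segments: list[VesselSegment], geometry: SectorGeometry,
                   angio: BinaryAngiogram | None = None) -> dict:
    """Per-sector mean Poiseuille resistance, plus densities if given a mask.

    Each segment is assigned to one sector by its midpoint node; the
    global value is the mean over all assignable segments.  Sectors with
    no segments report NaN.  When ``angio`` is supplied, vessel density
    is computed for the foveal disc and parafoveal ring.
    """
    by_sector: dict[str, list[float]] = {s: [] for s in SECTORS}
    all_r: list[float] = []
    unassigned = 0
    for seg in segments:
        label = geometry.classify(seg.midpoint)
        if label is None:
            unassigned += 1
            continue
        r = seg.resistance
        by_sector[label].append(r)
        all_r.append(r)
    if unassigned:
        logger.info("%d segments outside the parafovea were not assigned",
                    unassigned)
    out: dict = {}
    for s in SECTORS:
        vals = by_sector[s]
        if not vals:
            logger.info("sector %r has no segments; reported as missing", s)
        out[f"resistance_{s}"] = float(np.mean(vals)) if vals else np.nan
        out[f"n_segments_{s}"] = len(vals)
    out["resistance_global"] = float(np.mean(all_r)) if all_r else np.nan
    out["n_segments_total"] = len(segments)
    out["n_segments_unassigned"] = unassigned
    if angio is not None:
        for which in ("fovea", "parafovea"):
            region = geometry.region_mask(angio.mask.shape, which)
            out[f"density_{which}"] = vessel_density(angio.mask, region)
    return out
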