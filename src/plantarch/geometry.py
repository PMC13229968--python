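"""Forward-kinematic 3-D reconstruction and simulation-based traits.

The token/XML representation stores only local organ parameters; whole-plant
traits (height, leaf inclination, canopy cover) only exist after composing
the chain of rotations from the plant base out to every organ. Conventions,
used consistently by the generator and every trait:

* right-handed frames, z up; a frame is a 3×3 rotation matrix whose third
  column is the organ's growth axis (and, for leaf frames, the lamina
  normal);
* an (pitch, yaw, roll) triple composes as ``Rz(yaw) · Ry(pitch) · Rx(roll)``
  — yaw outermost, so changing the base yaw rotates the whole plant rigidly
  about the vertical axis;
* the phyllotactic angle accumulates azimuth node by node along a shoot;
  internode pitch tilts each internode away from the shoot axis without
  compounding;
* petiole curvature bends the petiole as a circular arc in its pitch plane,
  discretized in 5 segments; leaves attach to the arc's end frame;
* the unifoliate leaf pair attaches at azimuth offsets {0°, 180°}, the
  trifoliate leaflets at {0°, +120°, −120°} (terminal leaflet first); the
  two lateral leaflets are scaled by the petiole's leaflet_scale;
* a leaf is a square lamina of side ``scale·√A₀`` centred ``side/2`` along
  its local x axis, with unit prototype area A₀ = 1 m², so leaf area is
  exactly scale² (× leaflet_scale² for lateral leaflets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PlantArchitecture, PlantMetadata
from .tokenizer import TokenSequence, detokenize
from .vocab import Vocabulary

__all__ = [
    "Geometry3D",
    "OrganCounts",
    "TraitReport",
    "reconstruct_geometry",
    "plant_height",
    "leaf_inclination_distribution",
    "count_organs",
    "bounding_metadata",
    "compute_traits",
    "UNIT_LEAF_AREA",
]

UNIT_LEAF_AREA = 1.0          # m^2, prototype lamina area at scale 1
_ARC_SEGMENTS = 5
_RASTER_CELLS = 256

_UNIFOLIATE_OFFSETS = (0.0, 180.0)
_TRIFOLIATE_OFFSETS = (0.0, 120.0, -120.0)


def _rot(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Rz(yaw) · Ry(pitch) · Rx(roll), angles in degrees."""
    p, y, r = np.deg2rad([pitch, yaw, roll])
    cy, sy = np.cos(y), np.sin(y)
    cp, sp = np.cos(p), np.sin(p)
    cr, sr = np.cos(r), np.sin(r)
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1.0]])
    ry = np.array([[cp, 0, sp], [0, 1.0, 0], [-sp, 0, cp]])
    rx = np.array([[1.0, 0, 0], [0, cr, -sr], [0, sr, cr]])
    return rz @ ry @ rx


def _rz(deg: float) -> np.ndarray:
    return _rot(0.0, deg, 0.0)


def _ry(deg: float) -> np.ndarray:
    return _rot(deg, 0.0, 0.0)


@dataclass
class Geometry3D:
    """Reconstructed per-organ 3-D geometry of one plant."""

    base_position: np.ndarray          # (3,)
    segments: np.ndarray               # (n_seg, 2, 3) internode+petiole endpoints
    leaf_centers: np.ndarray           # (n_leaf, 3)
    leaf_normals: np.ndarray           # (n_leaf, 3), unit
    leaf_areas: np.ndarray             # (n_leaf,), m^2
    leaf_frames: np.ndarray            # (n_leaf, 3, 3)
    leaf_sides: np.ndarray             # (n_leaf,), lamina side length, m

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_centers)


@dataclass
class OrganCounts:
    n_shoots: int
    n_phytomers: int
    n_leaves: int


@dataclass
class TraitReport:
    """Simulation-derived whole-plant traits."""

    height_m: float
    leaf_count: int
    total_leaf_area_m2: float
    inclination_histogram: np.ndarray     # probability mass per bin over [0°, 90°]
    bin_edges_deg: np.ndarray


def reconstruct_geometry(plant: PlantArchitecture) -> Geometry3D:
    """Compose rotations root → leaf and place every organ in 3-D."""
    base = np.asarray(plant.base_position, dtype=float)
    m_base = _rot(*plant.base_rotation)

    segments: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    areas: list[float] = []
    frames: list[np.ndarray] = []
    sides: list[float] = []

    # attachment point and frame per (shoot_id, node): filled as shoots are walked
    node_anchor: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    for shoot in plant.shoots:
        if shoot.parent_shoot_id == -1:
            pos, frame = base, m_base
        else:
            pos, frame = node_anchor[(shoot.parent_shoot_id, shoot.parent_node_index)]
        s_frame = frame @ _rot(shoot.base_pitch, shoot.base_yaw, shoot.base_roll)
        azimuth = 0.0
        for node, ph in enumerate(shoot.phytomers):
            azimuth += ph.internode.phyllotactic_angle
            i_frame = s_frame @ _rz(azimuth) @ _ry(ph.internode.pitch)
            tip = pos + i_frame[:, 2] * ph.internode.length
            segments.append(np.stack([pos, tip]))
            node_anchor[(shoot.shoot_id, node)] = (tip, i_frame)

            # petiole: circular-arc bend in the pitch plane
            g = i_frame @ _ry(ph.petiole.pitch)
            p = tip
            step = ph.petiole.length / _ARC_SEGMENTS
            bend = _ry(ph.petiole.curvature / _ARC_SEGMENTS)
            for _ in range(_ARC_SEGMENTS):
                q = p + g[:, 2] * step
                segments.append(np.stack([p, q]))
                p = q
                g = g @ bend

            trifoliate = ph.is_trifoliate
            offsets = _TRIFOLIATE_OFFSETS if trifoliate else _UNIFOLIATE_OFFSETS
            leaflet = ph.petiole.leaflet_scale if trifoliate else 1.0
            for slot, leaf in zip(range(len(ph.leaves)), ph.leaves):
                eff_scale = leaf.scale * (leaflet if trifoliate and slot > 0 else 1.0)
                lf = g @ _rz(offsets[slot]) @ _rot(leaf.pitch, leaf.yaw, leaf.roll)
                side = eff_scale * np.sqrt(UNIT_LEAF_AREA)
                center = p + lf[:, 0] * (side / 2.0)
                centers.append(center)
                normals.append(lf[:, 2])
                areas.append(eff_scale ** 2 * UNIT_LEAF_AREA)
                frames.append(lf)
                sides.append(side)

            pos = tip   # next internode starts at this node

    n = len(centers)
    return Geometry3D(
        base_position=base,
        segments=np.asarray(segments).reshape(-1, 2, 3) if segments else np.zeros((0, 2, 3)),
        leaf_centers=np.asarray(centers).reshape(n, 3),
        leaf_normals=np.asarray(normals).reshape(n, 3),
        leaf_areas=np.asarray(areas, dtype=float),
        leaf_frames=np.asarray(frames).reshape(n, 3, 3),
        leaf_sides=np.asarray(sides, dtype=float),
    )


def _all_points(geom: Geometry3D) -> np.ndarray:
    pts = [geom.segments.reshape(-1, 3)]
    if geom.n_leaves:
        pts.append(_leaf_corners(geom).reshape(-1, 3))
    return np.concatenate(pts) if pts else np.zeros((0, 3))


def _leaf_corners(geom: Geometry3D) -> np.ndarray:
    """(n_leaf, 4, 3) world-space corners of each square lamina."""
    h = geom.leaf_sides[:, None] / 2.0
    ex = geom.leaf_frames[:, :, 0] * h
    ey = geom.leaf_frames[:, :, 1] * h
    c = geom.leaf_centers
    return np.stack([c - ex - ey, c + ex - ey, c + ex + ey, c - ex + ey], axis=1)


def plant_height(geom: Geometry3D) -> float:
    """Highest point above the base plane, in metres (0 for empty geometry)."""
    pts = _all_points(geom)
    if len(pts) == 0:
        return 0.0
    return float(pts[:, 2].max() - geom.base_position[2])


def leaf_inclination_distribution(geom: Geometry3D, n_bins: int = 10
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Leaf inclination histogram: angle of leaf normal from vertical,
    folded to [0°, 90°], as probability masses over ``n_bins`` equal bins.

    Returns (masses, bin_edges_deg); masses sum to 1. Raises for leafless
    plants.
    """
    if geom.n_leaves == 0:
        raise ValueError("plant has no leaves: inclination distribution undefined")
    nz = np.abs(np.clip(geom.leaf_normals[:, 2], -1.0, 1.0))
    incl = np.rad2deg(np.arccos(nz))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(incl, bins=edges)
    return hist / hist.sum(), edges


def count_organs(seq: TokenSequence, vocab: Vocabulary) -> OrganCounts:
    """Organ tallies straight from the token sequence.

    Shoots are the count of shoot tokens, phytomers of internode tokens,
    leaves of leaf-slot tokens (organ codes 3–5). The sequence is grammar-
    checked first (DecodeError on violation).
    """
    detokenize(seq, vocab)   # raises DecodeError if ungrammatical
    organ_codes = [tid % 6 for tid in seq if vocab.is_organ(tid)]
    return OrganCounts(
        n_shoots=sum(1 for c in organ_codes if c == 0),
        n_phytomers=sum(1 for c in organ_codes if c == 1),
        n_leaves=sum(1 for c in organ_codes if c >= 3),
    )


def bounding_metadata(geom: Geometry3D, window_m: float) -> PlantMetadata:
    """Top-view window metadata: width, height, vegetation fraction.

    Width is the larger horizontal bounding-box side; vegetation fraction is
    the share of a ``window_m × window_m`` window (centred on the plant
    base) covered by leaf laminae, on an orthographic top-view
    rasterization over a 256×256 grid.
    """
    from skimage.draw import polygon as _sk_polygon

    if window_m <= 0:
        raise ValueError("window_m must be positive")
    pts = _all_points(geom)
    if len(pts) == 0:
        return PlantMetadata(0.0, 0.0, 0.0)
    width = float(max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])))
    height = plant_height(geom)
    mask = np.zeros((_RASTER_CELLS, _RASTER_CELLS), dtype=bool)
    if geom.n_leaves:
        origin = geom.base_position[:2] - window_m / 2.0
        cell = window_m / _RASTER_CELLS
        corners = _leaf_corners(geom)
        for quad in corners:
            rr = (quad[:, 1] - origin[1]) / cell
            cc = (quad[:, 0] - origin[0]) / cell
            r_idx, c_idx = _sk_polygon(rr, cc, shape=mask.shape)
            mask[r_idx, c_idx] = True
    fraction = float(mask.sum()) / mask.size
    return PlantMetadata(width_m=width, height_m=height, vegetation_fraction=fraction)


def compute_traits(plant: PlantArchitecture, n_bins: int = 10) -> TraitReport:
    """Reconstruct geometry and derive the whole-plant trait report."""
    geom = reconstruct_geometry(plant)
    if geom.n_leaves:
        hist, edges = leaf_inclination_distribution(geom, n_bins)
    else:
        hist, edges = np.zeros(n_bins), np.linspace(0.0, 90.0, n_bins + 1)
    return TraitReport(
        height_m=plant_height(geom),
        leaf_count=geom.n_leaves,
        total_leaf_area_m2=float(geom.leaf_areas.sum()),
        inclination_histogram=hist,
        bin_edges_deg=edges,
    )
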