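"""Structural-integrity quantification.

Two measurements on a binary scaffold mask:

* per-segment strut discontinuity — a design segment is CONTINUOUS when its
  two endpoint nodes are joined by a 26-connected path of mask voxels lying
  within a capture radius of the segment centerline; the discontinuity ratio
  is the percentage of DISCONTINUOUS segments;
* scaffold inner area on 2D cross-sections taken at fixed axial intervals —
  the area of the polygon through the innermost strut points of each slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import phantom as ph
from .geometry import DesignGraph
from .volio import VoxelVolume

__all__ = [
    "CONTINUOUS",
    "DISCONTINUOUS",
    "UNMEASURABLE",
    "IntegrityResult",
    "InnerAreaProfile",
    "IntegrityError",
    "segment_scaffold",
    "discontinuity_ratio",
    "inner_area_profile",
]

CONTINUOUS = "CONTINUOUS"
DISCONTINUOUS = "DISCONTINUOUS"
UNMEASURABLE = float("nan")

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


class IntegrityError(ValueError):
    pass


def segment_scaffold(
    volume: "ph.LabelVolume | VoxelVolume",
    fit=None,
    min_voxels: int = 0,
) -> np.ndarray:
    """Binary mask of visible strut material (Mg alloy + dense product).

    Label volumes are masked directly; grayscale volumes are classified
    voxel-wise by maximum posterior under the supplied histogram fit.
    ``min_voxels`` > 0 drops 26-connected speckle components smaller than
    that size (useful for noisy grayscale classifications).
    """
    if isinstance(volume, ph.LabelVolume):
        return volume.class_mask(ph.MG_ALLOY, ph.PRODUCT_DENSE)
    if fit is None:
        raise IntegrityError("grayscale input requires a HistogramFit")
    v = np.asarray(volume.values, dtype=np.float64)
    log_post = np.full(v.shape + (fit.n_components,), -np.inf)
    for i, (w, mu, sd) in enumerate(fit.components()):
        if w <= 0:
            continue
        log_post[..., i] = (
            math.log(w) - 0.5 * ((v - mu) / sd) ** 2 - math.log(sd)
        )
    comp = np.argmax(log_post, axis=-1)
    classes = np.array(
        [fit.class_assignment[i] for i in range(fit.n_components)], dtype=np.uint8
    )
    cls = classes[comp]
    mask = (cls == ph.MG_ALLOY) | (cls == ph.PRODUCT_DENSE)
    if min_voxels > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_voxels)
        mask &= ~np.isin(labels, small[small > 0])
    return mask


@dataclass
class IntegrityResult:
    per_segment_continuity: dict[int, str]
    discontinuity_ratio: float  # percent
    n_fragments: int
    empty_mask: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.per_segment_continuity)

    @property
    def n_discontinuous(self) -> int:
        return sum(
            1 for v in self.per_segment_continuity.values() if v == DISCONTINUOUS
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": list(self.per_segment_continuity),
                "continuity": list(self.per_segment_continuity.values()),
            }
        ).set_index("segment_id")

    def to_dict(self) -> dict:
        return {
            "discontinuity_ratio_percent": self.discontinuity_ratio,
            "n_segments": self.n_segments,
            "n_discontinuous": self.n_discontinuous,
            "n_fragments": self.n_fragments,
            "empty_mask": self.empty_mask,
        }


def _polyline_tube_check(
    mask: np.ndarray,
    spacing: float,
    origin: np.ndarray,
    centerline: np.ndarray,
    node_a: np.ndarray,
    node_b: np.ndarray,
    capture_radius: float,
) -> bool:
    """True when node_a and node_b are 26-connected through mask voxels
    within ``capture_radius`` of the centerline polyline."""
    nz, ny, nx = mask.shape
    lo = centerline.min(axis=0) - capture_radius - spacing
    hi = centerline.max(axis=0) + capture_radius + spacing
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, [nx, ny, nz])
    if np.any(i0 >= i1):
        return False
    sub = mask[i0[2]:i1[2], i0[1]:i1[1], i0[0]:i1[0]]
    if not sub.any():
        return False

    xs = origin[0] + spacing * np.arange(i0[0], i1[0])
    ys = origin[1] + spacing * np.arange(i0[1], i1[1])
    zs = origin[2] + spacing * np.arange(i0[2], i1[2])
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    dist2 = np.full(sub.shape, np.inf)
    for p0, p1 in zip(centerline[:-1], centerline[1:]):
        d = p1 - p0
        ll = float(d @ d)
        if ll == 0:
            continue
        q = pts - p0
        u = np.clip((q @ d) / ll, 0.0, 1.0)
        diff = q - u[..., None] * d
        dist2 = np.minimum(dist2, np.einsum("...i,...i", diff, diff))

    tube = sub & (dist2 <= capture_radius**2)
    if not tube.any():
        return False
    labels, _ = ndimage.label(tube, structure=_STRUCT_26)

    def seed_labels(node):
        d2 = np.einsum("...i,...i", pts - node, pts - node)
        sel = labels[(d2 <= capture_radius**2) & tube]
        return set(np.unique(sel))

    la, lb = seed_labels(node_a), seed_labels(node_b)
    return bool(la and lb and (la & lb))


def discontinuity_ratio(
    mask: np.ndarray,
    graph: DesignGraph,
    spacing: float,
    origin=(0.0, 0.0, 0.0),
    capture_radius: float | None = None,
    registration=None,
) -> IntegrityResult:
    """Per-segment continuity, overall discontinuity ratio, fragment count.

    ``registration`` maps design coordinates into the mask frame: ``None``
    (identity, the phantom case) or a ``(R, t)`` rigid pair with ``R`` a 3x3
    rotation and ``t`` a translation in mm.
    """
    mask = np.asarray(mask, dtype=bool)
    design = graph.design
    if capture_radius is None:
        capture_radius = 1.5 * design.strut_width
    origin = np.asarray(origin, dtype=float)

    if registration is None:
        nodes = graph.nodes
        transform = lambda p: p  # noqa: E731
    else:
        try:
            R, t = registration
            R = np.asarray(R, dtype=float).reshape(3, 3)
            t = np.asarray(t, dtype=float).reshape(3)
        except Exception as exc:
            raise IntegrityError(
                "registration must be None or a (3x3 rotation, translation) pair"
            ) from exc
        nodes = graph.nodes @ R.T + t
        transform = lambda p: p @ R.T + t  # noqa: E731

    if not mask.any():
        continuity = {s.id: DISCONTINUOUS for s in graph.segments}
        return IntegrityResult(
            per_segment_continuity=continuity,
            discontinuity_ratio=100.0,
            n_fragments=0,
            empty_mask=True,
        )

    continuity = {}
    for seg in graph.segments:
        ok = _polyline_tube_check(
            mask,
            spacing,
            origin,
            transform(seg.centerline),
            nodes[seg.node_a],
            nodes[seg.node_b],
            capture_radius,
        )
        continuity[seg.id] = CONTINUOUS if ok else DISCONTINUOUS

    _, n_fragments = ndimage.label(mask, structure=_STRUCT_26)
    n_disc = sum(1 for v in continuity.values() if v == DISCONTINUOUS)
    return IntegrityResult(
        per_segment_continuity=continuity,
        discontinuity_ratio=100.0 * n_disc / len(continuity),
        n_fragments=int(n_fragments),
    )


# ---------------------------------------------------------------------------
# inner area

@dataclass
class InnerAreaProfile:
    slice_positions: np.ndarray  # mm from the first occupied slice
    areas: np.ndarray  # mm^2, NaN where unmeasurable
    mean_area: float  # mm^2 over measurable slices (NaN if none)

    def measurable(self) -> np.ndarray:
        return ~np.isnan(self.areas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_mm": self.slice_positions, "inner_area_mm2": self.areas}
        )

    def to_dict(self) -> dict:
        return {
            "positions_mm": self.slice_positions.tolist(),
            "areas_mm2": [None if math.isnan(a) else a for a in self.areas],
            "mean_area_mm2": None if math.isnan(self.mean_area) else self.mean_area,
        }


def _slice_inner_points(
    sl: np.ndarray, spacing: float, n_angular_bins: int = 36
) -> np.ndarray | None:
    """Innermost strut points (x, y in voxel units * spacing) of one slice.

    With >= 3 strut cross-sections, one innermost point per connected
    component; a slice whose (single or double) component wraps most of the
    way around the centroid — a tube wall — instead contributes the
    innermost point per angular sector.  Otherwise the slice is unmeasurable.
    """
    if not sl.any():
        return None
    labels, ncomp = ndimage.label(sl, structure=_STRUCT_8)
    yy, xx = np.nonzero(sl)
    cy, cx = yy.mean(), xx.mean()
    dy, dx = (yy - cy) * spacing, (xx - cx) * spacing
    radii = np.hypot(dx, dy)
    angles = np.arctan2(dy, dx)

    if ncomp >= 3:
        pts = []
        comp = labels[yy, xx]
        for c in range(1, ncomp + 1):
            sel = comp == c
            i = np.argmin(np.where(sel, radii, np.inf))
            pts.append((dx[i], dy[i]))
        return np.asarray(pts)

    # tube-wall fallback: require >= 3/4 angular coverage around the centroid
    bins = ((angles + math.pi) / (2 * math.pi) * n_angular_bins).astype(int)
    bins = np.clip(bins, 0, n_angular_bins - 1)
    occupied = np.unique(bins)
    if occupied.size < 0.75 * n_angular_bins:
        return None
    pts = []
    for b in occupied:
        sel = bins == b
        i = np.argmin(np.where(sel, radii, np.inf))
        pts.append((dx[i], dy[i]))
    return np.asarray(pts)


def _polygon_area(points: np.ndarray) -> float:
    """Shoelace area of the polygon through points sorted by angle."""
    order = np.argsort(np.arctan2(points[:, 1], points[:, 0]))
    p = points[order]
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def inner_area_profile(
    mask: np.ndarray,
    spacing: float,
    interval: float = 3.0,
    min_points: int = 3,
) -> InnerAreaProfile:
    """Inner areas on axial sections every ``interval`` mm.

    Sections start at the first slice containing mask voxels (the proximal
    end); the device axis is the z axis.
    """
    mask = np.asarray(mask, dtype=bool)
    occupied = np.flatnonzero(mask.any(axis=(1, 2)))
    if occupied.size == 0:
        return InnerAreaProfile(
            slice_positions=np.array([]), areas=np.array([]), mean_area=UNMEASURABLE
        )
    step = max(1, int(round(interval / spacing)))
    z_indices = np.arange(occupied[0], occupied[-1] + 1, step)
    positions, areas = [], []
    for zi in z_indices:
        pts = _slice_inner_points(mask[zi], spacing)
        if pts is None or len(pts) < min_points:
            area = UNMEASURABLE
        else:
            area = _polygon_area(pts)
        positions.append((zi - occupied[0]) * spacing)
        areas.append(area)
    areas = np.asarray(areas, dtype=float)
    ok = ~np.isnan(areas)
    mean_area = float(areas[ok].mean()) if ok.any() else UNMEASURABLE
    return InnerAreaProfile(
        slice_positions=np.asarray(positions), areas=areas, mean_area=mean_area
    )
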