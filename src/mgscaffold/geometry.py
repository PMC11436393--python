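"""Parametric scaffold geometry.

A scaffold is a stack of sinusoidal rings on a cylinder, joined by straight
axial links.  Each ring of ``n`` crowns is the closed curve

    theta -> (r_c cos(theta), r_c sin(theta), z_i + A cos(n (theta - phi_i)))

with ``r_c = (nominal_diameter - strut_thickness) / 2`` the centerline radius
and ``A`` the crown amplitude.  Nodes sit at the 2n axial extrema of each ring
(peaks and valleys); a *limb* segment is the arc between two adjacent extrema,
so each crown contributes two limbs.  Adjacent rings are phase-shifted by half
a crown so peaks of one ring line up with valleys of the next; links are
straight segments at a subset of those aligned angular positions.

The decomposition into segments is the unit of account for discontinuity
analysis: a design with R rings, n crowns and L links has
``R * 2n + (R - 1) * L`` segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ScaffoldDesign",
    "Segment",
    "DesignGraph",
    "DesignError",
    "build_design",
    "segment_count",
    "nominal_volume",
    "design_from_dict",
]

#: number of sample points per limb centerline polyline
_LIMB_SAMPLES = 33


class DesignError(ValueError):
    """Raised when scaffold design parameters violate an invariant."""


@dataclass(frozen=True)
class ScaffoldDesign:
    """Parametric description of a crown-and-link scaffold.

    Lengths are in mm.  Defaults approximate a 3-mm device with 110 um
    square struts, ~10 rings over ~15 mm.
    """

    nominal_diameter: float = 3.0
    n_rings: int = 10
    crowns_per_ring: int = 6
    links_between_rings: int = 2
    strut_width: float = 0.11
    strut_thickness: float = 0.11
    ring_pitch: float = 1.5
    crown_amplitude: float = 0.6

    def __post_init__(self) -> None:
        validate_design(self)

    @property
    def centerline_radius(self) -> float:
        return (self.nominal_diameter - self.strut_thickness) / 2.0

    @property
    def length(self) -> float:
        """Axial extent of the centerline lattice."""
        return (self.n_rings - 1) * self.ring_pitch + 2 * self.crown_amplitude

    def to_dict(self) -> dict:
        return asdict(self)


def validate_design(design: ScaffoldDesign) -> None:
    positive = (
        "nominal_diameter",
        "strut_width",
        "strut_thickness",
        "ring_pitch",
        "crown_amplitude",
    )
    for name in positive:
        if not getattr(design, name) > 0:
            raise DesignError(f"{name} must be > 0, got {getattr(design, name)!r}")
    if int(design.n_rings) != design.n_rings or design.n_rings < 1:
        raise DesignError(f"n_rings must be an integer >= 1, got {design.n_rings!r}")
    if design.crowns_per_ring < 3:
        raise DesignError(
            f"crowns_per_ring must be >= 3, got {design.crowns_per_ring!r}"
        )
    if design.links_between_rings < 1:
        raise DesignError(
            f"links_between_rings must be >= 1, got {design.links_between_rings!r}"
        )
    if design.links_between_rings > design.crowns_per_ring:
        raise DesignError(
            "links_between_rings cannot exceed crowns_per_ring "
            f"({design.links_between_rings} > {design.crowns_per_ring})"
        )
    quarter = design.nominal_diameter / 4.0
    if design.strut_width >= quarter:
        raise DesignError(
            f"strut_width must be < nominal_diameter/4 ({design.strut_width} >= {quarter})"
        )
    if design.strut_thickness >= quarter:
        raise DesignError(
            f"strut_thickness must be < nominal_diameter/4 "
            f"({design.strut_thickness} >= {quarter})"
        )
    if design.n_rings > 1 and design.ring_pitch <= 2 * design.crown_amplitude:
        raise DesignError(
            "ring_pitch must exceed 2 * crown_amplitude so links have positive "
            f"length ({design.ring_pitch} <= {2 * design.crown_amplitude})"
        )


@dataclass(frozen=True)
class Segment:
    """One strut segment: a crown limb or an inter-ring link."""

    id: int
    node_a: int
    node_b: int
    kind: str  # "limb" | "link"
    centerline: np.ndarray  # (m, 3) points in mm

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())


@dataclass
class DesignGraph:
    """Node/segment decomposition of a scaffold design."""

    design: ScaffoldDesign
    nodes: np.ndarray  # (N, 3) mm
    segments: list[Segment] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_ids(self) -> list[int]:
        return [s.id for s in self.segments]

    def total_centerline_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(range(len(self.nodes)))
        for s in self.segments:
            g.add_edge(s.node_a, s.node_b, key=s.id, length=s.length, kind=s.kind)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    # ------------------------------------------------------------------ export

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nodes, columns=["x_mm", "y_mm", "z_mm"]).rename_axis(
            "node_id"
        )

    def segments_frame(self) -> pd.DataFrame:
        rows = [
            {
                "segment_id": s.id,
                "node_a": s.node_a,
                "node_b": s.node_b,
                "kind": s.kind,
                "length_mm": s.length,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows).set_index("segment_id")

    def to_json_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "nodes": self.nodes.tolist(),
            "segments": [
                {
                    "id": s.id,
                    "node_a": s.node_a,
                    "node_b": s.node_b,
                    "kind": s.kind,
                    "centerline": s.centerline.tolist(),
                }
                for s in self.segments
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)


def segment_count(design: ScaffoldDesign) -> int:
    """Number of strut segments: ``R*2n + (R-1)*L``."""
    return design.n_rings * 2 * design.crowns_per_ring + (
        design.n_rings - 1
    ) * design.links_between_rings


def _ring_phase(ring: int, crowns: int) -> float:
    # adjacent rings are offset by half a crown so peaks face valleys
    return (ring % 2) * np.pi / crowns


def _ring_z(design: ScaffoldDesign, ring: int) -> float:
    return design.crown_amplitude + ring * design.ring_pitch


def build_design(design: ScaffoldDesign | None = None, **params) -> DesignGraph:
    """Build the node/segment graph for a design.

    Either pass a :class:`ScaffoldDesign` or keyword parameters for one.
    """
    if design is None:
        design = ScaffoldDesign(**params)
    elif params:
        raise TypeError("pass either a design or keyword parameters, not both")

    n = design.crowns_per_ring
    r_c = design.centerline_radius
    amp = design.crown_amplitude

    # nodes: ring extrema, indexed (ring, j) with j in [0, 2n)
    node_index: dict[tuple[int, int], int] = {}
    coords: list[tuple[float, float, float]] = []
    for ring in range(design.n_rings):
        phi = _ring_phase(ring, n)
        z0 = _ring_z(design, ring)
        for j in range(2 * n):
            theta = phi + j * np.pi / n
            z = z0 + amp * np.cos(j * np.pi)  # +A at even j (peak), -A at odd
            node_index[(ring, j)] = len(coords)
            coords.append((r_c * np.cos(theta), r_c * np.sin(theta), z))
    nodes = np.asarray(coords, dtype=float)

    segments: list[Segment] = []

    def add_segment(a: int, b: int, kind: str, centerline: np.ndarray) -> None:
        segments.append(
            Segment(
                id=len(segments),
                node_a=a,
                node_b=b,
                kind=kind,
                centerline=np.asarray(centerline, dtype=float),
            )
        )

    # crown limbs: arc between adjacent extrema of the ring sinusoid
    for ring in range(design.n_rings):
        phi = _ring_phase(ring, n)
        z0 = _ring_z(design, ring)
        for j in range(2 * n):
            t = np.linspace(j * np.pi / n, (j + 1) * np.pi / n, _LIMB_SAMPLES)
            theta = phi + t
            poly = np.column_stack(
                [
                    r_c * np.cos(theta),
                    r_c * np.sin(theta),
                    z0 + amp * np.cos(n * t),
                ]
            )
            add_segment(
                node_index[(ring, j)],
                node_index[(ring, (j + 1) % (2 * n))],
                "limb",
                poly,
            )

    # links: straight axial bridges at evenly spaced aligned peak/valley pairs
    for ring in range(design.n_rings - 1):
        for li in range(design.links_between_rings):
            peak = int(np.floor(n * li / design.links_between_rings))
            j = 2 * peak  # peak node index on ring
            j_next = (j - 1) % (2 * n) if ring % 2 == 0 else (j + 1) % (2 * n)
            a = node_index[(ring, j)]
            b = node_index[(ring + 1, j_next)]
            pa, pb = nodes[a], nodes[b]
            poly = np.linspace(pa, pb, 5)
            add_segment(a, b, "link", poly)

    graph = DesignGraph(design=design, nodes=nodes, segments=segments)
    assert graph.n_segments == segment_count(design)
    return graph


def nominal_volume(design: ScaffoldDesign, graph: DesignGraph | None = None) -> float:
    """As-manufactured scaffold volume, mm^3.

    Sum over segments of centerline length x width x thickness.  Overlap at
    junctions is not subtracted; see :func:`mgscaffold.phantom.measured_volume`
    for the voxel-union measure.
    """
    if graph is None:
        graph = build_design(design)
    return graph.total_centerline_length() * design.strut_width * design.strut_thickness


def straight_strut_graph(
    design: ScaffoldDesign | None = None,
    length: float = 2.0,
    offset_xy: tuple[float, float] = (0.0, 0.0),
    z0: float = 0.0,
) -> DesignGraph:
    """Single straight axial strut, for calibration and oracle tests.

    ``offset_xy`` shifts the centerline off the volume axis, which controls
    the sub-voxel grid phase of the rasterized cross-section.
    """
    if design is None:
        design = ScaffoldDesign(n_rings=1)
    x, y = offset_xy
    poly = np.array([[x, y, z0], [x, y, z0 + length]], dtype=float)
    seg = Segment(id=0, node_a=0, node_b=1, kind="limb", centerline=poly)
    return DesignGraph(design=design, nodes=poly.copy(), segments=[seg])


def design_from_dict(d: dict) -> ScaffoldDesign:
    """Build a design from a (config-file) mapping; unknown keys rejected."""
    allowed = set(ScaffoldDesign.__dataclass_fields__)
    unknown = set(d) - allowed
    if unknown:
        raise DesignError(f"unknown design parameter(s): {sorted(unknown)}")
    return ScaffoldDesign(**d)
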