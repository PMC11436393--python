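"""Synthetic micro-CT phantom generation.

Voxelizes a scaffold design graph into a five-class label volume, applies a
degradation state (isotropic surface erosion with product substitution, plus
discrete segment cuts), and renders a grayscale volume with partial-volume
blur and additive noise.

Label codes (uint8):

====================  ====  ================================================
class                 code  rendered appearance
====================  ====  ================================================
BACKGROUND            0     air / lumen
TISSUE                1     vessel wall
PRODUCT_LUCENT        2     low-attenuation degradation product (MgO-like)
MG_ALLOY              3     metallic strut backbone
PRODUCT_DENSE         4     high-attenuation product (Ca/P-salt-like)
====================  ====  ================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .geometry import DesignGraph
from .volio import VoxelVolume

__all__ = [
    "BACKGROUND",
    "TISSUE",
    "PRODUCT_LUCENT",
    "MG_ALLOY",
    "PRODUCT_DENSE",
    "CLASS_NAMES",
    "LabelVolume",
    "MaterialModel",
    "DegradationState",
    "PhantomError",
    "voxelize",
    "apply_degradation",
    "render_grayscale",
    "measured_volume",
]

BACKGROUND, TISSUE, PRODUCT_LUCENT, MG_ALLOY, PRODUCT_DENSE = range(5)
CLASS_NAMES = {
    BACKGROUND: "BACKGROUND",
    TISSUE: "TISSUE",
    PRODUCT_LUCENT: "PRODUCT_LUCENT",
    MG_ALLOY: "MG_ALLOY",
    PRODUCT_DENSE: "PRODUCT_DENSE",
}


class PhantomError(ValueError):
    pass


@dataclass
class LabelVolume:
    """Per-voxel material classes plus the segment-id map from voxelization."""

    labels: np.ndarray  # uint8, (nz, ny, nx)
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    segment_ids: np.ndarray | None = None  # int32, -1 outside struts

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise PhantomError(f"labels must be 3D, got shape {self.labels.shape}")
        if not self.spacing > 0:
            raise PhantomError(f"spacing must be > 0, got {self.spacing}")
        if self.labels.size and self.labels.max() > PRODUCT_DENSE:
            raise PhantomError("labels contain codes outside the five classes")

    @property
    def dims(self) -> tuple[int, int, int]:
        nz, ny, nx = self.labels.shape
        return (nx, ny, nz)

    def class_mask(self, *classes: int) -> np.ndarray:
        return np.isin(self.labels, classes)

    def mg_voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels == MG_ALLOY))

    def as_voxel_volume(self) -> VoxelVolume:
        return VoxelVolume(values=self.labels, spacing=self.spacing, origin=self.origin)


@dataclass(frozen=True)
class MaterialModel:
    """Per-class mean grayvalue and within-class texture spread (a.u.).

    Means must be strictly increasing in the order background < tissue <
    lucent product < Mg alloy < dense product (radiolucency ordering).
    """

    means: tuple[float, float, float, float, float] = (0.0, 30.0, 60.0, 100.0, 140.0)
    spreads: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.means) != 5 or len(self.spreads) != 5:
            raise PhantomError("material model needs 5 means and 5 spreads")
        if not all(b > a for a, b in zip(self.means, self.means[1:])):
            raise PhantomError(
                f"class means must be strictly increasing, got {self.means}"
            )
        if any(s < 0 for s in self.spreads):
            raise PhantomError("spreads must be >= 0")

    def mean_of(self, cls: int) -> float:
        return self.means[cls]


@dataclass(frozen=True)
class DegradationState:
    """Degradation applied to a pristine phantom at one timepoint."""

    time_months: float = 0.0
    erosion_depth: float = 0.0  # mm, = k * t under the isotropic model
    substitution_fraction_dense: float = 0.5
    substitution_fraction_lucent: float = 0.3
    cut_segment_ids: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erosion_depth < 0:
            raise PhantomError(f"erosion_depth must be >= 0, got {self.erosion_depth}")
        fd, fl = self.substitution_fraction_dense, self.substitution_fraction_lucent
        if fd < 0 or fl < 0 or fd + fl > 1.0 + 1e-12:
            raise PhantomError(
                f"substitution fractions must be >= 0 and sum <= 1 (got {fd}, {fl})"
            )
        object.__setattr__(self, "cut_segment_ids", frozenset(self.cut_segment_ids))


# ---------------------------------------------------------------------------
# voxelization

def _sweep_subsegment(
    seg_ids: np.ndarray,
    seg_id: int,
    p0: np.ndarray,
    p1: np.ndarray,
    half_h: float,
    half_w: float,
    spacing: float,
    origin: np.ndarray,
    cap: float,
) -> None:
    """Mark voxels inside the rectangular sweep from p0 to p1 (in place).

    The cross-section is oriented with thickness along the (projected) radial
    direction and width along the binormal; ``cap`` extends the sweep past
    both ends to close wedge gaps at polyline bends and junctions.
    """
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0:
        return
    t_hat = d / length
    mid = 0.5 * (p0 + p1)
    radial = np.array([mid[0], mid[1], 0.0])
    radial -= t_hat * float(radial @ t_hat)
    nrm = np.linalg.norm(radial)
    if nrm < 1e-12:  # centered on the axis: any transverse frame works
        radial = np.array([1.0, 0.0, 0.0]) - t_hat * t_hat[0]
        nrm = np.linalg.norm(radial)
    e1 = radial / nrm
    e2 = np.cross(t_hat, e1)

    margin = np.hypot(half_h, half_w) + cap
    lo = np.minimum(p0, p1) - margin
    hi = np.maximum(p0, p1) + margin
    nz, ny, nx = seg_ids.shape
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, [nx, ny, nz])
    if np.any(i0 >= i1):
        return

    xs = origin[0] + spacing * np.arange(i0[0], i1[0])
    ys = origin[1] + spacing * np.arange(i0[1], i1[1])
    zs = origin[2] + spacing * np.arange(i0[2], i1[2])
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    qx, qy, qz = X - p0[0], Y - p0[1], Z - p0[2]
    u = qx * t_hat[0] + qy * t_hat[1] + qz * t_hat[2]
    a = qx * e1[0] + qy * e1[1] + qz * e1[2]
    b = qx * e2[0] + qy * e2[1] + qz * e2[2]
    inside = (
        (u >= -cap)
        & (u <= length + cap)
        & (np.abs(a) <= half_h)
        & (np.abs(b) <= half_w)
    )
    view = seg_ids[i0[2]:i1[2], i0[1]:i1[1], i0[0]:i1[0]]
    np.copyto(view, seg_id, where=inside & (view < 0))


def _rasterize_segments(
    graph: DesignGraph,
    shape: tuple[int, int, int],
    origin: np.ndarray,
    spacing: float,
    half_h: float,
    half_w: float,
    cap_inner: float,
    cap_end: float,
) -> np.ndarray:
    """Segment-id map (-1 outside) for the swept rectangles of a graph."""
    seg_ids = np.full(shape, -1, dtype=np.int32)
    if half_h <= 0 or half_w <= 0:
        return seg_ids
    for seg in graph.segments:
        pts = seg.centerline
        last = len(pts) - 2
        for i in range(last + 1):
            cap = cap_end if (i == 0 or i == last) else cap_inner
            _sweep_subsegment(
                seg_ids, seg.id, pts[i], pts[i + 1], half_h, half_w,
                spacing, origin, cap,
            )
    return seg_ids


def voxelize(
    graph: DesignGraph,
    spacing: float = 0.02,
    strut_width: float | None = None,
    strut_thickness: float | None = None,
    tissue_inner_margin: float = 0.15,
    tissue_outer_margin: float = 0.35,
    pad: float = 0.25,
    origin_shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LabelVolume:
    """Rasterize a design graph into a label volume.

    Struts become MG_ALLOY where the voxel center lies inside the rectangular
    cross-section swept along a segment centerline; a coaxial tissue annulus
    surrounds the device; everything else is background.  Requires at least
    four voxels across the strut thickness.
    """
    design = graph.design
    w = design.strut_width if strut_width is None else strut_width
    h = design.strut_thickness if strut_thickness is None else strut_thickness
    if spacing > h / 4.0 + 1e-12:
        raise PhantomError(
            f"spacing {spacing} mm too coarse for strut thickness {h} mm; "
            f"need spacing <= {h / 4.0:.4g} mm (>= 4 voxels across a strut)"
        )

    r_out = design.nominal_diameter / 2.0 + tissue_outer_margin
    half_xy = r_out + pad
    if graph.segments:
        z_lo = min(float(s.centerline[:, 2].min()) for s in graph.segments) - pad
        z_hi = max(float(s.centerline[:, 2].max()) for s in graph.segments) + pad
    else:
        z_lo, z_hi = -pad, pad
    nx = ny = int(np.ceil(2 * half_xy / spacing)) + 1
    nz = int(np.ceil((z_hi - z_lo) / spacing)) + 1
    origin = np.array(
        [-(nx - 1) / 2.0 * spacing, -(ny - 1) / 2.0 * spacing, z_lo]
    ) + np.asarray(origin_shift, dtype=float)

    seg_ids = _rasterize_segments(
        graph, (nz, ny, nx), origin, spacing,
        half_h=h / 2.0, half_w=w / 2.0,
        cap_inner=spacing / 2.0,  # close bend wedges between polyline pieces
        cap_end=h / 2.0,  # close junction wedges at segment ends
    )

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    # coaxial tissue annulus straddling the strut centerline radius
    x = origin[0] + spacing * np.arange(nx)
    y = origin[1] + spacing * np.arange(ny)
    rr = np.hypot(*np.meshgrid(y, x, indexing="ij"))  # (ny, nx)
    r_c = design.centerline_radius
    annulus = (rr >= r_c - h / 2.0 - tissue_inner_margin) & (rr <= r_out)
    labels[:, annulus] = TISSUE
    labels[seg_ids >= 0] = MG_ALLOY

    return LabelVolume(
        labels=labels, spacing=spacing, origin=tuple(origin), segment_ids=seg_ids
    )


def measured_volume(volume: LabelVolume, *classes: int) -> float:
    """Voxel-union volume (mm^3) of the given classes (default: MG_ALLOY)."""
    if not classes:
        classes = (MG_ALLOY,)
    return float(np.count_nonzero(volume.class_mask(*classes))) * volume.spacing**3


# ---------------------------------------------------------------------------
# degradation

def _eroded_mask_geometric(
    volume: LabelVolume, graph: DesignGraph, depth: float
) -> np.ndarray:
    """Mg voxels lost when every exposed face recedes by ``depth``.

    The eroded solid is re-rasterized as the sweep of the cross-section
    shrunk by ``depth`` on every side (erosion of a swept rectangle is the
    sweep of the eroded rectangle), so the voxel fraction tracks the
    closed-form area law without distance-map quantization artifacts.
    """
    design = graph.design
    half_h = design.strut_thickness / 2.0 - depth
    half_w = design.strut_width / 2.0 - depth
    mg = volume.labels == MG_ALLOY
    if half_h <= 0 or half_w <= 0:
        return mg
    keep_ids = _rasterize_segments(
        graph, volume.labels.shape, np.asarray(volume.origin), volume.spacing,
        half_h=half_h, half_w=half_w,
        cap_inner=volume.spacing / 2.0,
        cap_end=half_h,
    )
    return mg & (keep_ids < 0)


def _eroded_mask_edt(
    volume: LabelVolume, graph: DesignGraph, depth: float, seed: int
) -> np.ndarray:
    """EDT-based erosion with stochastic partial-layer removal.

    Voxel-center distances are quantized to whole layers on grid-aligned
    faces; the layer straddled by the erosion front is removed with the
    probability that matches the closed-form remaining rectangle area in
    expectation.  The per-voxel uniform field depends only on the seed, so
    deeper fronts remove supersets of shallower ones.  Tilted faces
    rasterize to staircases whose EDT under-measures depth, so this method
    over-erodes obliquely oriented struts by up to half a voxel per face;
    the geometric method is free of that bias.
    """
    mg = volume.labels == MG_ALLOY
    if not mg.any():
        return np.zeros_like(mg)
    nz_idx = np.nonzero(mg)
    sl = tuple(
        slice(max(int(ix.min()) - 1, 0), min(int(ix.max()) + 2, n))
        for ix, n in zip(nz_idx, mg.shape)
    )
    dist = np.zeros(mg.shape, dtype=np.float32)
    dist[sl] = distance_transform_edt(mg[sl], sampling=volume.spacing)
    s = volume.spacing
    w = graph.design.strut_width
    h = graph.design.strut_thickness

    def rect_area(x):
        return np.clip(1.0 - 2.0 * x / w, 0.0, None) * np.clip(
            1.0 - 2.0 * x / h, 0.0, None
        )

    d0 = np.maximum(dist - s, 0.0)
    a0, a1 = rect_area(d0), rect_area(dist)
    a_front = rect_area(np.clip(depth, d0, dist))
    denom = a0 - a1
    with np.errstate(divide="ignore", invalid="ignore"):
        p_remove = np.where(denom > 0, (a0 - a_front) / denom, 0.0)
    p_remove = np.clip(np.nan_to_num(p_remove), 0.0, 1.0)
    p_remove[dist <= depth] = 1.0
    u_field = np.ones(mg.shape, dtype=np.float64)
    u_field[sl] = np.random.default_rng(seed).random(mg[sl].shape)
    return mg & (u_field < p_remove)


def apply_degradation(
    volume: LabelVolume,
    graph: DesignGraph,
    state: DegradationState,
    method: str = "geometric",
) -> LabelVolume:
    """Erode the Mg phase isotropically and remove cut segments.

    Mg voxels within ``erosion_depth`` of the original strut surface are
    reassigned to PRODUCT_DENSE / PRODUCT_LUCENT / TISSUE according to the
    substitution fractions (seeded per-voxel draw); all voxels of segments in
    the cut list become TISSUE.  ``method`` selects how the receded surface
    is located: ``"geometric"`` re-rasterizes the shrunken strut sweep
    (sub-voxel exact), ``"edt"`` thresholds the Euclidean distance transform
    of the pristine exterior (quantized to voxel layers).  Either way the
    front derives from the pristine surface, so Mg voxel sets are nested
    across increasing depths.
    """
    valid_ids = set(graph.segment_ids())
    unknown = set(state.cut_segment_ids) - valid_ids
    if unknown:
        raise PhantomError(f"unknown segment id(s) in cut list: {sorted(unknown)}")
    if method not in ("geometric", "edt"):
        raise PhantomError(f"unknown erosion method {method!r}")

    labels = volume.labels.copy()
    mg = labels == MG_ALLOY

    if state.erosion_depth > 0 and mg.any():
        if method == "geometric":
            eroded = _eroded_mask_geometric(volume, graph, state.erosion_depth)
        else:
            eroded = _eroded_mask_edt(
                volume, graph, state.erosion_depth, state.seed
            )
        idx = np.flatnonzero(eroded.ravel())
        rng = np.random.default_rng(state.seed + 1)
        u = rng.random(idx.size)
        fd = state.substitution_fraction_dense
        fl = state.substitution_fraction_lucent
        dest = np.full(idx.size, TISSUE, dtype=np.uint8)
        dest[u < fd] = PRODUCT_DENSE
        dest[(u >= fd) & (u < fd + fl)] = PRODUCT_LUCENT
        labels.ravel()[idx] = dest

    seg_ids = volume.segment_ids
    if state.cut_segment_ids:
        if seg_ids is None:
            raise PhantomError("volume has no segment-id map; cannot apply cuts")
        cut = np.isin(seg_ids, list(state.cut_segment_ids))
        labels[cut] = TISSUE
        seg_ids = np.where(cut, np.int32(-1), seg_ids)

    return LabelVolume(
        labels=labels,
        spacing=volume.spacing,
        origin=volume.origin,
        segment_ids=seg_ids,
    )


# ---------------------------------------------------------------------------
# rendering

def render_grayscale(
    volume: LabelVolume,
    material: MaterialModel | None = None,
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelVolume:
    """Render a label volume to grayscale.

    Class means (plus seeded within-class texture) are convolved with an
    isotropic Gaussian PSF of ``psf_sigma`` voxels, then zero-mean Gaussian
    noise of sd ``noise_sd`` is added.
    """
    if material is None:
        material = MaterialModel()
    if psf_sigma < 0 or noise_sd < 0:
        raise PhantomError("psf_sigma and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    means = np.asarray(material.means, dtype=np.float32)
    img = means[volume.labels]
    spreads = np.asarray(material.spreads, dtype=np.float32)
    if np.any(spreads > 0):
        img = img + spreads[volume.labels] * rng.standard_normal(
            volume.labels.shape, dtype=np.float32
        )
    if psf_sigma > 0:
        img = gaussian_filter(img, sigma=psf_sigma)
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    return VoxelVolume(
        values=img.astype(np.float32), spacing=volume.spacing, origin=volume.origin
    )
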