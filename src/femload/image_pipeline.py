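"""Grayscale volume -> aligned, segmented, cartilage-capped model.

Mirrors the image-processing front end of micro-FE joint load prediction:
Gaussian smoothing, block-mean resampling and fixed-threshold segmentation;
a femoral-head sphere fit; an implant-style anatomical frame built from the
shaft axis and the neck cross-section minimum; and finally rotation into
that frame, cropping to 1.5 head radii and addition of a spherical
cartilage layer used to apply joint contact loads.

Axis convention of the anatomical frame (rows of ``axes``):
``ml`` points medial, ``ap`` anterior(ish), ``vert`` points proximally
(from the shaft towards the head). The triad is right-handed and
orthonormal to 1e-9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import VoxelImage

__all__ = [
    "AnatomicalFrame",
    "SegmentedModel",
    "LABEL_BACKGROUND",
    "LABEL_BONE",
    "LABEL_CARTILAGE",
    "preprocess",
    "fit_head_sphere",
    "build_frame",
    "align_crop_cartilage",
    "mirror_left_to_right",
    "largest_component",
]

LABEL_BACKGROUND = 0
LABEL_BONE = 1
LABEL_CARTILAGE = 2


@dataclass
class AnatomicalFrame:
    """Implant-style anatomical coordinate frame of a proximal femur.

    ``axes`` holds the unit row vectors (medio-lateral, anterior-posterior,
    vertical) expressed in the coordinate system of the image the frame was
    built from. ``head_centre`` is the origin of the anatomical frame.
    """

    head_centre: np.ndarray
    head_radius: float
    neck_midpoint: np.ndarray
    axes: np.ndarray  # 3x3, rows = (ml, ap, vert)
    fit_rms: float = 0.0

    def __post_init__(self) -> None:
        self.head_centre = np.asarray(self.head_centre, dtype=float)
        self.neck_midpoint = np.asarray(self.neck_midpoint, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not self.head_radius > 0:
            raise ValueError("head_radius must be > 0")
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal to 1e-9")

    @property
    def ml(self) -> np.ndarray:
        return self.axes[0]

    @property
    def ap(self) -> np.ndarray:
        return self.axes[1]

    @property
    def vertical(self) -> np.ndarray:
        return self.axes[2]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> frame coordinates centred on the head."""
        return (np.asarray(points) - self.head_centre) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.axes + self.head_centre

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# anatomical frame (mm); rows of axes = ml, ap, vert\n")
            fh.write("head_centre " + " ".join(f"{v:.9g}" for v in self.head_centre) + "\n")
            fh.write(f"head_radius {self.head_radius:.9g}\n")
            fh.write("neck_midpoint " + " ".join(f"{v:.9g}" for v in self.neck_midpoint) + "\n")
            for row in self.axes:
                fh.write("axis " + " ".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnatomicalFrame":
        centre = radius = neck = None
        axes = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            key, *vals = line.split()
            vals = [float(v) for v in vals]
            if key == "head_centre":
                centre = vals
            elif key == "head_radius":
                radius = vals[0]
            elif key == "neck_midpoint":
                neck = vals
            elif key == "axis":
                axes.append(vals)
        return cls(centre, radius, neck, np.asarray(axes))


@dataclass
class SegmentedModel:
    """Aligned label volume {background, bone, cartilage} in frame coords.

    The label grid lives in the anatomical frame: axis 0 = medio-lateral
    (increasing medially), axis 1 = anterior-posterior, axis 2 = vertical
    (increasing proximally). The femoral head centre sits at physical
    coordinate (0, 0, 0); ``labels.origin`` locates the grid's first voxel
    centre relative to it. The lateral and distal crop faces are the low-ml
    and low-vert faces of the grid.
    """

    labels: VoxelImage
    frame: AnatomicalFrame
    cartilage_thickness: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cartilage_thickness > 0:
            raise ValueError("cartilage_thickness must be > 0")

    @property
    def voxel_size(self) -> float:
        return self.labels.voxel_size

    def element_centres(self) -> np.ndarray:
        """(n, 3) physical centres of all voxels, head centre at origin."""
        cx, cy, cz = self.labels.voxel_centres()
        return np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(
    img: VoxelImage,
    threshold: float,
    filter_support: float = 2.0,
    filter_sigma: float = 1.6,
    resample_factor: int = 1,
    boundary: str = "nearest",
) -> VoxelImage:
    """Gaussian filter, block-mean resample and threshold a grayscale volume.

    ``filter_sigma`` is in voxels; ``filter_support`` is the truncation
    radius of the kernel in voxels (support 2 at sigma 1.6 reproduces the
    scanner-software convention). Resampling is mean-pooling of grey values
    by an integer factor, applied after filtering and before thresholding;
    voxels with grey value >= ``threshold`` become bone.
    """
    if resample_factor != int(resample_factor) or resample_factor < 1:
        raise ValueError(f"resample_factor must be a positive integer, got {resample_factor}")
    resample_factor = int(resample_factor)
    vals = np.asarray(img.values, dtype=float)
    if filter_sigma > 0:
        vals = ndimage.gaussian_filter(
            vals, sigma=filter_sigma, truncate=filter_support / filter_sigma, mode=boundary
        )
    origin = img.origin.copy()
    if resample_factor > 1:
        f = resample_factor
        nx, ny, nz = (s - s % f for s in vals.shape)
        vals = vals[:nx, :ny, :nz]
        vals = vals.reshape(nx // f, f, ny // f, f, nz // f, f).mean(axis=(1, 3, 5))
        origin = origin + (f - 1) / 2 * img.voxel_size
    binary = (vals >= threshold).astype(np.uint8)
    meta = dict(img.meta)
    if not binary.any():
        warnings.warn("preprocess produced an all-background segmentation")
        meta["all_background"] = True
    return VoxelImage(binary, img.voxel_size * resample_factor, origin, meta)


def mirror_left_to_right(img: VoxelImage) -> VoxelImage:
    """Mirror a left specimen across the frontal plane (flip first axis)."""
    return img.copy_with(values=img.values[::-1].copy())


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 6-connected foreground component."""
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask.astype(bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == np.argmax(counts)


# ---------------------------------------------------------------------------
# head sphere fit

def _surface_voxels(binary: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(binary, structure=ndimage.generate_binary_structure(3, 1))
    return binary.astype(bool) & ~eroded


def _fit_sphere_lsq(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit; raises on degenerate point sets."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError(f"sphere fit needs >= 4 points, got {len(points)}")
    mean = points.mean(axis=0)
    p = points - mean  # centre data for conditioning
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("degenerate (coplanar/collinear) point set for sphere fit")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3] + mean
    radius = float(np.sqrt(sol[3] + (sol[:3] ** 2).sum()))
    r = np.linalg.norm(points - centre, axis=1)
    rms = float(np.sqrt(np.mean((r - radius) ** 2)))
    return centre, radius, rms


def fit_head_sphere(
    binary: VoxelImage,
    head_region_hint: tuple[slice, slice, slice] | None = None,
    pole_axis: np.ndarray | None = None,
    window_deg: float = 90.0,
) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through the femoral-head surface voxels.

    Surface voxels are selected within an angular window around the
    proximal pole (default: the proximal hemisphere) to avoid neck
    contamination; the selection is refined once using the first fit.
    Returns ``(centre_mm, radius_mm, rms_residual_mm)``.
    """
    mask = binary.values.astype(bool)
    if head_region_hint is not None:
        sub = np.zeros_like(mask)
        sub[head_region_hint] = True
        mask = mask & sub
    if not mask.any():
        raise ValueError("no foreground voxels in the head region")
    surf = _surface_voxels(mask)
    idx = np.argwhere(surf)
    pts = binary.origin + idx * binary.voxel_size
    pole = np.asarray(pole_axis if pole_axis is not None else [0.0, 0.0, 1.0], dtype=float)
    pole = pole / np.linalg.norm(pole)

    # initial centre guess: centroid of foreground in the proximal quarter
    fg = np.argwhere(mask)
    proj = (binary.origin + fg * binary.voxel_size) @ pole
    top = proj >= proj.min() + 0.75 * (proj.max() - proj.min())
    centre = (binary.origin + fg[top] * binary.voxel_size).mean(axis=0)

    cos_win = np.cos(np.deg2rad(window_deg))
    radius = rms = None
    for _ in range(2):
        d = pts - centre
        dn = np.linalg.norm(d, axis=1)
        keep = dn > 0
        sel = np.zeros(len(pts), dtype=bool)
        sel[keep] = (d[keep] @ pole) / dn[keep] >= cos_win
        if sel.sum() < 4:
            sel = np.ones(len(pts), dtype=bool)
        centre, radius, rms = _fit_sphere_lsq(pts[sel])
    return centre, radius, rms


# ---------------------------------------------------------------------------
# anatomical frame

def build_frame(
    binary: VoxelImage,
    shaft_section_mm: float = 40.0,
    head_region_hint: tuple[slice, slice, slice] | None = None,
    neck_slab_mm: float | None = None,
) -> AnatomicalFrame:
    """Construct the implant-style frame from a binary proximal femur.

    The vertical axis is the line fitted to shaft slice centroids over a
    distal section (default 40 mm; scale down for small synthetic domains).
    The neck axis joins the head centre to the centroid of the smallest
    cross-section along the head-to-shaft search axis; the AP and ML axes
    complete the right-handed orthonormal triad.
    """
    mask = binary.values.astype(bool)
    if not mask.any():
        raise ValueError("empty structure")
    h = binary.voxel_size

    # shaft axis from distal slice centroids (image z assumed roughly distal-proximal)
    zs = np.where(mask.any(axis=(0, 1)))[0]
    n_slices = max(int(round(shaft_section_mm / h)), 3)
    distal = zs[: min(n_slices, len(zs))]
    counts = np.array([np.count_nonzero(mask[:, :, k]) for k in distal])
    # an obliquely cut shaft end yields partial cross-sections whose
    # centroids are off-axis; keep only (near-)complete slices
    full = counts >= 0.8 * np.median(counts)
    if full.sum() >= 3:
        distal = distal[full]
    cents = []
    for k in distal:
        ij = np.argwhere(mask[:, :, k])
        cents.append([ij[:, 0].mean(), ij[:, 1].mean(), k])
    cents = np.asarray(cents, dtype=float) * h + binary.origin
    centroid = cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents - centroid)
    vertical = vt[0] / np.linalg.norm(vt[0])

    centre, radius, rms = fit_head_sphere(binary, head_region_hint=head_region_hint)
    if vertical @ (centre - centroid) < 0:  # point proximally, towards the head
        vertical = -vertical

    # neck search: slide a slab from the head towards the shaft and find the
    # smallest cross-section; the search axis is refined towards the waist
    # centroid found in the previous pass (the neck is oblique to both the
    # shaft axis and the head-to-shaft-foot direction)
    idx = np.argwhere(mask)
    pts = binary.origin + idx * binary.voxel_size
    slab = neck_slab_mm if neck_slab_mm is not None else max(h, radius / 10.0)
    target = pts.mean(axis=0)  # whole-bone centroid as the initial aim
    neck_mid = None
    for _pass in range(3):
        search = target - centre
        if np.linalg.norm(search) < 1e-9:
            raise ValueError("neck search axis ill-defined")
        search = search / np.linalg.norm(search)
        t = (pts - centre) @ search
        stations = np.arange(0.8 * radius, 3.0 * radius, slab)
        if len(stations) < 3:
            raise ValueError("no room for a neck between head and shaft")
        areas = np.full(len(stations), np.nan)
        for i, ti in enumerate(stations):
            in_slab = np.abs(t - ti) <= slab / 2
            if in_slab.any():
                # exclude matter far off-axis (e.g. greater trochanter)
                q = pts[in_slab] - (centre + ti * search)
                r_perp = np.linalg.norm(q - np.outer(q @ search, search), axis=1)
                n_in = np.count_nonzero(r_perp <= 1.5 * radius)
                if n_in:
                    areas[i] = n_in * h * h
        finite = np.where(np.isfinite(areas))[0]
        if len(finite) < 3:
            raise ValueError("no interior minimum of neck cross-sectional area found")
        f0, f1 = finite[0], finite[-1]
        seg_areas = areas[f0:f1 + 1]
        seg_areas = np.where(np.isfinite(seg_areas), seg_areas, np.inf)
        smooth = seg_areas.copy()
        smooth[1:-1] = (seg_areas[:-2] + seg_areas[1:-1] + seg_areas[2:]) / 3.0
        kk = 1 + int(np.argmin(smooth[1:-1]))
        if not np.isfinite(smooth[kk]) or not (smooth[kk] < smooth[0] and smooth[kk] < smooth[-1]):
            raise ValueError("no interior minimum of neck cross-sectional area found")
        k = f0 + kk
        # waist centroid over a band around the minimum for stability
        in_slab = np.abs(t - stations[k]) <= 1.5 * slab
        q = pts[in_slab] - (centre + stations[k] * search)
        r_perp = np.linalg.norm(q - np.outer(q @ search, search), axis=1)
        neck_mid = pts[in_slab][r_perp <= 1.5 * radius].mean(axis=0)
        target = neck_mid

    neck_axis = centre - neck_mid
    neck_axis = neck_axis / np.linalg.norm(neck_axis)
    ap = np.cross(vertical, neck_axis)
    if np.linalg.norm(ap) < 1e-9:
        raise ValueError("neck axis parallel to shaft axis; frame ill-defined")
    ap = ap / np.linalg.norm(ap)
    ml = np.cross(ap, vertical)
    ml = ml / np.linalg.norm(ml)
    axes = np.vstack([ml, ap, vertical])
    return AnatomicalFrame(centre, radius, neck_mid, axes, fit_rms=rms)


# ---------------------------------------------------------------------------
# alignment, cropping, cartilage layer

def align_crop_cartilage(
    binary: VoxelImage,
    frame: AnatomicalFrame,
    crop_factor: float = 1.5,
    cartilage_thickness: float = 2.2,
    margin_voxels: int = 2,
    articular_limit_deg: float = 125.0,
    neck_exclusion_deg: float = 45.0,
) -> SegmentedModel:
    """Resample into the anatomical frame, crop, and add the cartilage cap.

    The crop box extends ``crop_factor * R`` lateral and distal of the head
    centre and one head radius plus the cartilage layer in the remaining
    directions. Cartilage fills background voxels between the bone surface
    and the outer sphere of radius ``R + cartilage_thickness`` over the
    articular region -- directions within ``articular_limit_deg`` of the
    proximal pole; bone naturally extends beyond the outer sphere towards
    the neck and shaft, so only bone penetrating the articular surface
    raises (increase the thickness).
    """
    if crop_factor < 1:
        raise ValueError("crop_factor must be >= 1")
    if cartilage_thickness <= 0:
        raise ValueError("cartilage_thickness must be > 0")
    h = binary.voxel_size
    R = frame.head_radius
    r_out = R + cartilage_thickness
    m = margin_voxels * h
    lo = np.array([-crop_factor * R, -(r_out + m), -crop_factor * R])
    hi = np.array([r_out + m, r_out + m, r_out + m])
    n = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    origin_local = lo + h / 2

    axes_grid = [origin_local[a] + h * np.arange(n[a]) for a in range(3)]
    local = np.stack(np.meshgrid(*axes_grid, indexing="ij"), axis=-1)
    world = local.reshape(-1, 3) @ frame.axes + frame.head_centre
    idx = (world - binary.origin) / h
    vals = ndimage.map_coordinates(
        binary.values.astype(np.uint8), idx.T, order=0, mode="constant", cval=0
    ).reshape(tuple(n))
    bone = vals > 0

    dist = np.linalg.norm(local, axis=-1)
    local3 = local.reshape(-1, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        polar = np.degrees(
            np.arccos(np.clip(local3[:, 2] / np.maximum(dist.ravel(), 1e-12), -1.0, 1.0))
        ).reshape(dist.shape)
    articular = polar <= articular_limit_deg
    # the head-neck junction is not articular: exclude a cone around the
    # direction in which the neck attaches to the head
    attach = frame.to_local(frame.neck_midpoint)
    attach_norm = np.linalg.norm(attach)
    if attach_norm > 1e-9:
        attach = attach / attach_norm
        with np.errstate(invalid="ignore"):
            ang_neck = np.degrees(
                np.arccos(np.clip((local3 @ attach) / np.maximum(dist.ravel(), 1e-12), -1, 1))
            ).reshape(dist.shape)
        articular &= ang_neck >= neck_exclusion_deg
    outside = bone & (dist > r_out) & articular
    if outside.any():
        raise ValueError(
            f"{int(outside.sum())} bone voxels penetrate the articular surface "
            f"(outer sphere R + {cartilage_thickness} mm); increase cartilage_thickness"
        )
    r_in = max(R - cartilage_thickness, 0.0)
    cart = ~bone & (dist <= r_out) & (dist >= r_in) & articular

    labels = np.zeros(tuple(n), dtype=np.uint8)
    labels[bone] = LABEL_BONE
    labels[cart] = LABEL_CARTILAGE
    local_frame = AnatomicalFrame(
        head_centre=np.zeros(3),
        head_radius=R,
        neck_midpoint=frame.to_local(frame.neck_midpoint),
        axes=np.eye(3),
        fit_rms=frame.fit_rms,
    )
    return SegmentedModel(
        labels=VoxelImage(labels, h, origin_local),
        frame=local_frame,
        cartilage_thickness=cartilage_thickness,
        meta={"crop_factor": crop_factor},
    )
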