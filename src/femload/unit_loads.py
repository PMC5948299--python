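"""Unit joint-load cases: directions, sphere-cone load patches, nodal forces.

A unit load case pushes on the femoral head through the cartilage layer:
its load patch is the intersection of the spherical articular surface with
a cone (default full opening angle 40 deg) about the load direction, and
the nodal force vectors are scaled so the resultant magnitude is exactly
the configured value (default 1000 N).

Load directions live in the frontal (ml-vert) plane and are given as the
inclination from the vertical axis, positive towards medial. Nodal forces
point into the head (compressive), i.e. the resultant of the applied
forces lies along -d for load direction d; predicted joint load vectors
are reported along +d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_pipeline import LABEL_BACKGROUND, LABEL_CARTILAGE, SegmentedModel

__all__ = ["LoadPatchSpec", "LoadCase", "make_load_set", "build_load_case", "direction_vector"]

DISTRIBUTIONS = ("uniform_normal", "uniform_parallel", "hertz_parallel")


@dataclass(frozen=True)
class LoadPatchSpec:
    """Geometry and force-distribution recipe of one unit load."""

    inclination: float  # degrees from the vertical axis, frontal plane
    opening_angle: float = 40.0  # full cone apex angle, degrees
    distribution: str = "uniform_normal"
    rotation_offset: float = 0.0  # degrees, about the AP axis

    def __post_init__(self) -> None:
        if not 0 < self.opening_angle < 180:
            raise ValueError("opening_angle must be in (0, 180) degrees")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}; choose from {DISTRIBUTIONS}")

    @property
    def effective_inclination(self) -> float:
        return self.inclination + self.rotation_offset


@dataclass
class LoadCase:
    """One unit load: patch nodes, per-node forces, 1000 N-class resultant."""

    id: int
    spec: LoadPatchSpec
    nodes: np.ndarray  # (m, 3) int lattice indices of loaded nodes
    forces: np.ndarray  # (m, 3) N
    resultant: np.ndarray  # (3,) N, sum of nodal forces (points into the head)
    direction: np.ndarray  # (3,) unit vector +d (head centre -> patch)
    patch_area: float  # mm^2, radial-projected exposed-face area
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# load case {self.id}: inclination {self.spec.effective_inclination} deg, "
                     f"{self.spec.distribution}, area {self.patch_area:.4g} mm^2\n")
            fh.write("# i j k fx_N fy_N fz_N\n")
            for (i, j, k), f in zip(self.nodes, self.forces):
                fh.write(f"{i} {j} {k} {f[0]:.9e} {f[1]:.9e} {f[2]:.9e}\n")


def direction_vector(inclination_deg: float) -> np.ndarray:
    """Unit vector at a frontal-plane inclination from the vertical axis."""
    a = np.deg2rad(inclination_deg)
    return np.array([np.sin(a), 0.0, np.cos(a)])


def make_load_set(
    n_loads: int,
    angle_min: float = -20.0,
    angle_max: float = 100.0,
    rotation_offset: float = 0.0,
    opening_angle: float = 40.0,
    distribution: str = "uniform_normal",
) -> list[LoadPatchSpec]:
    """Equally spaced load directions inclusive of both endpoint angles."""
    if n_loads < 1:
        raise ValueError("n_loads must be >= 1")
    if n_loads == 1:
        if angle_min != angle_max:
            warnings.warn("n_loads=1 with angle_min != angle_max: using angle_min only")
        angles = [angle_min]
    else:
        if angle_min >= angle_max:
            raise ValueError("angle_min must be < angle_max")
        angles = np.linspace(angle_min, angle_max, n_loads)
    return [
        LoadPatchSpec(float(a), opening_angle=opening_angle,
                      distribution=distribution, rotation_offset=rotation_offset)
        for a in angles
    ]


def _outer_surface_faces(model: SegmentedModel) -> tuple[np.ndarray, np.ndarray]:
    """Exposed cartilage faces on the articular (outer) surface.

    Returns face-centre positions (n, 3) mm and outward face normals (n, 3).
    A face is exposed when the neighbouring voxel is background or outside
    the grid; faces are kept only on the outer half of the cartilage shell
    so that marrow-pore faces never enter a load patch.
    """
    labels = model.labels.values
    solid = labels != LABEL_BACKGROUND
    cart = labels == LABEL_CARTILAGE
    h = model.voxel_size
    centres, normals = [], []
    for axis in range(3):
        for sign in (-1, 1):
            nb = np.roll(solid, -sign, axis=axis)
            # voxels at the grid border are exposed in that direction
            edge = [slice(None)] * 3
            edge[axis] = -1 if sign == 1 else 0
            nb[tuple(edge)] = False
            exposed = cart & ~nb
            idx = np.argwhere(exposed).astype(float)
            if len(idx) == 0:
                continue
            pos = model.labels.origin + idx * h
            pos[:, axis] += sign * h / 2
            nrm = np.zeros((len(idx), 3))
            nrm[:, axis] = sign
            centres.append(pos)
            normals.append(nrm)
    if not centres:
        raise ValueError("model has no exposed cartilage surface")
    return np.concatenate(centres), np.concatenate(normals)


def _patch_nodes(model: SegmentedModel, d: np.ndarray, half_angle: float) -> np.ndarray:
    """Lattice nodes of exposed outer cartilage faces inside the cone."""
    labels = model.labels.values
    solid = labels != LABEL_BACKGROUND
    cart = labels == LABEL_CARTILAGE
    h = model.voxel_size
    r_mid = model.frame.head_radius + model.cartilage_thickness / 2
    cos_half = np.cos(half_angle)
    nodes = set()
    corners = {
        0: [(0, 0), (0, 1), (1, 0), (1, 1)],  # offsets in the two other axes
    }
    for axis in range(3):
        ax_other = [a for a in range(3) if a != axis]
        for sign in (-1, 1):
            nb = np.roll(solid, -sign, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = -1 if sign == 1 else 0
            nb[tuple(edge)] = False
            exposed = np.argwhere(cart & ~nb)
            if len(exposed) == 0:
                continue
            pos = model.labels.origin + exposed * h
            pos[:, axis] += sign * h / 2
            rad = np.linalg.norm(pos, axis=1)
            ok = rad >= r_mid
            with np.errstate(invalid="ignore"):
                ok &= (pos @ d) / np.maximum(rad, 1e-12) >= cos_half
            for vox in exposed[ok]:
                base = vox.copy()
                if sign == 1:
                    base[axis] += 1  # node-plane index of the high face
                for o1, o2 in corners[0]:
                    n = base.copy()
                    n[ax_other[0]] += o1
                    n[ax_other[1]] += o2
                    nodes.add(tuple(int(v) for v in n))
    return np.asarray(sorted(nodes), dtype=int)


def node_positions(model: SegmentedModel, nodes: np.ndarray) -> np.ndarray:
    """Physical positions (mm) of lattice nodes; head centre at origin."""
    return model.labels.origin + (np.asarray(nodes, dtype=float) - 0.5) * model.voxel_size


def build_load_case(
    model: SegmentedModel,
    spec: LoadPatchSpec,
    resultant_magnitude: float = 1000.0,
    case_id: int = 0,
) -> LoadCase:
    """Distribute nodal forces over the sphere-cone load patch.

    ``uniform_normal`` applies equal-magnitude forces along the inward
    sphere normal of each node; ``uniform_parallel`` applies equal vectors
    along -d; ``hertz_parallel`` applies vectors along -d weighted by the
    Hertzian profile sqrt(1 - (r/a)^2) with in-plane radius r and contact
    radius a on the articular sphere. In every mode the nodal magnitudes
    are rescaled so the resultant force equals ``resultant_magnitude``.
    """
    d = direction_vector(spec.effective_inclination)
    half = np.deg2rad(spec.opening_angle / 2)
    nodes = _patch_nodes(model, d, half)
    if len(nodes) == 0:
        raise ValueError(
            f"empty load patch at inclination {spec.effective_inclination} deg"
        )
    pos = node_positions(model, nodes)
    rad = np.linalg.norm(pos, axis=1)

    if spec.distribution == "uniform_normal":
        dirs = -pos / rad[:, None]
        w = np.ones(len(nodes))
    else:
        dirs = np.tile(-d, (len(nodes), 1))
        if spec.distribution == "uniform_parallel":
            w = np.ones(len(nodes))
        else:  # hertz_parallel
            r_patch = model.frame.head_radius + model.cartilage_thickness
            a = r_patch * np.sin(half)
            r_in_plane = np.linalg.norm(pos - np.outer(pos @ d, d), axis=1)
            w = np.sqrt(np.clip(1.0 - (r_in_plane / a) ** 2, 0.0, None))
            if not w.any():
                raise ValueError("all Hertz weights vanished; patch degenerate")

    raw = (w[:, None] * dirs).sum(axis=0)
    norm = np.linalg.norm(raw)
    if norm < 1e-12:
        raise ValueError("nodal forces cancel; cannot scale to target resultant")
    forces = w[:, None] * dirs * (resultant_magnitude / norm)
    resultant = forces.sum(axis=0)

    meta: dict = {}
    achieved = -resultant / np.linalg.norm(resultant)
    dev = np.rad2deg(np.arccos(np.clip(achieved @ d, -1.0, 1.0)))
    meta["direction_deviation_deg"] = float(dev)
    if dev > 5.0:
        warnings.warn(
            f"load patch at {spec.effective_inclination} deg is clipped: achieved "
            f"resultant direction deviates {dev:.1f} deg from the nominal direction"
        )
        meta["clipped"] = True

    # patch area: radial projection of exposed outer faces inside the cone
    f_pos, f_nrm = _outer_surface_faces(model)
    f_rad = np.linalg.norm(f_pos, axis=1)
    r_mid = model.frame.head_radius + model.cartilage_thickness / 2
    in_cone = (f_rad >= r_mid) & ((f_pos @ d) / np.maximum(f_rad, 1e-12) >= np.cos(half))
    rhat = f_pos[in_cone] / f_rad[in_cone, None]
    area = float(np.abs((f_nrm[in_cone] * rhat).sum(axis=1)).sum() * model.voxel_size**2)

    return LoadCase(
        id=case_id, spec=spec, nodes=nodes, forces=forces,
        resultant=resultant, direction=d, patch_area=area, meta=meta,
    )
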